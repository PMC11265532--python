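"""Hexachromatic checkerboard sensor geometry and raw-frame simulation.

A hexachromatic imager pairs vertically stacked photodiodes (three spectral
measurements per pixel) with a pixelated filter array: visible-pass (400-700 nm)
and NIR-pass (700-1000 nm) filters alternate in a checkerboard, so each pixel
records either a visible (R, G, B) or a NIR (NIR1, NIR2, NIR3) triplet. Both
spectral streams are therefore sampled at half the sensor's spatial resolution,
offset from each other by one pixel horizontally.

This module defines the sampling geometry and simulates raw mosaic frames from
full-resolution six-channel ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNEL_NAMES = ("vis_r", "vis_g", "vis_b", "nir_1", "nir_2", "nir_3")

__all__ = [
    "CHANNEL_NAMES",
    "MultispectralImage",
    "SamplingMask",
    "MosaicFrame",
    "SparseChannelImage",
    "make_masks",
    "mosaic",
    "split",
    "recombine",
]


@dataclass(frozen=True)
class MultispectralImage:
    """Full-resolution H x W x 6 image in [0, 1].

    Channels 0-2 are the visible triplet (R, G, B), channels 3-5 the NIR
    triplet.
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 6:
            raise ValueError(f"expected H x W x 6 array, got shape {arr.shape}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("image must be at least 2 x 2 pixels")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("image values must lie in [0, 1]")
        if len(self.channel_names) != 6:
            raise ValueError("exactly 6 channel names required")
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def visible(self) -> np.ndarray:
        """The visible (R, G, B) channel stack."""
        return self.data[:, :, :3]

    @property
    def nir(self) -> np.ndarray:
        """The NIR channel stack."""
        return self.data[:, :, 3:]


@dataclass(frozen=True)
class SamplingMask:
    """Checkerboard partition of the pixel lattice into visible and NIR classes.

    ``phase`` records the parity of the visible class: pixel (r, c) is
    visible-class iff (r + c) % 2 == phase.
    """

    vis_mask: np.ndarray
    nir_mask: np.ndarray
    phase: int

    def __post_init__(self) -> None:
        vis = np.asarray(self.vis_mask, dtype=bool)
        nir = np.asarray(self.nir_mask, dtype=bool)
        if vis.shape != nir.shape or vis.ndim != 2:
            raise ValueError("masks must be 2-D arrays of identical shape")
        if self.phase not in (0, 1):
            raise ValueError(f"phase must be 0 or 1, got {self.phase}")
        if np.any(vis & nir) or not np.all(vis | nir):
            raise ValueError("masks must partition the pixel lattice")
        object.__setattr__(self, "vis_mask", vis)
        object.__setattr__(self, "nir_mask", nir)

    @property
    def shape(self) -> tuple[int, int]:
        return self.vis_mask.shape


@dataclass(frozen=True)
class MosaicFrame:
    """Raw H x W x 3 sensor readout: one triplet per pixel, class by parity."""

    data: np.ndarray
    phase: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("frame contains non-finite values")
        if self.phase not in (0, 1):
            raise ValueError(f"phase must be 0 or 1, got {self.phase}")
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def mask(self) -> SamplingMask:
        """The sampling mask implied by this frame's shape and phase."""
        return make_masks(self.height, self.width, self.phase)


@dataclass(frozen=True)
class SparseChannelImage:
    """Half-sampled 3-channel stream: data defined exactly where ``valid``.

    Unmeasured pixels are stored as 0; the valid mask is authoritative and a
    stored 0 must never be read as a measurement.
    """

    data: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        valid = np.asarray(self.valid, dtype=bool)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 array, got shape {arr.shape}")
        if valid.shape != arr.shape[:2]:
            raise ValueError("valid mask shape must match image plane")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sparse image contains non-finite values")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "valid", valid)


def make_masks(height: int, width: int, phase: int = 0) -> SamplingMask:
    """Build the checkerboard sampling masks for a ``height x width`` sensor.

    Pixel (r, c) belongs to the visible class iff ``(r + c) % 2 == phase``;
    the NIR class is the complement. Within every 2 x 2 block each class
    appears exactly twice, and the two streams are offset by one pixel
    horizontally.
    """
    if height < 2 or width < 2:
        raise ValueError(f"sensor must be at least 2 x 2, got {height} x {width}")
    if phase not in (0, 1):
        raise ValueError(f"phase must be 0 or 1, got {phase}")
    rr, cc = np.indices((height, width))
    vis = (rr + cc) % 2 == phase
    return SamplingMask(vis_mask=vis, nir_mask=~vis, phase=phase)


def mosaic(image: MultispectralImage, mask: SamplingMask) -> MosaicFrame:
    """Simulate the raw sensor frame for a six-channel scene.

    Visible-class pixels carry channels 0-2 of the scene, NIR-class pixels
    channels 3-5; sampled values are copied exactly (no resampling loss).
    """
    if mask.shape != (image.height, image.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match image "
            f"shape {(image.height, image.width)}"
        )
    frame = np.where(mask.vis_mask[:, :, None], image.visible, image.nir)
    return MosaicFrame(data=frame, phase=mask.phase)


def split(frame: MosaicFrame) -> tuple[SparseChannelImage, SparseChannelImage]:
    """Separate a mosaic frame into its visible and NIR half-sampled streams.

    Returns ``(visible_stream, nir_stream)``; their valid masks are
    complementary checkerboards and measured values equal the frame values
    bit-exactly.
    """
    mask = frame.mask()
    vis = SparseChannelImage(
        data=np.where(mask.vis_mask[:, :, None], frame.data, 0.0),
        valid=mask.vis_mask,
    )
    nir = SparseChannelImage(
        data=np.where(mask.nir_mask[:, :, None], frame.data, 0.0),
        valid=mask.nir_mask,
    )
    return vis, nir


def recombine(
    vis: SparseChannelImage, nir: SparseChannelImage, phase: int
) -> MosaicFrame:
    """Inverse of :func:`split`: reassemble the raw frame from its streams."""
    if vis.data.shape != nir.data.shape:
        raise ValueError("stream shapes differ")
    if np.any(vis.valid & nir.valid) or not np.all(vis.valid | nir.valid):
        raise ValueError("stream valid masks must be complementary")
    frame = np.where(vis.valid[:, :, None], vis.data, nir.data)
    return MosaicFrame(data=frame, phase=phase)
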