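"""1D bilinear interpolation baseline for checkerboard-sampled streams.

Because the visible and NIR streams are offset by one pixel horizontally, every
missing pixel of one stream has measured horizontal neighbours in the same row
(except at the left/right image border, where a single neighbour exists). The
baseline fills each missing pixel with the mean of its measured horizontal
neighbours, clamping to the single neighbour at borders. The result keeps the
low-frequency content of the full-resolution image — half of its pixels are the
true measurements — and serves both as the comparison method and as the input
to the residual CNN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensor import (
    MosaicFrame,
    MultispectralImage,
    SparseChannelImage,
    split,
)

__all__ = ["InterpolatedImage", "bilinear_1d", "demosaic_bilinear"]


@dataclass(frozen=True)
class InterpolatedImage:
    """Densely filled 3-channel image plus the mask of originally measured pixels."""

    data: np.ndarray
    source_valid: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        valid = np.asarray(self.source_valid, dtype=bool)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 array, got shape {arr.shape}")
        if valid.shape != arr.shape[:2]:
            raise ValueError("source_valid shape must match image plane")
        if not np.all(np.isfinite(arr)):
            raise ValueError("interpolated image contains non-finite values")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "source_valid", valid)


def _neighbor_average(
    data: np.ndarray, valid: np.ndarray, offsets: list[tuple[int, int]]
) -> np.ndarray:
    """Mean of measured neighbours at the given (dr, dc) offsets, per pixel.

    Neighbours outside the image or unmeasured do not contribute. Raises if a
    missing pixel ends up with no contributing neighbour (impossible under
    checkerboard masks, so it signals a malformed mask).
    """
    h, w, _ = data.shape
    acc = np.zeros((h, w, 3), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int64)
    for dr, dc in offsets:
        src_r = slice(max(0, -dr), h - max(0, dr))
        src_c = slice(max(0, -dc), w - max(0, dc))
        dst_r = slice(max(0, dr), h - max(0, -dr))
        dst_c = slice(max(0, dc), w - max(0, -dc))
        contrib = valid[src_r, src_c]
        acc[dst_r, dst_c] += np.where(
            contrib[:, :, None], data[src_r, src_c], 0.0
        )
        cnt[dst_r, dst_c] += contrib
    missing = ~valid
    if np.any(missing & (cnt == 0)):
        raise RuntimeError(
            "missing pixel with no measured neighbour; sampling mask is not a "
            "checkerboard class"
        )
    safe = np.maximum(cnt, 1)
    return acc / safe[:, :, None]


def bilinear_1d(
    sparse: SparseChannelImage, axis: str = "h", two_dimensional: bool = False
) -> InterpolatedImage:
    """Fill a half-sampled checkerboard stream by neighbour averaging.

    Parameters
    ----------
    sparse
        One checkerboard class of a mosaic frame.
    axis
        ``"h"`` (default) averages the left/right neighbours, matching the
        one-pixel horizontal offset of the two streams; ``"v"`` averages
        up/down instead.
    two_dimensional
        If true, average all four measured edge neighbours instead of the 1D
        pair. Provided for sensitivity checks; not the baseline.

    Measured pixels pass through bit-exactly; at borders the single available
    neighbour is replicated.
    """
    if axis not in ("h", "v"):
        raise ValueError(f"axis must be 'h' or 'v', got {axis!r}")
    if two_dimensional:
        offsets = [(0, -1), (0, 1), (-1, 0), (1, 0)]
    elif axis == "h":
        offsets = [(0, -1), (0, 1)]
    else:
        offsets = [(-1, 0), (1, 0)]
    filled = _neighbor_average(sparse.data, sparse.valid, offsets)
    out = np.where(sparse.valid[:, :, None], sparse.data, filled)
    return InterpolatedImage(data=out, source_valid=sparse.valid.copy())


def demosaic_bilinear(
    frame: MosaicFrame, axis: str = "h", two_dimensional: bool = False
) -> MultispectralImage:
    """Demosaic a raw frame by interpolating both streams independently.

    Splits the frame into its visible and NIR streams, fills each with
    :func:`bilinear_1d`, and stacks the results into a six-channel image
    (visible in channels 0-2, NIR in 3-5).
    """
    vis_sparse, nir_sparse = split(frame)
    vis = bilinear_1d(vis_sparse, axis=axis, two_dimensional=two_dimensional)
    nir = bilinear_1d(nir_sparse, axis=axis, two_dimensional=two_dimensional)
    stacked = np.concatenate([vis.data, nir.data], axis=2)
    return MultispectralImage(data=np.clip(stacked, 0.0, 1.0))
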