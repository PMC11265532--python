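"""Image-quality evaluation for demosaiced reconstructions.

Four metrics, computed against full-resolution ground truth on [0, 1] images:

* per-channel MSE and PSNR (PSNR = 10 log10(peak^2 / MSE), dB);
* the 95th percentile of the per-pixel structural dissimilarity
  DSSIM = (1 - SSIM) / 2, with SSIM from the standard 11x11 Gaussian window
  (sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1) — tail percentile rather
  than mean, so localized artifacts (zipper edges) are not averaged away;
* the 95th percentile of the per-pixel channel-space difference ("Delta E"),
  the Euclidean distance across a 3-channel triplet normalized by the maximal
  distance sqrt(3) * peak and expressed in percent. The same formula applies
  to visible and NIR triplets, keeping the two domains comparable (a CIE76
  Lab variant is available for the visible triplet);
* a frequency-domain comparison: centered log-magnitude FFT spectra and their
  central vertical-frequency line profile in dB, used to quantify how much
  high-frequency content a reconstruction loses.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import deltaE_cie76, rgb2lab
from skimage.metrics import structural_similarity

from .sensor import CHANNEL_NAMES, MultispectralImage

__all__ = [
    "MetricReport",
    "FrequencyProfile",
    "mse",
    "psnr",
    "dssim_map",
    "dssim_p95",
    "delta_e_p95",
    "frequency_compare",
    "evaluate",
]

LOG_FLOOR_DB = -120.0


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a: np.ndarray, b: np.ndarray) -> np.ndarray | float:
    """Mean squared error; per channel for H x W x C input, scalar for H x W."""
    a, b = _check_shapes(a, b)
    diff = a - b
    if diff.ndim == 3:
        return np.mean(diff * diff, axis=(0, 1))
    return float(np.mean(diff * diff))


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> np.ndarray | float:
    """Peak signal-to-noise ratio, 10 log10(peak^2 / MSE), in dB.

    Identical inputs give +inf (zero error has no finite PSNR).
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    err = mse(a, b)
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(peak**2 / np.asarray(err, dtype=np.float64))
    if np.ndim(err) == 0:
        return float(out)
    return out


def dssim_map(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> np.ndarray:
    """Per-pixel structural dissimilarity map, (1 - SSIM) / 2 in [0, 1].

    For multichannel input the SSIM map is averaged over channels before the
    dissimilarity transform.
    """
    a, b = _check_shapes(a, b)
    kwargs = dict(
        data_range=peak,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
        full=True,
    )
    if a.ndim == 3:
        _, smap = structural_similarity(a, b, channel_axis=-1, **kwargs)
        smap = smap.mean(axis=-1)
    else:
        _, smap = structural_similarity(a, b, **kwargs)
    return np.clip((1.0 - smap) / 2.0, 0.0, 1.0)


def dssim_p95(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """95th percentile of the per-pixel DSSIM map."""
    return float(np.percentile(dssim_map(a, b, peak=peak), 95))


def delta_e_p95(
    a: np.ndarray, b: np.ndarray, peak: float = 1.0, method: str = "euclidean"
) -> float:
    """95th percentile of the per-pixel triplet difference.

    ``method="euclidean"`` (default): Euclidean distance across the three
    channels, as a percentage of the maximal distance sqrt(3) * peak; valid
    for visible and NIR triplets alike. ``method="cie76"``: CIE76 Delta E*ab
    after Lab conversion (visible triplet only; reported in Delta E units,
    not percent).
    """
    a, b = _check_shapes(a, b)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("delta E requires an H x W x 3 triplet image")
    if method == "euclidean":
        dist = np.sqrt(np.sum((a - b) ** 2, axis=2))
        pct = 100.0 * dist / (np.sqrt(3.0) * peak)
        return float(np.percentile(pct, 95))
    if method == "cie76":
        de = deltaE_cie76(rgb2lab(a / peak), rgb2lab(b / peak))
        return float(np.percentile(de, 95))
    raise ValueError(f"unknown delta E method {method!r}")


@dataclass(frozen=True)
class FrequencyProfile:
    """Centered log-magnitude spectra and their vertical-frequency profiles.

    ``profile`` and ``reference_profile`` are the central columns of the
    shifted spectra (vertical frequencies, DC at the middle index), in dB;
    ``difference_profile`` is reconstruction minus reference.
    """

    spectrum: np.ndarray
    reference_spectrum: np.ndarray
    profile: np.ndarray
    reference_profile: np.ndarray
    difference_profile: np.ndarray

    def high_frequency_deficit(self, fraction: float = 0.25) -> float:
        """Mean |difference| (dB) over the top ``fraction`` of vertical
        frequencies (largest distances from DC in the line profile)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n = self.difference_profile.shape[0]
        center = n // 2
        dist = np.abs(np.arange(n) - center)
        cutoff = dist.max() * (1.0 - fraction)
        sel = dist > cutoff
        if not np.any(sel):
            sel = dist == dist.max()
        return float(np.mean(np.abs(self.difference_profile[sel])))


def _log_magnitude(image: np.ndarray) -> np.ndarray:
    spec = np.fft.fftshift(np.fft.fft2(image))
    mag_db = 20.0 * np.log10(np.abs(spec) + 10 ** (LOG_FLOOR_DB / 20.0))
    return np.maximum(mag_db, LOG_FLOOR_DB)


def frequency_compare(recon: np.ndarray, reference: np.ndarray) -> FrequencyProfile:
    """Compare a reconstruction's FFT magnitude with its reference.

    Inputs are single-channel (use luminance for a visible image). The
    spectrum of a real image is conjugate-symmetric, so the central column of
    the shifted spectrum summarizes the vertical-frequency content.
    """
    recon, reference = _check_shapes(recon, reference)
    if recon.ndim != 2:
        raise ValueError("frequency comparison expects single-channel images")
    spec_r = _log_magnitude(recon)
    spec_t = _log_magnitude(reference)
    col = recon.shape[1] // 2
    prof_r = spec_r[:, col]
    prof_t = spec_t[:, col]
    return FrequencyProfile(
        spectrum=spec_r,
        reference_spectrum=spec_t,
        profile=prof_r,
        reference_profile=prof_t,
        difference_profile=prof_r - prof_t,
    )


@dataclass(frozen=True)
class MetricReport:
    """Per-channel PSNR/MSE plus tail DSSIM and Delta E for one comparison."""

    psnr: dict[str, float]
    mse: dict[str, float]
    p95_dssim_vis: float
    p95_dssim_nir: float
    p95_delta_e_vis: float
    p95_delta_e_nir: float

    def to_dict(self) -> dict:
        return {
            "psnr_db": dict(self.psnr),
            "mse": dict(self.mse),
            "p95_dssim": {"vis": self.p95_dssim_vis, "nir": self.p95_dssim_nir},
            "p95_delta_e_pct": {
                "vis": self.p95_delta_e_vis,
                "nir": self.p95_delta_e_nir,
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "channel", "value"])
            for name, val in self.psnr.items():
                writer.writerow(["psnr_db", name, val])
            for name, val in self.mse.items():
                writer.writerow(["mse", name, val])
            writer.writerow(["p95_dssim", "vis", self.p95_dssim_vis])
            writer.writerow(["p95_dssim", "nir", self.p95_dssim_nir])
            writer.writerow(["p95_delta_e_pct", "vis", self.p95_delta_e_vis])
            writer.writerow(["p95_delta_e_pct", "nir", self.p95_delta_e_nir])


def evaluate(
    recon: MultispectralImage, truth: MultispectralImage, peak: float = 1.0
) -> MetricReport:
    """Full four-metric report for a reconstruction against ground truth."""
    a, b = _check_shapes(recon.data, truth.data)
    per_channel_mse = np.mean((a - b) ** 2, axis=(0, 1))
    with np.errstate(divide="ignore"):
        per_channel_psnr = 10.0 * np.log10(peak**2 / per_channel_mse)
    return MetricReport(
        psnr={name: float(v) for name, v in zip(CHANNEL_NAMES, per_channel_psnr)},
        mse={name: float(v) for name, v in zip(CHANNEL_NAMES, per_channel_mse)},
        p95_dssim_vis=dssim_p95(a[:, :, :3], b[:, :, :3], peak=peak),
        p95_dssim_nir=dssim_p95(a[:, :, 3:], b[:, :, 3:], peak=peak),
        p95_delta_e_vis=delta_e_p95(a[:, :, :3], b[:, :, :3], peak=peak),
        p95_delta_e_nir=delta_e_p95(a[:, :, 3:], b[:, :, 3:], peak=peak),
    )
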