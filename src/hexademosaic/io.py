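"""Reading and writing of images, frames, logs and configs.

Pixel data live in [0, 1] in memory; integer files (8/16-bit PNG and TIFF)
are normalized on read and re-quantized on write, losslessly at the stored
bit depth. Six-channel images are stored as 6-page single-channel TIFFs in
the fixed page order vis_r, vis_g, vis_b, nir_1, nir_2, nir_3; raw mosaic
frames as 3-channel TIFFs with a JSON sidecar recording the checkerboard
phase and channel semantics.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .sensor import CHANNEL_NAMES, MosaicFrame, MultispectralImage

__all__ = [
    "read_image",
    "write_image",
    "read_multispectral",
    "write_multispectral",
    "read_frame",
    "write_frame",
    "write_training_log",
    "load_train_config",
]

_MAXVAL = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


def _normalize(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype in _MAXVAL:
        return arr.astype(np.float64) / _MAXVAL[arr.dtype]
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise IOError(f"{path}: unsupported pixel dtype {arr.dtype}")


def _quantize(data: np.ndarray, bit_depth: int) -> np.ndarray:
    if bit_depth == 8:
        return np.round(np.clip(data, 0, 1) * 255.0).astype(np.uint8)
    if bit_depth == 16:
        return np.round(np.clip(data, 0, 1) * 65535.0).astype(np.uint16)
    raise ValueError(f"unsupported bit depth {bit_depth}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as float64 in [0, 1].

    Multi-page TIFFs come back as H x W x pages; single images keep their
    native layout (H x W or H x W x C).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tif:
                series = tif.series[0]
                arr = series.asarray()
                axes = series.axes
            if arr.ndim == 3 and not axes.endswith("S"):
                # page-major stack -> channel-last
                arr = np.moveaxis(arr, 0, -1)
        else:
            arr = np.asarray(iio.imread(path))
    except Exception as exc:  # corrupt or unreadable
        raise IOError(f"failed to read image {path}: {exc}") from exc
    return _normalize(arr, path)


def write_image(path: str | Path, data: np.ndarray, bit_depth: int = 16) -> None:
    """Write an image, quantizing [0, 1] floats to the requested bit depth.

    H x W x 6 arrays are written as 6-page TIFFs; other layouts as ordinary
    single-page images.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    q = _quantize(np.asarray(data), bit_depth)
    if path.suffix.lower() in (".tif", ".tiff"):
        if q.ndim == 3 and q.shape[2] == 6:
            tifffile.imwrite(path, np.moveaxis(q, -1, 0), photometric="minisblack")
        elif q.ndim == 3 and q.shape[2] == 3:
            tifffile.imwrite(path, q, photometric="rgb")
        else:
            tifffile.imwrite(path, q)
    else:
        iio.imwrite(path, q)


def read_multispectral(path: str | Path) -> MultispectralImage:
    """Read a six-channel image from a 6-page TIFF."""
    arr = read_image(path)
    if arr.ndim != 3 or arr.shape[2] != 6:
        raise IOError(f"{path}: expected a 6-page multispectral TIFF, got {arr.shape}")
    return MultispectralImage(data=arr)


def write_multispectral(
    path: str | Path, image: MultispectralImage, bit_depth: int = 16
) -> None:
    write_image(path, image.data, bit_depth=bit_depth)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame(path: str | Path, frame: MosaicFrame, bit_depth: int = 16) -> None:
    """Write a raw mosaic frame plus its JSON sidecar (phase, semantics)."""
    path = Path(path)
    write_image(path, frame.data, bit_depth=bit_depth)
    meta = {
        "format": "hexademosaic-mosaic-frame",
        "phase": frame.phase,
        "channel_names": list(CHANNEL_NAMES),
        "convention": "pixel (r, c) carries the visible triplet iff (r + c) % 2 == phase",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_frame(path: str | Path, phase: int | None = None) -> MosaicFrame:
    """Read a raw frame; the phase comes from the sidecar unless overridden."""
    path = Path(path)
    arr = read_image(path)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"{path}: expected a 3-channel mosaic frame, got {arr.shape}")
    if phase is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise IOError(f"{path}: no phase given and sidecar {sidecar} missing")
        phase = int(json.loads(sidecar.read_text())["phase"])
    return MosaicFrame(data=arr, phase=phase)


def write_training_log(path: str | Path, log: list[dict]) -> None:
    """Training log as CSV with columns step, loss, lr."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["step", "loss", "lr"])
        writer.writeheader()
        writer.writerows(log)


_TRAIN_KEYS = {
    "depth", "filters", "learning_rate", "patch_size", "patches_per_image",
    "augment", "batch_size", "steps", "seed", "phase", "axis", "dtype",
    "log_every", "zero_init_final",
}
_DATA_KEYS = {"dir", "synthetic"}
_SYNTH_KEYS = {
    "n", "seed", "height", "width", "n_edges", "n_curves", "curve_width",
    "n_textures", "gradient_amplitude", "vis_nir_correlation", "noise_sigma",
}


def load_train_config(path: str | Path) -> dict:
    """Load and validate a YAML training config.

    Schema: top-level keys ``data`` (either ``dir: <path>`` or ``synthetic:
    {n, seed, ...scene fields}``) and ``train`` (TrainConfig fields). Unknown
    keys anywhere are rejected.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - {"data", "train"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    data = cfg.get("data", {})
    if not isinstance(data, dict) or (set(data) - _DATA_KEYS):
        raise ValueError(f"{path}: 'data' must contain only {sorted(_DATA_KEYS)}")
    if "synthetic" in data:
        extra = set(data["synthetic"]) - _SYNTH_KEYS
        if extra:
            raise ValueError(f"{path}: unknown synthetic-data keys {sorted(extra)}")
    train = cfg.get("train", {})
    if not isinstance(train, dict) or (set(train) - _TRAIN_KEYS):
        bad = sorted(set(train) - _TRAIN_KEYS) if isinstance(train, dict) else train
        raise ValueError(f"{path}: unknown train keys {bad}")
    return cfg
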