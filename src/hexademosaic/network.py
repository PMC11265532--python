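"""Deep residual CNN that predicts high-frequency demosaicing corrections.

The network maps a bilinearly interpolated 3-channel stream to the residual
(ground truth minus interpolation); the demosaiced stream is interpolation plus
predicted residual. Architecture: N convolutional layers with 3x3 kernels and
one-pixel padding. Layers 1..N-1 use 64 filters, each followed by batch
normalization and a SELU activation; layer N is a plain convolution down to 3
channels with no normalization or activation. Because the interpolated input
already carries the low-frequency content (half its pixels are exact
measurements), the network only has to learn the high-frequency differences,
which keeps very deep models trainable.

Implemented directly on numpy (im2col + BLAS matmul); both the inference path
and the analytic backward pass used by the trainer live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .interp import bilinear_1d
from .sensor import MosaicFrame, MultispectralImage, split

# Canonical self-normalizing SELU constants (fixed points of the SELU map).
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772

__all__ = [
    "SELU_LAMBDA",
    "SELU_ALPHA",
    "SeluParams",
    "NetworkConfig",
    "ResidualModel",
    "selu",
    "selu_grad",
    "conv2d",
    "demosaic_cnn",
    "reconstruct",
]


@dataclass(frozen=True)
class SeluParams:
    """Scale (lambda) and negative-branch saturation (alpha) of SELU."""

    lambda_: float = SELU_LAMBDA
    alpha: float = SELU_ALPHA

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.alpha <= 0:
            raise ValueError("SELU lambda and alpha must be positive")


def selu(x: np.ndarray | float, params: SeluParams = SeluParams()) -> np.ndarray:
    """selu(x) = lambda * x for x > 0, lambda * alpha * (e^x - 1) for x <= 0."""
    x = np.asarray(x)
    return np.where(
        x > 0, params.lambda_ * x, params.lambda_ * params.alpha * np.expm1(x)
    )


def selu_grad(x: np.ndarray, params: SeluParams = SeluParams()) -> np.ndarray:
    """Derivative of SELU w.r.t. its input (right derivative at 0)."""
    x = np.asarray(x)
    return np.where(
        x > 0, params.lambda_, params.lambda_ * params.alpha * np.exp(np.minimum(x, 0))
    )


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the residual network."""

    depth: int = 20
    filters: int = 64
    kernel_size: int = 3
    in_channels: int = 3
    out_channels: int = 3

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd to preserve dimensions")
        if min(self.filters, self.in_channels, self.out_channels) < 1:
            raise ValueError("channel counts must be positive")

    @property
    def padding(self) -> int:
        return self.kernel_size // 2


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Unfold NHWC input into (B*H*W, k*k*C) patch rows (zero padding)."""
    b, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    # windows: (B, H, W, C, k, k) -> (B, H, W, k, k, C)
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    v = v.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(v).reshape(b * h * w, k * k * c)


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padding 2-D convolution of an NHWC batch.

    ``weight`` has shape (k, k, C_in, C_out); kernels span the full input
    channel depth, so a single kernel is a k x k x C_in volume.
    """
    out, _ = _conv_forward(x, weight, bias)
    return out


def _conv_forward(
    x: np.ndarray, weight: np.ndarray, bias: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    k, _, cin, cout = weight.shape
    if x.shape[3] != cin:
        raise ValueError(f"input has {x.shape[3]} channels, kernel expects {cin}")
    if x.shape[1] < k or x.shape[2] < k:
        raise ValueError("spatial dimensions smaller than the kernel")
    cols = _im2col(x, k, k // 2)
    out = cols @ weight.reshape(k * k * cin, cout)
    out += bias
    b, h, w, _ = x.shape
    return out.reshape(b, h, w, cout), cols


def _conv_backward(
    dout: np.ndarray, cols: np.ndarray, weight: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padding convolution.

    Returns (dx, dW, db). dx is itself a convolution of dout with the
    spatially flipped kernel, channels transposed.
    """
    k, _, cin, cout = weight.shape
    dflat = dout.reshape(-1, cout)
    dw = (cols.T @ dflat).reshape(k, k, cin, cout)
    db = dflat.sum(axis=0)
    w_rot = weight[::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, cout, cin)
    dx, _ = _conv_forward(dout, np.ascontiguousarray(w_rot), np.zeros(cin, weight.dtype))
    return dx, dw, db


class ResidualModel:
    """Learnable residual predictor: weights, biases and normalization state.

    Hidden layers hold convolution weight/bias plus batch-norm scale (gamma),
    shift (beta) and running mean/variance; the final layer holds only
    weight/bias. Training mode normalizes with batch statistics and updates
    the running estimates; inference mode uses the stored running statistics.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(
        self,
        config: NetworkConfig,
        selu_params: SeluParams = SeluParams(),
        dtype: np.dtype = np.float32,
        provenance: dict | None = None,
    ) -> None:
        self.config = config
        self.selu_params = selu_params
        self.dtype = np.dtype(dtype)
        self.provenance = dict(provenance or {})
        self.layers: list[dict[str, np.ndarray]] = []

    # ---------------------------------------------------------------- init
    @classmethod
    def initialize(
        cls,
        config: NetworkConfig,
        seed: int = 0,
        selu_params: SeluParams = SeluParams(),
        dtype: np.dtype = np.float32,
    ) -> "ResidualModel":
        """MSRA (He) initialization: W ~ N(0, 2/fan_in), zero biases,
        unit batch-norm scale, zero shift."""
        model = cls(config, selu_params, dtype, provenance={"init_seed": int(seed)})
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        cin = config.in_channels
        for n in range(config.depth):
            last = n == config.depth - 1
            cout = config.out_channels if last else config.filters
            fan_in = k * k * cin
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, cout))
            layer = {
                "W": w.astype(model.dtype),
                "b": np.zeros(cout, dtype=model.dtype),
            }
            if not last:
                layer["gamma"] = np.ones(cout, dtype=model.dtype)
                layer["beta"] = np.zeros(cout, dtype=model.dtype)
                layer["run_mean"] = np.zeros(cout, dtype=model.dtype)
                layer["run_var"] = np.ones(cout, dtype=model.dtype)
            model.layers.append(layer)
            cin = cout
        return model

    @property
    def trainable_keys(self) -> tuple[str, ...]:
        return ("W", "b", "gamma", "beta")

    def zero_final_layer(self) -> None:
        """Zero the last layer's parameters; the model then predicts a zero
        residual and demosaicing reduces exactly to the bilinear baseline."""
        self.layers[-1]["W"][:] = 0
        self.layers[-1]["b"][:] = 0

    # ------------------------------------------------------------- forward
    def forward(
        self, x: np.ndarray, training: bool = False, want_cache: bool = False
    ):
        """Predict the residual for a batch of interpolated patches.

        ``x`` is (B, H, W, 3) or (H, W, 3); output spatial shape equals the
        input's. With ``want_cache`` the per-layer intermediates needed by
        :meth:`backward` are returned alongside the residual.
        """
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        if x.ndim != 4 or x.shape[3] != self.config.in_channels:
            raise ValueError(f"expected NHWC input with "
                             f"{self.config.in_channels} channels, got {x.shape}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        caches: list[dict] = []
        h = x
        for n, layer in enumerate(self.layers):
            last = n == len(self.layers) - 1
            z, cols = _conv_forward(h, layer["W"], layer["b"])
            cache: dict = {"cols": cols} if want_cache else {}
            if not last:
                z, bn_cache = self._bn_forward(z, layer, training)
                h = selu(z, self.selu_params).astype(self.dtype, copy=False)
                if want_cache:
                    cache["bn"] = bn_cache
                    cache["z"] = z
            else:
                h = z
            if want_cache:
                caches.append(cache)
        out = h[0] if squeeze else h
        return (out, caches) if want_cache else out

    def _bn_forward(self, z: np.ndarray, layer: dict, training: bool):
        if training:
            mu = z.mean(axis=(0, 1, 2))
            var = z.var(axis=(0, 1, 2))
            m = self.BN_MOMENTUM
            layer["run_mean"] = ((1 - m) * layer["run_mean"] + m * mu).astype(self.dtype)
            layer["run_var"] = ((1 - m) * layer["run_var"] + m * var).astype(self.dtype)
        else:
            mu = layer["run_mean"]
            var = layer["run_var"]
        inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
        xhat = (z - mu) * inv_std
        out = layer["gamma"] * xhat + layer["beta"]
        cache = {"xhat": xhat, "inv_std": inv_std, "training": training}
        return out.astype(self.dtype, copy=False), cache

    # ------------------------------------------------------------ backward
    def backward(self, d_res: np.ndarray, caches: list[dict]) -> list[dict]:
        """Backpropagate a gradient w.r.t. the residual through all layers.

        Returns one gradient dict per layer (keys matching the trainable
        parameters). Requires the cache from ``forward(..., training=True,
        want_cache=True)``.
        """
        grads: list[dict] = [dict() for _ in self.layers]
        d = np.ascontiguousarray(d_res, dtype=self.dtype)
        if d.ndim == 3:
            d = d[None]
        for n in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[n]
            cache = caches[n]
            last = n == len(self.layers) - 1
            if not last:
                d = d * selu_grad(cache["z"], self.selu_params).astype(self.dtype)
                d, dgamma, dbeta = self._bn_backward(d, layer, cache["bn"])
                grads[n]["gamma"] = dgamma
                grads[n]["beta"] = dbeta
            d, dw, db = _conv_backward(d, cache["cols"], layer["W"])
            grads[n]["W"] = dw
            grads[n]["b"] = db
        return grads

    def _bn_backward(self, dout: np.ndarray, layer: dict, bn_cache: dict):
        xhat = bn_cache["xhat"]
        inv_std = bn_cache["inv_std"]
        dgamma = (dout * xhat).sum(axis=(0, 1, 2))
        dbeta = dout.sum(axis=(0, 1, 2))
        if not bn_cache["training"]:
            # running statistics are constants in inference mode
            return dout * layer["gamma"] * inv_std, dgamma, dbeta
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        dxhat = dout * layer["gamma"]
        dz = (
            inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=(0, 1, 2)) - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
        )
        return dz.astype(self.dtype, copy=False), dgamma, dbeta

    # ------------------------------------------------------- serialization
    def save(self, path: str | Path) -> None:
        """Write the checkpoint: ``<path>`` (npz arrays) + ``<path>.json`` manifest."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        arrays = {}
        for n, layer in enumerate(self.layers):
            for key, val in layer.items():
                arrays[f"layer{n}_{key}"] = val
        np.savez(path, **arrays)
        manifest = {
            "format": "hexademosaic-residual-model",
            "depth": self.config.depth,
            "filters": self.config.filters,
            "kernel_size": self.config.kernel_size,
            "in_channels": self.config.in_channels,
            "out_channels": self.config.out_channels,
            "selu_lambda": self.selu_params.lambda_,
            "selu_alpha": self.selu_params.alpha,
            "dtype": self.dtype.name,
            "provenance": self.provenance,
        }
        manifest_path = path.with_suffix(path.suffix + ".json")
        manifest_path.write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ResidualModel":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        manifest_path = path.with_suffix(path.suffix + ".json")
        if not manifest_path.exists():
            raise FileNotFoundError(f"missing checkpoint manifest {manifest_path}")
        manifest = json.loads(manifest_path.read_text())
        config = NetworkConfig(
            depth=manifest["depth"],
            filters=manifest["filters"],
            kernel_size=manifest["kernel_size"],
            in_channels=manifest["in_channels"],
            out_channels=manifest["out_channels"],
        )
        model = cls(
            config,
            SeluParams(manifest["selu_lambda"], manifest["selu_alpha"]),
            dtype=np.dtype(manifest["dtype"]),
            provenance=manifest.get("provenance", {}),
        )
        with np.load(path) as data:
            model.layers = [dict() for _ in range(config.depth)]
            for key in data.files:
                idx, pname = key[len("layer"):].split("_", 1)
                model.layers[int(idx)][pname] = data[key]
        return model


def reconstruct(
    frame: MosaicFrame,
    vis_model: ResidualModel,
    nir_model: ResidualModel | None = None,
    axis: str = "h",
) -> np.ndarray:
    """Demosaic a raw frame with the CNN; returns the unclipped 6-channel array.

    Each stream is bilinearly interpolated and the model's predicted residual
    is added back. By default the NIR stream reuses the visible-trained model
    (the color and NIR spectra carry comparable high-frequency structure, so a
    color-trained network transfers); pass ``nir_model`` for independent NIR
    weights.
    """
    if vis_model is None:
        raise ValueError("a visible-stream model is required")
    if nir_model is None:
        nir_model = vis_model
    vis_sparse, nir_sparse = split(frame)
    out = np.empty((frame.height, frame.width, 6), dtype=np.float64)
    for sl, sparse, model in (
        (slice(0, 3), vis_sparse, vis_model),
        (slice(3, 6), nir_sparse, nir_model),
    ):
        interp = bilinear_1d(sparse, axis=axis)
        residual = model.forward(interp.data.astype(model.dtype), training=False)
        out[:, :, sl] = interp.data + residual.astype(np.float64)
    return out


def demosaic_cnn(
    frame: MosaicFrame,
    vis_model: ResidualModel,
    nir_model: ResidualModel | None = None,
    axis: str = "h",
) -> MultispectralImage:
    """CNN demosaicing with the output clipped to the sensor's [0, 1] range."""
    raw = reconstruct(frame, vis_model, nir_model=nir_model, axis=axis)
    return MultispectralImage(data=np.clip(raw, 0.0, 1.0))
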