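"""Training of the residual demosaicing network.

Training data are full-resolution 3-channel images treated as ground truth for
one sensor stream: each ground-truth patch X is checkerboard-sampled, the
missing pixels are filled by 1D bilinear interpolation to give Y, and the
network is trained to predict the residual X - Y. The objective is the batch
mean of the squared L2 norm of the reconstruction error,

    L(theta) = (1/n) * sum_i || (F(Y_i; theta) + Y_i) - X_i ||^2,

minimized with Adam from MSRA-initialized weights. Patches (default 100 per
image, 50 x 50 px — demosaicing is a local prediction problem, so local
context dominates) are augmented with the 8 dihedral transforms (4 rotations
x horizontal flip); the mosaic/interpolation simulation is re-applied to each
augmented patch so the horizontal interpolation geometry stays consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .interp import bilinear_1d
from .network import NetworkConfig, ResidualModel, SeluParams
from .sensor import (
    MosaicFrame,
    SparseChannelImage,
    make_masks,
)

__all__ = [
    "TrainConfig",
    "PatchBatch",
    "extract_patches",
    "augment",
    "residual_loss",
    "simulate_pair",
    "build_patch_pool",
    "Adam",
    "train",
    "train_on_patches",
]


@dataclass
class TrainConfig:
    """Hyperparameters of a training run.

    ``learning_rate`` defaults to 1e-5, the constant-rate Adam setting used
    at full scale; short runs (a few hundred steps) need a larger rate to
    move He-initialized weights appreciably. Batch size and step budget are
    free choices — only the constant-rate policy is fixed.
    """

    depth: int = 20
    filters: int = 64
    learning_rate: float = 1e-5
    patch_size: int = 50
    patches_per_image: int = 100
    augment: bool = True
    batch_size: int = 64
    steps: int = 1000
    seed: int = 0
    phase: int = 0
    axis: str = "h"
    dtype: str = "float32"
    log_every: int = 1
    zero_init_final: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patch_size < 3:
            raise ValueError("patch size must be at least the kernel size")
        if min(self.batch_size, self.steps, self.patches_per_image) < 1:
            raise ValueError("batch size, steps and patches_per_image must be >= 1")
        if self.phase not in (0, 1):
            raise ValueError("phase must be 0 or 1")

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(depth=self.depth, filters=self.filters)


@dataclass(frozen=True)
class PatchBatch:
    """Aligned training patches: network input Y, ground truth X, and the
    bilinear base Y_hat added back to the predicted residual (here the input
    and the base coincide: the network consumes the interpolation itself)."""

    Y: np.ndarray
    X: np.ndarray
    Y_hat: np.ndarray

    def __post_init__(self) -> None:
        if not (self.Y.shape == self.X.shape == self.Y_hat.shape):
            raise ValueError("patch tensors must be aligned")


def extract_patches(
    image: np.ndarray, n: int, size: int, seed: int
) -> list[np.ndarray]:
    """``n`` square patches at uniformly random offsets (with replacement)."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than patch size {size}")
    rng = np.random.default_rng(seed)
    tops = rng.integers(0, h - size + 1, n)
    lefts = rng.integers(0, w - size + 1, n)
    return [image[t : t + size, l : l + size].copy() for t, l in zip(tops, lefts)]


def augment(patch: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral variants of a square patch (4 rotations x h-flip).

    The original is element 0; re-applying ``augment`` to any output yields
    the same set of 8 (group closure).
    """
    patch = np.asarray(patch)
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("augmentation requires a square patch")
    out = []
    for k in range(4):
        rot = np.rot90(patch, k)
        out.append(np.ascontiguousarray(rot))
        out.append(np.ascontiguousarray(rot[:, ::-1]))
    return out


def residual_loss(
    residual: np.ndarray, y_hat: np.ndarray, x: np.ndarray
) -> float:
    """Batch mean of the squared L2 norm of (residual + y_hat - x).

    Zero exactly when the reconstruction equals the ground truth.
    """
    residual, y_hat, x = (np.asarray(a) for a in (residual, y_hat, x))
    if not (residual.shape == y_hat.shape == x.shape):
        raise ValueError("residual, y_hat and x must share a shape")
    err = residual.astype(np.float64) + y_hat.astype(np.float64) - x.astype(np.float64)
    n = err.shape[0] if err.ndim == 4 else 1
    return float(np.sum(err * err) / n)


def simulate_pair(
    patch: np.ndarray, phase: int = 0, axis: str = "h"
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the sensor for one ground-truth patch: (interpolated, truth).

    The patch is checkerboard-sampled as one stream (the complementary class
    carries the other spectral band and is simply absent here) and refilled
    with the 1D bilinear baseline.
    """
    patch = np.asarray(patch, dtype=np.float64)
    mask = make_masks(patch.shape[0], patch.shape[1], phase)
    sparse = SparseChannelImage(
        data=np.where(mask.vis_mask[:, :, None], patch, 0.0), valid=mask.vis_mask
    )
    interp = bilinear_1d(sparse, axis=axis)
    return interp.data, patch


def build_patch_pool(
    images: list[np.ndarray], config: TrainConfig
) -> PatchBatch:
    """Extract, augment and sensor-simulate the training patch pool."""
    if len(images) == 0:
        raise ValueError("training requires at least one image")
    ys, xs = [], []
    for i, img in enumerate(images):
        img = np.asarray(img, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("training images must be H x W x 3")
        patches = extract_patches(
            img, config.patches_per_image, config.patch_size, config.seed + 7919 * i
        )
        for patch in patches:
            variants = augment(patch) if config.augment else [patch]
            for var in variants:
                y, x = simulate_pair(var, phase=config.phase, axis=config.axis)
                ys.append(y)
                xs.append(x)
    dtype = np.dtype(config.dtype)
    y_arr = np.stack(ys).astype(dtype)
    x_arr = np.stack(xs).astype(dtype)
    return PatchBatch(Y=y_arr, X=x_arr, Y_hat=y_arr)


class Adam:
    """Adam optimizer over a ResidualModel's trainable parameters."""

    def __init__(
        self,
        model: ResidualModel,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.model = model
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(layer[k]) for k in model.trainable_keys if k in layer}
            for layer in model.layers
        ]
        self.v = [
            {k: np.zeros_like(layer[k]) for k in model.trainable_keys if k in layer}
            for layer in model.layers
        ]

    def step(self, grads: list[dict]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for layer, g, m, v in zip(self.model.layers, grads, self.m, self.v):
            for key in g:
                grad = g[key].astype(layer[key].dtype, copy=False)
                m[key] = self.beta1 * m[key] + (1 - self.beta1) * grad
                v[key] = self.beta2 * v[key] + (1 - self.beta2) * grad * grad
                mhat = m[key] / b1c
                vhat = v[key] / b2c
                layer[key] = layer[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_on_patches(
    pool: PatchBatch,
    config: TrainConfig,
    model: ResidualModel | None = None,
) -> tuple[ResidualModel, list[dict]]:
    """Run the Adam loop on a prepared patch pool; returns (model, log).

    Batches are drawn with replacement under the config seed; the log records
    (step, loss, lr) per logged step. A non-finite loss aborts with a
    diagnostic.
    """
    if model is None:
        model = ResidualModel.initialize(
            config.network_config(),
            seed=config.seed,
            dtype=np.dtype(config.dtype),
        )
        if config.zero_init_final:
            # start the residual branch at zero: the untrained model then
            # reproduces the bilinear baseline exactly, and a short run can
            # only build improvements on top of parity
            model.zero_final_layer()
        model.provenance.update(
            {"train_config": {k: v for k, v in asdict(config).items()}}
        )
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model, lr=config.learning_rate)
    n_pool = pool.Y.shape[0]
    log: list[dict] = []
    for step in range(1, config.steps + 1):
        idx = rng.integers(0, n_pool, config.batch_size)
        y = pool.Y[idx]
        x = pool.X[idx]
        res, caches = model.forward(y, training=True, want_cache=True)
        err = res + y - x
        loss_val = float(np.sum(err.astype(np.float64) ** 2) / y.shape[0])
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"training diverged: non-finite loss {loss_val} at step {step} "
                f"(lr={config.learning_rate})"
            )
        d_res = (2.0 / y.shape[0]) * err
        grads = model.backward(d_res, caches)
        opt.step(grads)
        if step % config.log_every == 0 or step == config.steps:
            log.append({"step": step, "loss": loss_val, "lr": config.learning_rate})
    return model, log


def train(
    images: list[np.ndarray], config: TrainConfig
) -> tuple[ResidualModel, list[dict]]:
    """Train a residual model from a set of 3-channel ground-truth images."""
    pool = build_patch_pool(images, config)
    return train_on_patches(pool, config)
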