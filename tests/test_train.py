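import numpy as np
import pytest

from hexademosaic import (
    NetworkConfig,
    PatchBatch,
    ResidualModel,
    TrainConfig,
    augment,
    extract_patches,
    residual_loss,
    train,
)
from hexademosaic.network import conv2d
from hexademosaic.train import build_patch_pool, simulate_pair, train_on_patches


def _signature(patch):
    return patch.tobytes()


class TestExtractPatches:
    def test_single_placement_returns_whole_image(self, rng):
        img = rng.uniform(0, 1, (50, 50, 3))
        (patch,) = extract_patches(img, 1, 50, seed=0)
        assert np.array_equal(patch, img)

    def test_deterministic_under_seed(self, rng):
        img = rng.uniform(0, 1, (80, 90, 3))
        a = extract_patches(img, 10, 20, seed=7)
        b = extract_patches(img, 10, 20, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_all_patches_inside_bounds(self, rng):
        img = rng.uniform(0, 1, (200, 200, 3))
        patches = extract_patches(img, 100, 50, seed=1)
        assert len(patches) == 100
        assert all(p.shape == (50, 50, 3) for p in patches)
        pool = {p.tobytes() for p in patches}
        # placements vary (no out-of-bounds clamping artifacts)
        assert len(pool) > 1

    def test_image_smaller_than_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches(rng.uniform(0, 1, (30, 30, 3)), 1, 50, seed=0)


class TestAugment:
    def test_generic_patch_gives_8_distinct_variants(self, rng):
        patch = rng.uniform(0, 1, (6, 6, 3))
        variants = augment(patch)
        assert len(variants) == 8
        assert len({_signature(v) for v in variants}) == 8
        assert _signature(variants[0]) == _signature(patch)

    def test_constant_patch_gives_identical_variants(self):
        variants = augment(np.full((4, 4, 3), 0.3))
        assert len({_signature(v) for v in variants}) == 1

    def test_group_closure(self, rng):
        patch = rng.uniform(0, 1, (5, 5, 3))
        orbit = {_signature(v) for v in augment(patch)}
        for v in augment(patch):
            assert {_signature(u) for u in augment(v)} == orbit

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(rng.uniform(0, 1, (4, 6, 3)))

    def test_pool_size_multiplied_by_8(self, rng):
        img = rng.uniform(0, 1, (60, 60, 3))
        cfg = TrainConfig(depth=2, patch_size=20, patches_per_image=3, augment=True)
        pool = build_patch_pool([img], cfg)
        assert pool.Y.shape[0] == 3 * 8
        cfg_plain = TrainConfig(
            depth=2, patch_size=20, patches_per_image=3, augment=False
        )
        assert build_patch_pool([img], cfg_plain).Y.shape[0] == 3


class TestResidualLoss:
    def test_zero_when_residual_equals_truth_minus_base(self, rng):
        x = rng.uniform(0, 1, (2, 8, 8, 3))
        y = rng.uniform(0, 1, (2, 8, 8, 3))
        assert residual_loss(x - y, y, x) == pytest.approx(0.0, abs=1e-24)

    def test_zero_for_zero_residual_and_exact_base(self, rng):
        x = rng.uniform(0, 1, (2, 8, 8, 3))
        assert residual_loss(np.zeros_like(x), x, x) == 0.0

    def test_matches_scalar_loop_oracle(self, rng):
        res = rng.normal(0, 0.1, (2, 3, 3, 3))
        y = rng.uniform(0, 1, (2, 3, 3, 3))
        x = rng.uniform(0, 1, (2, 3, 3, 3))
        expected = 0.0
        for b in range(2):
            for r in range(3):
                for c in range(3):
                    for ch in range(3):
                        e = res[b, r, c, ch] + y[b, r, c, ch] - x[b, r, c, ch]
                        expected += e * e
        expected /= 2
        assert residual_loss(res, y, x) == pytest.approx(expected, rel=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            residual_loss(np.zeros((2, 4, 4, 3)), np.zeros((2, 4, 4, 3)),
                          np.zeros((2, 4, 5, 3)))

    def test_nonnegative(self, rng):
        for _ in range(5):
            args = [rng.normal(0, 1, (1, 4, 4, 3)) for _ in range(3)]
            assert residual_loss(*args) >= 0.0


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradient vs. central differences on a tiny float64 net."""
        rng = np.random.default_rng(0)
        model = ResidualModel.initialize(
            NetworkConfig(depth=3, filters=3), seed=0, dtype=np.float64
        )
        y = rng.uniform(0, 1, (2, 6, 6, 3))
        x = np.clip(y + rng.normal(0, 0.05, y.shape), 0, 1)

        def loss_at():
            res = model.forward(y, training=True)
            return residual_loss(res, y, x)

        res, caches = model.forward(y, training=True, want_cache=True)
        d_res = (2.0 / y.shape[0]) * (res + y - x)
        grads = model.backward(d_res, caches)

        eps = 1e-6
        checked = 0
        for li, layer in enumerate(model.layers):
            for key in ("W", "b", "gamma", "beta"):
                if key not in layer:
                    continue
                flat = layer[key].reshape(-1)
                for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = loss_at()
                    flat[idx] = orig - eps
                    lm = loss_at()
                    flat[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    an = grads[li][key].reshape(-1)[idx]
                    if max(abs(fd), abs(an)) < 1e-6:
                        # structurally zero gradient (e.g. conv bias cancelled
                        # by batch-norm mean subtraction): below FD noise floor
                        checked += 1
                        continue
                    denom = max(abs(fd), abs(an))
                    assert abs(fd - an) / denom < 1e-4, (li, key, idx, fd, an)
                    checked += 1
        assert checked >= 20


class TestTrainLoop:
    def test_loss_trend_non_increasing_on_constant_image(self):
        img = np.full((60, 60, 3), 0.5)
        cfg = TrainConfig(
            depth=2, filters=4, patch_size=16, patches_per_image=4,
            augment=False, batch_size=4, steps=50, seed=0,
            learning_rate=1e-3,
        )
        _, log = train([img], cfg)
        losses = np.array([e["loss"] for e in log])
        ma = np.convolve(losses, np.ones(10) / 10, mode="valid")
        assert ma[-1] <= ma[0]

    def test_fixed_seed_run_reproducible(self, rng):
        img = rng.uniform(0, 1, (60, 60, 3))
        cfg = TrainConfig(
            depth=2, filters=4, patch_size=16, patches_per_image=4,
            augment=False, batch_size=4, steps=20, seed=3, learning_rate=1e-3,
        )
        _, log_a = train([img], cfg)
        _, log_b = train([img], cfg)
        assert log_a[-1]["loss"] == log_b[-1]["loss"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig(depth=2))

    def test_nan_input_aborts_with_diagnostic(self, rng):
        y = rng.uniform(0, 1, (8, 8, 8, 3)).astype(np.float32)
        x = y.copy()
        y[0, 0, 0, 0] = np.nan
        pool = PatchBatch(Y=y, X=x, Y_hat=y)
        cfg = TrainConfig(depth=2, filters=4, patch_size=8, batch_size=8, steps=5)
        with pytest.raises(RuntimeError, match="diverged"):
            train_on_patches(pool, cfg)

    def test_recovers_linear_filter_target(self, rng):
        """When truth = bilinear + fixed linear filter response, a depth-2
        model should drive the loss down by orders of magnitude."""
        kernel = np.zeros((3, 3, 3, 3))
        for ch in range(3):
            kernel[1, 0, ch, ch] = 0.05
            kernel[1, 2, ch, ch] = -0.05
        ys, xs = [], []
        for i in range(8):
            base = rng.uniform(0.2, 0.8, (16, 16, 3))
            y, _ = simulate_pair(base)
            x = y + conv2d(y[None], kernel, np.zeros(3))[0]
            ys.append(y)
            xs.append(np.clip(x, 0, 1))
        y_arr = np.stack(ys).astype(np.float32)
        x_arr = np.stack(xs).astype(np.float32)
        pool = PatchBatch(Y=y_arr, X=x_arr, Y_hat=y_arr)
        cfg = TrainConfig(
            depth=2, filters=8, patch_size=16, batch_size=8, steps=400,
            learning_rate=3e-3, seed=1, zero_init_final=True,
        )
        model, log = train_on_patches(pool, cfg)
        res = model.forward(y_arr.astype(np.float64))
        final = residual_loss(res, y_arr, x_arr)
        initial = residual_loss(np.zeros_like(y_arr), y_arr, x_arr)
        assert final < initial / 20
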