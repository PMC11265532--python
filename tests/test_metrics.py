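import numpy as np
import pytest

from hexademosaic import (
    MultispectralImage,
    delta_e_p95,
    dssim_p95,
    evaluate,
    frequency_compare,
    mse,
    psnr,
)
from hexademosaic.metrics import dssim_map


class TestMse:
    def test_identical_images_zero(self, rng):
        a = rng.uniform(0, 1, (8, 8, 3))
        assert np.all(mse(a, a) == 0)

    def test_constant_offset_closed_form(self):
        a = np.full((10, 10, 3), 0.4)
        assert np.allclose(mse(a, a + 0.2), 0.04)

    def test_matches_double_loop_oracle(self, rng):
        a = rng.uniform(0, 1, (8, 8, 3))
        b = rng.uniform(0, 1, (8, 8, 3))
        expected = np.zeros(3)
        for r in range(8):
            for c in range(8):
                for ch in range(3):
                    expected[ch] += (a[r, c, ch] - b[r, c, ch]) ** 2
        expected /= 64
        assert np.allclose(mse(a, b), expected, rtol=1e-12)

    def test_symmetric(self, rng):
        a, b = rng.uniform(0, 1, (2, 6, 6, 3))
        assert np.array_equal(mse(a, b), mse(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros((4, 4)), np.zeros((4, 5)))


class TestPsnr:
    def test_identical_images_infinite(self, rng):
        a = rng.uniform(0, 1, (6, 6))
        assert psnr(a, a) == np.inf

    @pytest.mark.parametrize("err,expected", [(0.1, 20.0), (0.01, 40.0)])
    def test_uniform_error_closed_form(self, err, expected):
        a = np.full((16, 16), 0.5)
        assert psnr(a, a + err, peak=1.0) == pytest.approx(expected, abs=1e-9)

    def test_psnr_mse_identity(self, rng):
        a = rng.uniform(0, 1, (8, 8, 3))
        b = rng.uniform(0, 1, (8, 8, 3))
        assert np.allclose(
            psnr(a, b), 10 * np.log10(1.0 / np.asarray(mse(a, b))), atol=1e-9
        )

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((4, 4)), peak=0)


class TestDssim:
    def test_identical_images_zero(self, rng):
        a = rng.uniform(0, 1, (24, 24, 3))
        assert dssim_p95(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_inverted_structured_image_near_one(self, rng):
        # binary block pattern: inversion destroys structure everywhere
        blocks = (rng.uniform(0, 1, (4, 4)) > 0.5).astype(float)
        a = np.kron(blocks, np.ones((8, 8)))
        assert dssim_p95(a, 1.0 - a) > 0.9

    def test_p95_at_least_median(self, rng):
        a = rng.uniform(0, 1, (24, 24))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        m = dssim_map(a, b)
        assert np.percentile(m, 95) >= np.median(m)

    def test_symmetric(self, rng):
        a = rng.uniform(0, 1, (20, 20))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        assert dssim_p95(a, b) == pytest.approx(dssim_p95(b, a), abs=1e-12)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            dssim_p95(np.zeros((6, 6)), np.ones((6, 6)))


class TestDeltaE:
    def test_identical_images_zero(self, rng):
        a = rng.uniform(0, 1, (8, 8, 3))
        assert delta_e_p95(a, a) == 0.0

    def test_zeros_vs_ones_is_100_percent(self):
        assert delta_e_p95(np.zeros((8, 8, 3)), np.ones((8, 8, 3))) == pytest.approx(
            100.0
        )

    def test_matches_per_pixel_loop_oracle(self, rng):
        a = rng.uniform(0, 1, (6, 6, 3))
        b = rng.uniform(0, 1, (6, 6, 3))
        dist = np.empty((6, 6))
        for r in range(6):
            for c in range(6):
                dist[r, c] = np.sqrt(np.sum((a[r, c] - b[r, c]) ** 2))
        expected = np.percentile(100 * dist / np.sqrt(3), 95)
        assert delta_e_p95(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetric(self, rng):
        a, b = rng.uniform(0, 1, (2, 6, 6, 3))
        assert delta_e_p95(a, b) == delta_e_p95(b, a)

    def test_cie76_variant_zero_for_identical(self, rng):
        a = rng.uniform(0, 1, (8, 8, 3))
        assert delta_e_p95(a, a, method="cie76") == 0.0

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            delta_e_p95(np.zeros((4, 4)), np.zeros((4, 4)))


class TestDegradationMonotonicity:
    def test_noise_amplitude_orders_metrics(self, rng):
        base = rng.uniform(0.2, 0.8, (32, 32, 3))
        noise = rng.normal(0, 1, base.shape)
        mses, des, dssims = [], [], []
        for amp in (0.02, 0.06, 0.15):
            noisy = np.clip(base + amp * noise, 0, 1)
            mses.append(float(np.mean(mse(base, noisy))))
            des.append(delta_e_p95(base, noisy))
            dssims.append(dssim_p95(base, noisy))
        assert mses[0] < mses[1] < mses[2]
        assert des[0] < des[1] < des[2]
        assert dssims[0] <= dssims[1] <= dssims[2]


class TestFrequencyCompare:
    def test_identical_images_zero_difference(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        prof = frequency_compare(a, a)
        assert np.all(prof.difference_profile == 0.0)

    def test_real_input_spectrum_symmetric(self, rng):
        a = rng.uniform(0, 1, (33, 33))  # odd size: exact point symmetry
        prof = frequency_compare(a, a)
        assert np.allclose(prof.spectrum, prof.spectrum[::-1, ::-1], atol=1e-6)

    def test_blurred_sinusoid_deficit_at_stripe_frequency(self):
        h = w = 64
        f = 12
        rr = np.arange(h)[:, None] * np.ones((1, w))
        stripes = 0.5 + 0.4 * np.sin(2 * np.pi * f * rr / h)
        kernel = np.array([0.25, 0.5, 0.25])
        blurred = np.apply_along_axis(
            lambda col: np.convolve(np.pad(col, 1, mode="wrap"), kernel, "valid"),
            0,
            stripes,
        )
        prof = frequency_compare(blurred, stripes)
        diff = np.abs(prof.difference_profile.copy())
        center = h // 2
        diff[center] = 0.0  # ignore DC
        peaks = set(np.argsort(diff)[-2:])
        assert peaks == {center - f, center + f}

    def test_high_frequency_deficit_selects_top_quartile(self):
        prof = frequency_compare(np.zeros((16, 16)) + 0.5, np.full((16, 16), 0.5))
        assert prof.high_frequency_deficit(0.25) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frequency_compare(np.zeros((8, 8)), np.zeros((8, 9)))


class TestEvaluate:
    def test_perfect_reconstruction_all_zero(self, rng):
        img = MultispectralImage(data=rng.uniform(0, 1, (24, 24, 6)))
        report = evaluate(img, img)
        assert all(v == 0.0 for v in report.mse.values())
        assert all(v == np.inf for v in report.psnr.values())
        assert report.p95_dssim_vis == pytest.approx(0.0, abs=1e-12)
        assert report.p95_delta_e_vis == 0.0
        assert report.p95_delta_e_nir == 0.0

    def test_report_satisfies_psnr_mse_identity(self, rng):
        a = MultispectralImage(data=rng.uniform(0, 1, (24, 24, 6)))
        b = MultispectralImage(
            data=np.clip(a.data + rng.normal(0, 0.05, a.data.shape), 0, 1)
        )
        report = evaluate(a, b)
        for name in report.psnr:
            assert report.psnr[name] == pytest.approx(
                10 * np.log10(1.0 / report.mse[name]), abs=1e-9
            )

    def test_serialization_schema(self, tmp_path, rng):
        import json

        a = MultispectralImage(data=rng.uniform(0, 1, (24, 24, 6)))
        b = MultispectralImage(
            data=np.clip(a.data + rng.normal(0, 0.02, a.data.shape), 0, 1)
        )
        report = evaluate(a, b)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert set(loaded) == {"psnr_db", "mse", "p95_dssim", "p95_delta_e_pct"}
        assert set(loaded["psnr_db"]) == {
            "vis_r", "vis_g", "vis_b", "nir_1", "nir_2", "nir_3"
        }
        report.to_csv(tmp_path / "report.csv")
        lines = (tmp_path / "report.csv").read_text().strip().splitlines()
        assert lines[0] == "metric,channel,value"
        assert len(lines) == 1 + 6 + 6 + 4
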