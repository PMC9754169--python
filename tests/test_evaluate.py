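"""Metrics, improvement arithmetic, significance tests, mu rule, reports."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from ctdense import (mae, ssim_per_slice, improvement_pct, significance_test,
                     select_m, tabulate, build_report, MSelectionRule)


class TestMae:
    def test_identical_is_zero(self, rng):
        x = rng.random((3, 8, 8))
        assert mae(x, x) == 0.0

    def test_constant_offset_in_hu(self):
        x = np.zeros((4, 4))
        # 5 HU offset = 0.0025 on the [0,1] scale of a 2000-HU window
        assert mae(x + 0.0025, x) == pytest.approx(5.0)

    def test_matches_brute_force_loop(self, rng):
        pred = rng.random((8, 8))
        true = rng.random((8, 8))
        total = 0.0
        for i in range(8):
            for j in range(8):
                total += abs(pred[i, j] - true[i, j])
        assert mae(pred, true, hu_window=None) == pytest.approx(total / 64, rel=1e-12)

    def test_masked(self, rng):
        pred = np.zeros((4, 4))
        true = np.zeros((4, 4))
        true[0, 0] = 0.5
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        assert mae(pred, true, mask=mask, hu_window=None) == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            mae(np.zeros((4, 4)), np.zeros((4, 4)), mask=np.zeros((4, 4), bool))


def _reference_ssim_gaussian(a, b, win_size=7, sigma=1.5):
    """Independent SSIM: direct Gaussian-window formulation via scipy."""
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    # per-slice min-max normalization, as the protocol prescribes
    a = (a - a.min()) / (a.max() - a.min())
    b = (b - b.min()) / (b.max() - b.min())
    c1, c2 = (0.01 * 1.0) ** 2, (0.03 * 1.0) ** 2
    # Gaussian window truncated at 3.5 sigma; win_size sets the border crop
    f = lambda x: gaussian_filter(x, sigma, truncate=3.5, mode="reflect")
    mu_a, mu_b = f(a), f(b)
    saa = f(a * a) - mu_a ** 2
    sbb = f(b * b) - mu_b ** 2
    sab = f(a * b) - mu_a * mu_b
    smap = ((2 * mu_a * mu_b + c1) * (2 * sab + c2)) / \
        ((mu_a ** 2 + mu_b ** 2 + c1) * (saa + sbb + c2))
    pad = (win_size - 1) // 2
    return smap[pad:-pad, pad:-pad].mean()


class TestSsim:
    def test_identical_slices(self, rng):
        x = rng.random((16, 16))
        assert ssim_per_slice(x, x) == pytest.approx(1.0)

    def test_negated_slice_below_one(self, rng):
        x = rng.random((16, 16))
        assert ssim_per_slice(x, 1 - x) < 1.0

    def test_matches_independent_reference(self, rng):
        a = rng.random((16, 16))
        b = np.clip(a + rng.normal(0, 0.1, (16, 16)), 0, 1)
        ours = ssim_per_slice(a, b, win_size=7)
        ref = _reference_ssim_gaussian(a, b, win_size=7)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_constant_slice_fallback(self):
        c = np.full((12, 12), 0.3)
        assert ssim_per_slice(c, c) == pytest.approx(1.0)

    def test_masked_average(self, rng):
        a = rng.random((16, 16))
        b = np.clip(a + rng.normal(0, 0.05, (16, 16)), 0, 1)
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        full = ssim_per_slice(a, b)
        masked = ssim_per_slice(a, b, mask=mask)
        assert -1.0 <= masked <= 1.0
        assert masked != pytest.approx(full)


class TestImprovement:
    def test_headline_error_improvement(self):
        assert improvement_pct(23.13, 18.03) == pytest.approx(22.05, abs=0.005)

    def test_organ_error_improvement(self):
        assert improvement_pct(14.25, 10.91) == pytest.approx(23.44, abs=0.005)

    def test_no_change_is_zero(self):
        assert improvement_pct(10, 10) == 0.0

    def test_similarity_direction(self):
        assert improvement_pct(0.866, 0.885, metric="similarity") == \
            pytest.approx(2.19, abs=0.005)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            improvement_pct(0.0, 1.0)


class TestSignificance:
    def test_identical_samples_degenerate(self):
        x = np.arange(20.0)
        res = significance_test(x, x)
        assert res.degenerate and res.p_value == 1.0 and res.favors == "tie"

    def test_constant_shift_detected(self, rng):
        a = rng.random(100)
        res = significance_test(a, a + 0.5)
        assert res.p_value < 0.01
        assert res.favors == "A"

    def test_null_calibration(self):
        """Under exchangeable pairs, small p-values stay near nominal rate."""
        rng = np.random.default_rng(99)
        pvals = [significance_test(rng.normal(size=30), rng.normal(size=30)).p_value
                 for _ in range(60)]
        assert np.mean(np.asarray(pvals) < 0.05) < 0.2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            significance_test(np.zeros(3), np.zeros(4))


class TestSelectM:
    def test_stops_before_threshold_exceeded(self):
        table = [(1, 5.0), (2, 12.0), (3, 20.0)]
        assert select_m(table, MSelectionRule(mu=15.0)) == 2

    def test_single_entry(self):
        assert select_m([(1, 5.0)], MSelectionRule(mu=5.0)) == 1

    def test_all_exceed_returns_smallest_with_warning(self):
        with pytest.warns(UserWarning):
            chosen = select_m([(1, 20.0), (2, 30.0)], MSelectionRule(mu=15.0))
        assert chosen == 1

    def test_empty_table(self):
        with pytest.raises(ValueError):
            select_m([], MSelectionRule(mu=1.0))


class TestTabulate:
    def test_average_recomputes_from_cells(self):
        df = tabulate({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0]})
        assert df.loc["a", "Average"] == pytest.approx(2.0)
        assert df.loc["Improvement (b vs. a)", "Average"] == pytest.approx(0.0)

    def test_improvement_row_cellwise(self):
        df = tabulate({"ref": [10.0, 20.0], "new": [5.0, 20.0]})
        row = df.loc["Improvement (new vs. ref)"]
        assert row["Slice 1"] == pytest.approx(50.0)
        assert row["Slice 2"] == pytest.approx(0.0)

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            tabulate({"a": [1.0, 2.0], "b": [1.0]})


class TestBuildReport:
    def _data(self, rng):
        truth = rng.random((6, 3, 12, 12)).astype(np.float32)
        noisy = np.clip(truth + rng.normal(0, 0.02, truth.shape), 0, 1)
        return truth, {"exact": truth.copy(), "noisy": noisy.astype(np.float32)}

    def test_identical_prediction_scores_perfectly(self, rng):
        truth, preds = self._data(rng)
        report = build_report({"exact": preds["exact"]}, truth)
        assert report.per_position_mae.loc["exact"].max() == 0.0
        assert report.per_position_ssim.loc["exact", "Average"] == pytest.approx(1.0)

    def test_averages_and_pvalues_consistent(self, rng):
        truth, preds = self._data(rng)
        mask = np.zeros(truth.shape, bool)
        mask[:, :, 3:9, 3:9] = True
        report = build_report(preds, truth, organ_masks={"liver": mask})
        df = report.per_position_mae
        for method in ("exact", "noisy"):
            cells = df.loc[method, [c for c in df.columns if c != "Average"]]
            assert df.loc[method, "Average"] == pytest.approx(cells.mean())
        assert "liver" in report.per_organ_mae
        assert report.p_values.loc["exact vs. noisy", "p_value"] < 0.05

    def test_shape_mismatch_rejected(self, rng):
        truth, preds = self._data(rng)
        with pytest.raises(ValueError, match="shape"):
            build_report({"bad": preds["exact"][:, :2]}, truth)

    def test_csv_and_json_outputs(self, tmp_path, rng):
        truth, preds = self._data(rng)
        report = build_report(preds, truth)
        report.to_csv(tmp_path)
        assert (tmp_path / "mae.csv").exists()
        assert (tmp_path / "ssim.csv").exists()
        assert "mae" in report.to_json()
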