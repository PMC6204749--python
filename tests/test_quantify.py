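import dataclasses
import json

import numpy as np
import pytest

from uripad import (
    InputError,
    TemperatureModel,
    eliminate_outliers,
    estimate_concentration,
    gen_spot_image,
    make_remark,
    mean_gray,
    predict_gray,
    quantify_image,
)


def tukey_oracle(values):
    """Independent quartile/fence computation: sorted array + manual interpolation."""
    vals = sorted(float(v) for v in values)
    n = len(vals)

    def quantile(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return vals[lo] + (h - lo) * (vals[hi] - vals[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    kept = [v for v in vals if q1 - 1.5 * iqr <= v <= q3 + 1.5 * iqr]
    return kept, n - len(kept)


class TestEliminateOutliers:
    def test_single_extreme_value_removed(self):
        kept, n_removed = eliminate_outliers(np.array([100.0, 101.0, 99.0, 100.0, 250.0]))
        assert n_removed == 1
        assert sorted(kept.tolist()) == [99.0, 100.0, 100.0, 101.0]
        oracle_kept, oracle_removed = tukey_oracle([100, 101, 99, 100, 250])
        assert (sorted(kept.tolist()), n_removed) == (oracle_kept, oracle_removed)

    def test_constant_vector_untouched(self):
        kept, n_removed = eliminate_outliers(np.full(5, 50.0))
        assert n_removed == 0
        assert kept.size == 5

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError, match="too few"):
            eliminate_outliers(np.array([1.0, 2.0, 3.0, 4.0]))

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            vals = rng.normal(100, 10, n)
            if rng.random() < 0.5:  # sprinkle gross outliers
                vals[rng.integers(0, n)] += rng.choice([-1, 1]) * rng.uniform(50, 200)
            kept, n_removed = eliminate_outliers(vals)
            oracle_kept, oracle_removed = tukey_oracle(vals)
            assert n_removed == oracle_removed
            np.testing.assert_allclose(np.sort(kept), oracle_kept, rtol=0, atol=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_injected_outlier_fraction_recovered(self, truth, seed):
        rng = np.random.default_rng(seed)
        n = 5000
        vals = rng.normal(100, truth.pixel_sd, n)
        n_inject = n // 50  # 2%
        vals[rng.choice(n, n_inject, replace=False)] += truth.outlier_shift
        _, n_removed = eliminate_outliers(vals)
        assert 0.01 <= n_removed / n <= 0.03

    @pytest.mark.parametrize("seed", range(20))
    def test_idempotent_on_spot_pixel_data(self, truth, seed):
        """One pass suffices on real spot pixels: fences recomputed on the
        screened, unimodal data retain everything that survived."""
        image = gen_spot_image(250.0, truth, seed=seed)
        cmy = 255.0 - image[..., 0].astype(float)
        vals = cmy[cmy > 10]  # disc pixels
        kept, _ = eliminate_outliers(vals)
        kept2, n2 = eliminate_outliers(kept)
        assert n2 == 0
        np.testing.assert_array_equal(kept, kept2)


class TestMeanGray:
    def test_arithmetic_mean_and_identity(self):
        assert mean_gray(np.array([100.0, 102.0, 104.0])) == 102.0
        assert mean_gray(np.array([77.5])) == 77.5

    def test_empty_vector_rejected(self):
        with pytest.raises(InputError, match="empty"):
            mean_gray(np.array([]))

    @pytest.mark.parametrize("seed", range(10))
    def test_spot_mean_within_standard_error(self, truth, seed):
        rng = np.random.default_rng(seed)
        truth_gray = 90.0
        vals = rng.normal(truth_gray, truth.pixel_sd, 5000)
        se = truth.pixel_sd / np.sqrt(5000)
        assert abs(mean_gray(vals) - truth_gray) <= 3 * se


class TestEstimateConcentration:
    def test_baseline_gray_gives_zero_ppm(self, exact_curve):
        est = estimate_concentration(exact_curve.G0, exact_curve)
        assert est.ppm == 0.0
        assert est.censored == "none"

    def test_saturated_gray_censored_with_dilution_scaling(self, exact_curve):
        gray = exact_curve.G0 + 0.95 * exact_curve.span
        est = estimate_concentration(gray, exact_curve, dilution_factor=3.0)
        assert est.censored == "above_saturation"
        assert est.ppm == pytest.approx(3.0 * exact_curve.C_sat95)

    def test_round_trip_with_dilution(self, exact_curve):
        gray = predict_gray(exact_curve, 200.0)
        est = estimate_concentration(gray, exact_curve, dilution_factor=2.0)
        assert est.ppm == pytest.approx(400.0, rel=1e-9)

    def test_monotone_in_gray_up_to_censoring(self, fitted_curve):
        grays = np.linspace(fitted_curve.G0, fitted_curve.G0 + 0.949 * fitted_curve.span, 80)
        ppms = [estimate_concentration(g, fitted_curve).ppm for g in grays]
        assert np.all(np.diff(ppms) >= 0)

    def test_temperature_correction_applied(self, exact_curve):
        model = TemperatureModel(slope=0.56, intercept=68.0, reference_temp=25.0, r_squared=1.0)
        gray_25 = predict_gray(exact_curve, 150.0)
        gray_50 = gray_25 + 0.56 * 25.0  # same spot photographed warm
        est = estimate_concentration(
            gray_50, exact_curve, temperature_c=50.0, temp_model=model
        )
        assert est.ppm == pytest.approx(2.0 * 150.0, rel=1e-6)

    def test_signal_below_blank_rejected(self, fitted_curve):
        with pytest.raises(InputError, match="below blank"):
            estimate_concentration(fitted_curve.G0 - 5.0, fitted_curve)

    def test_missing_curve_rejected(self):
        with pytest.raises(InputError, match="calibration"):
            estimate_concentration(100.0, None)


class TestMakeRemark:
    @pytest.mark.parametrize(
        "ppm, label",
        [
            (0.0, "below_range"),
            (299.9, "below_range"),
            (300.0, "within_acceptable_limit"),
            (550.0, "within_acceptable_limit"),
            (700.0, "within_acceptable_limit"),
            (701.0, "above_acceptable_limit"),
        ],
    )
    def test_breakpoints(self, ppm, label):
        assert make_remark(ppm) == label

    def test_published_trial_values_all_within_limit(self):
        for ppm in (550.0, 558.0, 442.0, 553.0, 595.0, 315.0):
            assert make_remark(ppm) == "within_acceptable_limit"

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            make_remark(-1.0)


class TestQuantifyImage:
    def test_recovers_truth_with_dilution(self, truth, fitted_curve, spot_file):
        path = spot_file(100.0, truth, seed=4)
        result = quantify_image(path, fitted_curve)
        assert result.estimate.ppm == pytest.approx(200.0, rel=0.10)
        assert result.estimate.censored == "none"
        assert result.n_outliers_removed < result.n_pixels_total

    def test_blank_spot_reads_zero_and_below_range(self, noiseless_truth, exact_curve, spot_file):
        path = spot_file(0.0, noiseless_truth, seed=0)
        result = quantify_image(path, exact_curve)
        assert result.estimate.ppm == 0.0
        assert result.remark == "below_range"

    def test_beyond_saturation_censored(self, truth, fitted_curve, spot_file):
        path = spot_file(600.0, truth, seed=5)
        result = quantify_image(path, fitted_curve)
        assert result.estimate.censored == "above_saturation"
        assert result.estimate.ppm == pytest.approx(2.0 * fitted_curve.C_sat95)

    def test_json_report_keys(self, truth, fitted_curve, spot_file):
        result = quantify_image(spot_file(200.0, truth, seed=6), fitted_curve)
        payload = json.loads(result.to_json())
        assert set(payload) == {
            "mean_gray_cmy", "n_pixels_total", "n_outliers_removed", "ppm",
            "half_width", "censored", "remark", "dilution_factor", "temperature_c",
        }

    def test_end_to_end_median_relative_error(self, truth, fitted_curve, spot_file):
        errors = []
        for conc in (50.0, 100.0, 200.0, 300.0, 400.0):
            for seed in range(10):
                path = spot_file(conc, truth, seed=seed, name=f"{conc}_{seed}.png")
                result = quantify_image(path, fitted_curve)
                errors.append(abs(result.estimate.ppm / 2.0 - conc) / conc)
        assert np.median(errors) <= 0.10

    def test_outlier_pixels_barely_move_the_estimate(self, truth, fitted_curve, spot_file):
        clean_truth = dataclasses.replace(truth, outlier_fraction=0.0)
        for seed in range(5):
            dirty = quantify_image(
                spot_file(200.0, truth, seed=seed, name=f"d{seed}.png"), fitted_curve
            )
            clean = quantify_image(
                spot_file(200.0, clean_truth, seed=seed, name=f"c{seed}.png"), fitted_curve
            )
            assert abs(dirty.estimate.ppm - clean.estimate.ppm) / clean.estimate.ppm < 0.02
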