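import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import techvar as tv


class TestBlandAltman:
    def test_identical_inputs_have_zero_limits(self):
        ba = tv.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], scale="raw")
        assert ba.mean_diff == 0.0
        assert ba.loa_low == ba.loa_high == 0.0

    def test_antisymmetric_in_inputs(self):
        a = np.array([1.0, 4.0, 9.0, 2.0])
        b = np.array([2.0, 3.0, 8.0, 5.0])
        fwd = tv.bland_altman(a, b, scale="raw")
        rev = tv.bland_altman(b, a, scale="raw")
        assert fwd.mean_diff == pytest.approx(-rev.mean_diff)
        assert np.allclose(fwd.pairs.difference, -rev.pairs.difference)
        assert np.allclose(fwd.pairs.average, rev.pairs.average)

    def test_natural_log_hand_example(self):
        # log pairs: (1,1) and (3,1) -> diffs (0, 2)
        ba = tv.bland_altman(
            [math.e, math.e**3], [math.e, math.e], scale="natural_log"
        )
        assert ba.mean_diff == pytest.approx(1.0)
        assert ba.sd_diff == pytest.approx(math.sqrt(2))
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd_diff)

    def test_log_scale_excludes_zero_pairs(self):
        ba = tv.bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 2.0])
        assert ba.n_used == 2
        assert ba.n_excluded_zero == 1

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            tv.bland_altman([0.0, 1.0], [1.0, 1.0], scale="natural_log")

    def test_limits_capture_95_percent_of_normal_differences(self):
        rng = np.random.default_rng(17)
        a = rng.normal(10, 1, 10_000)
        b = a + rng.normal(0, 0.5, 10_000)
        ba = tv.bland_altman(a, b, scale="raw")
        diffs = ba.pairs.difference
        inside = ((diffs >= ba.loa_low) & (diffs <= ba.loa_high)).mean()
        assert inside == pytest.approx(0.95, abs=0.02)


class TestCorrelations:
    def test_doubling_preserves_both(self):
        a = np.array([1.0, 3.0, 2.0, 8.0])
        pearson, spearman = tv.correlations(a, 2 * a)
        assert spearman == pytest.approx(1.0)
        assert pearson == pytest.approx(1.0)

    def test_reversed_order(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        _, spearman = tv.correlations(a, a[::-1])
        assert spearman == pytest.approx(-1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 10, 50)
        b = rng.uniform(0.1, 10, 50)
        base = tv.correlations(a, b)[1]
        assert tv.correlations(2 * a, b)[1] == pytest.approx(base)
        assert tv.correlations(a, b**3)[1] == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tv.correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCvProfile:
    def test_excludes_undefined_cv_and_flags_display(self):
        quants = pd.DataFrame(
            {
                "region_id": ["r1", "r2", "r3"],
                "apn": [0.0, 2.0, 2000.0],
                "cv": [np.nan, 0.5, 0.1],
            }
        )
        prof = tv.cv_profile(quants)
        assert set(prof.region_id) == {"r2", "r3"}
        assert prof.set_index("region_id").display.to_dict() == {
            "r2": True,
            "r3": False,
        }

    def test_constant_depth_contributes_zero_cv(self, small_experiment):
        quants = small_experiment["quants"]
        prof = tv.cv_profile(quants[quants.lane_id == "rep1"])
        assert (prof.cv >= 0).all()
        assert (prof.apn > 0).all()

    def test_smoother_is_deterministic(self, small_experiment):
        quants = small_experiment["quants"]
        lane = quants[quants.lane_id == "rep1"]
        p1 = tv.cv_profile(lane)
        p2 = tv.cv_profile(lane)
        pd.testing.assert_frame_equal(p1, p2)


def _nll(beta, design, y):
    eta = np.clip(design @ beta, -500, 500)
    return float(np.sum(np.log1p(np.exp(eta)) - y * eta))


class TestLogisticIrls:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        design = np.ones((100, 1))
        beta, se, _, converged, _ = tv.logistic_irls(design, y)
        assert converged
        assert beta[0] == pytest.approx(math.log(0.25 / 0.75), abs=1e-8)

    def test_matches_generic_optimizer(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 300
            design = np.column_stack(
                [np.ones(n), rng.normal(size=n), rng.normal(size=n)]
            )
            truth = rng.normal(size=3)
            p = 1 / (1 + np.exp(-design @ truth))
            y = (rng.random(n) < p).astype(float)
            beta, _, _, converged, _ = tv.logistic_irls(design, y)
            assert converged
            res = optimize.minimize(
                _nll, np.zeros(3), args=(design, y), method="BFGS",
                options={"gtol": 1e-10},
            )
            assert np.allclose(beta, res.x, atol=1e-5)

    def test_separation_raises(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(float)
        design = np.column_stack([np.ones_like(x), x])
        with pytest.raises(ValueError, match="separation"):
            tv.logistic_irls(design, y)

    def test_singular_design_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        design = np.column_stack([np.ones_like(x), x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValueError, match="singular"):
            tv.logistic_irls(design, y)


class TestFitDetectionLogistic:
    def test_constant_response_rejected(self):
        records = pd.DataFrame(
            {"y": [0] * 20, "abundance": range(20), "length": range(20)}
        )
        with pytest.raises(ValueError, match="constant"):
            tv.fit_detection_logistic(records)

    def test_needs_enough_regions(self):
        records = pd.DataFrame(
            {"y": [0, 1] * 3, "abundance": range(6), "length": range(6)}
        )
        with pytest.raises(ValueError):
            tv.fit_detection_logistic(records)

    def test_recovers_known_coefficients(self):
        truth = np.array([0.5, -0.25, 0.004, -0.0136])
        rng = np.random.default_rng(101)
        n = 5000
        a = rng.uniform(0, 3, n)
        l = rng.uniform(20, 120, n)
        design = np.column_stack([np.ones(n), a, l, a * l])
        p = 1 / (1 + np.exp(-design @ truth))
        y = (rng.random(n) < p).astype(int)
        fit = tv.fit_detection_logistic(
            pd.DataFrame({"y": y, "abundance": a, "length": l})
        )
        assert fit.converged
        assert np.all(
            np.abs(fit.coefficients - truth) <= 3 * fit.standard_errors
        )

    def test_matches_statsmodels(self):
        smf = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        n = 2000
        a = rng.uniform(0, 3, n)
        l = rng.uniform(20, 120, n)
        eta = 0.3 - 0.2 * a + 0.002 * l - 0.005 * a * l
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = tv.fit_detection_logistic(
            pd.DataFrame({"y": y, "abundance": a, "length": l})
        )
        design = np.column_stack([np.ones(n), a, l, a * l])
        sm_fit = smf.Logit(y, design).fit(disp=0)
        assert np.allclose(fit.coefficients, sm_fit.params, atol=1e-6)
        assert np.allclose(fit.standard_errors, sm_fit.bse, atol=1e-5)


class TestCoveragePresenceMatrix:
    def test_structure(self, small_experiment):
        quants = small_experiment["quants"]
        mat = tv.coverage_presence_matrix(quants)
        assert len(mat) == quants.region_id.nunique()
        # buckets partition the regions 0..9
        assert set(mat.length_percentile_bucket) <= set(range(10))
        counts = mat.length_percentile_bucket.value_counts()
        assert counts.max() - counts.min() <= 1
        # sorted by length, stable
        assert (mat.length.diff().dropna() >= 0).all()

    def test_fully_detected_region_is_all_true(self, small_experiment):
        quants = small_experiment["quants"]
        mat = tv.coverage_presence_matrix(quants).set_index("region_id")
        det_cols = [c for c in mat.columns if c.startswith("detected_")]
        always = quants.groupby("region_id").detected.all()
        region = always[always].index[0]
        assert mat.loc[region, det_cols].all()
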