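import numpy as np
import pandas as pd
import pytest

from nlsempower import (
    ParameterRef,
    build_product_indicators,
    fit_fsr,
    fit_qisem,
    fit_sr,
    fit_upi,
    moderated_mediation_model,
    moderation_model,
    parse_model,
    simulate_dataset,
)
from nlsempower.estimators import product_indicator_pairs
from nlsempower.model_syntax import Term
from nlsempower.simulate import Sample

POI = ParameterRef.parse("Eta2~Eta1:Xi1")

STRUCTURAL_TRUTH = {
    "Eta1~Xi1": 0.2, "Eta1~Xi2": 0.5,
    "Eta2~Eta1": 0.2, "Eta2~Eta1:Xi1": 0.1, "Eta2~Xi1": 0.2,
    "Eta2~Xi2": 0.3, "Eta2~Xi1:Xi2": 0.1,
}


class TestScaleRegression:
    def test_consistent_under_perfect_measurement(self, perfect_spec):
        s = simulate_dataset(perfect_spec, 60_000, seed=21)
        fit = fit_sr(s, perfect_spec)
        assert fit.converged
        for key, truth in STRUCTURAL_TRUTH.items():
            est, se = fit.estimates[key], fit.standard_errors[key]
            assert abs(est - truth) < 3.5 * se, key

    def test_attenuation_with_fallible_indicators(self, study2_spec):
        """The product-term estimate is systematically below .1 when theta>0."""
        estimates = []
        for seed in range(200):
            s = simulate_dataset(study2_spec, 400, seed=seed)
            fit = fit_sr(s, study2_spec)
            if fit.converged:
                estimates.append(fit.estimates["Eta2~Eta1:Xi1"])
        mean = np.mean(estimates)
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert mean < 0.1 - 2 * se  # strict, significant underestimation

    def test_constant_indicator_flagged(self, study2_spec):
        s = simulate_dataset(study2_spec, 100, seed=0)
        bad = s.data.copy()
        bad["x1"] = 1.0
        fit = fit_sr(Sample(bad, s.seed), study2_spec)
        assert not fit.converged

    def test_sandwich_se_calibrated(self, study2_spec):
        """Empirical SD over replications matches the mean reported SE within 10%."""
        est, ses = [], []
        for seed in range(1000):
            s = simulate_dataset(study2_spec, 300, seed=seed)
            fit = fit_sr(s, study2_spec)
            if fit.converged:
                e, se = fit.resolve(POI)
                est.append(e)
                ses.append(se)
        assert np.std(est) == pytest.approx(np.mean(ses), rel=0.10)


class TestFactorScoreRegression:
    def test_near_zero_error_reproduces_latent_regression(self):
        spec = moderated_mediation_model(0.01)
        s = simulate_dataset(spec, 20_000, seed=31)
        fit = fit_fsr(s, spec)
        assert fit.converged
        for key, truth in STRUCTURAL_TRUTH.items():
            assert fit.estimates[key] == pytest.approx(truth, abs=0.03), key

    def test_high_reliability_large_n_interaction(self, study2_spec):
        s = simulate_dataset(study2_spec, 100_000, seed=32)
        fit = fit_fsr(s, study2_spec)
        assert fit.converged
        # small relative bias (a few percent) for the interaction
        assert fit.estimates["Eta2~Xi1:Xi2"] == pytest.approx(0.1, rel=0.10)

    def test_single_indicator_scores_proportional_to_indicator(self):
        spec = parse_model(
            "F =~ 1*f1\nf1~~0.5*f1\nF~~1*F\n"
            "G =~ 1*g1 + 1*g2 + 1*g3\ng1~~0.5*g1\ng2~~0.5*g2\ng3~~0.5*g3\n"
            "G ~ 0.4*F\nG~~0.84*G"
        )
        s = simulate_dataset(spec, 5_000, seed=33)
        fit = fit_fsr(s, spec)
        assert fit.converged
        # with loading and error fixed at population values the regression
        # score of F is a deterministic multiple of f1, so the slope of G on F
        # is the attenuated single-indicator slope: 0.4 / (1 + theta) * ...
        est = fit.estimates["G~F"]
        assert 0.3 < est < 0.65


class TestProductIndicators:
    def test_matched_pairs_count(self, study2_spec):
        pairs = product_indicator_pairs(study2_spec, Term("Xi1", "Xi2"), "matched")
        assert pairs == [("x1", "x4"), ("x2", "x5"), ("x3", "x6")]

    def test_all_pairs_count(self, study2_spec):
        pairs = product_indicator_pairs(study2_spec, Term("Xi1", "Xi2"), "all")
        assert len(pairs) == 9

    def test_quadratic_matched_squares(self):
        spec = parse_model(
            "A =~ 1*a1 + 1*a2\na1~~.2*a1\na2~~.2*a2\nA~~1*A\n"
            "B ~ 0.2*A + 0.1*A:A\nB~~0.9*B\nB =~ 1*b1\nb1~~.2*b1"
        )
        assert product_indicator_pairs(spec, Term("A", "A"), "matched") == [
            ("a1", "a1"), ("a2", "a2")
        ]

    def test_double_mean_centering_zero_mean(self, study2_spec):
        s = simulate_dataset(study2_spec, 500, seed=4)
        aug = build_product_indicators(s, study2_spec, "matched", "double_mean")
        prod_cols = [c for c in aug.columns if "." in c]
        assert len(prod_cols) == 6  # two product terms, three matched pairs each
        assert np.allclose(aug.data[prod_cols].mean(), 0.0, atol=1e-12)

    def test_unknown_options_rejected(self, study2_spec):
        s = simulate_dataset(study2_spec, 50, seed=4)
        with pytest.raises(ValueError):
            build_product_indicators(s, study2_spec, centering="weird")
        with pytest.raises(ValueError):
            product_indicator_pairs(study2_spec, Term("Xi1", "Xi2"), "weird")


class TestUPI:
    def test_consistent_at_high_reliability_large_n(self, study2_spec):
        s = simulate_dataset(study2_spec, 50_000, seed=41)
        fit = fit_upi(s, study2_spec)
        assert fit.converged
        for key, truth in STRUCTURAL_TRUTH.items():
            est, se = fit.estimates[key], fit.standard_errors[key]
            assert abs(est - truth) < 4 * se, key

    def test_small_sample_nonconvergence_flagged_not_raised(self, study2_spec):
        flags = []
        for seed in range(20):
            s = simulate_dataset(study2_spec, 60, seed=seed)
            flags.append(fit_upi(s, study2_spec).converged)
        # small n with 18 indicators: failures are possible and must be flags
        assert all(isinstance(f, bool) for f in flags)


class TestDispatch:
    def test_lms_refused(self, study2_spec):
        s = simulate_dataset(study2_spec, 100, seed=0)
        with pytest.raises(NotImplementedError, match="Mplus"):
            fit_qisem(s, study2_spec, "LMS")

    def test_unknown_method(self, study2_spec):
        s = simulate_dataset(study2_spec, 100, seed=0)
        with pytest.raises(ValueError, match="unknown method"):
            fit_qisem(s, study2_spec, "ABC")

    def test_poi_resolution_error_lists_parameters(self, study2_spec):
        s = simulate_dataset(study2_spec, 2_000, seed=1)
        fit = fit_sr(s, study2_spec)
        with pytest.raises(KeyError, match="available"):
            fit.resolve(ParameterRef.parse("Eta2~Xi2:Xi2"))
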