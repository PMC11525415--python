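import itertools

import numpy as np
import pytest

from nlsempower import (
    MomentsError,
    Term,
    endogenous_variance,
    linear_latent_cov,
    moderated_mediation_model,
    parse_model,
    product_moments,
    residual_variance_for_unit_variance,
    scale_reliability,
    simulate_dataset,
    variance_increment,
)

XI1XI2 = Term("Xi1", "Xi2")
ETA1XI1 = Term("Eta1", "Xi1")


class TestLinearLatentCov:
    def test_study2_linear_covariances(self, study2_spec):
        t = linear_latent_cov(study2_spec)
        # eta1 = .2 xi1 + .5 xi2 + zeta1 with Corr(xi1, xi2) = .5
        assert t.cov("Eta1", "Xi1") == pytest.approx(0.2 + 0.5 * 0.5)
        assert t.cov("Eta1", "Xi2") == pytest.approx(0.2 * 0.5 + 0.5)
        assert t.var("Eta1") == pytest.approx(1.0)
        assert t.var("Eta2") == pytest.approx(1.0)

    def test_no_equations_returns_declared_phi(self):
        spec = parse_model("A ~~ 2*A\nB ~~ 3*B")
        t = linear_latent_cov(spec)
        assert t.var("A") == 2 and t.var("B") == 3 and t.cov("A", "B") == 0

    def test_product_of_nonlinear_latent_rejected(self):
        text = "\n".join(
            [
                "A~~1*A", "B~~1*B",
                "C ~ 0.3*A:B", "C~~1*C",
                "D ~ 0.2*C:A", "D~~1*D",
            ]
        )
        with pytest.raises(MomentsError, match="product"):
            linear_latent_cov(parse_model(text))


class TestProductMoments:
    def test_interaction_variance_with_correlated_predictors(self, study2_spec):
        t = product_moments(study2_spec, [XI1XI2])
        # Var(xi1 xi2) = 1*1 + .5^2 for unit-variance, correlation-.5 normals
        assert t.var(XI1XI2) == pytest.approx(1.25)

    def test_study2_cross_product_covariance(self, study2_spec):
        t = product_moments(study2_spec, [XI1XI2, ETA1XI1])
        assert t.cov(ETA1XI1, XI1XI2) == pytest.approx(0.45 * 0.5 + 0.6 * 1.0)
        assert t.cov(XI1XI2, Term("Xi1")) == 0.0

    def test_independent_squares_uncorrelated(self):
        spec = parse_model("A ~~ 1*A\nB ~~ 1*B")
        t = product_moments(spec, [Term("A", "A"), Term("B", "B")])
        assert t.cov(Term("A", "A"), Term("B", "B")) == 0.0
        assert t.var(Term("A", "A")) == pytest.approx(2.0)  # Var(Z^2) = 2


class TestVarianceDecomposition:
    def test_study2_unit_variances(self, study2_spec):
        assert endogenous_variance(study2_spec, "Eta1") == pytest.approx(1.0)
        assert endogenous_variance(study2_spec, "Eta2") == pytest.approx(1.0)

    def test_study2_residual_variances(self, study2_spec):
        assert residual_variance_for_unit_variance(
            study2_spec, "Eta1"
        ) == pytest.approx(0.61)
        assert residual_variance_for_unit_variance(
            study2_spec, "Eta2"
        ) == pytest.approx(0.620975)

    def test_no_predictors_residual_is_one(self):
        spec = parse_model("A ~~ 0.4*A")
        assert residual_variance_for_unit_variance(spec, "A") == 1.0

    def test_overexplained_variance_raises(self):
        text = "A~~1*A\nB ~ 1.2*A\nB~~0.1*B"
        with pytest.raises(MomentsError, match="explained"):
            residual_variance_for_unit_variance(parse_model(text), "B")

    def test_residual_then_variance_is_one(self, study2_spec):
        """Plugging the solved residual variance back yields variance 1 exactly."""
        import dataclasses

        for latent in ("Eta1", "Eta2"):
            psi = residual_variance_for_unit_variance(study2_spec, latent)
            spec = dataclasses.replace(
                study2_spec,
                variances={**study2_spec.variances, (latent, latent): psi},
            )
            assert endogenous_variance(spec, latent) == pytest.approx(1.0)


class TestVarianceIncrements:
    def test_study2_printed_increments(self, study2_spec):
        inc1 = variance_increment(study2_spec, "Eta2", XI1XI2)
        inc2 = variance_increment(study2_spec, "Eta2", ETA1XI1, [XI1XI2])
        assert inc1 == pytest.approx(0.0125)
        assert inc2 == pytest.approx(0.028525)

    def test_total_increment_is_order_invariant(self, study2_spec):
        terms = [XI1XI2, ETA1XI1]
        totals = []
        for order in itertools.permutations(terms):
            total = 0.0
            for i, t in enumerate(order):
                total += variance_increment(
                    study2_spec, "Eta2", t, list(order[:i])
                )
            totals.append(total)
        assert totals[0] == pytest.approx(totals[1])

    def test_zero_coefficient_zero_increment(self):
        text = "\n".join(
            ["A~~1*A", "B~~1*B", "C ~ 0.3*A + 0*A:B", "C~~0.91*C"]
        )
        spec = parse_model(text)
        assert variance_increment(spec, "C", Term("A", "B")) == 0.0

    def test_unknown_term_raises(self, study2_spec):
        with pytest.raises(MomentsError, match="not in equation"):
            variance_increment(study2_spec, "Eta1", XI1XI2)


class TestScaleReliability:
    def test_error_free_scale(self):
        spec = parse_model(
            "F =~ 1*a + 1*b + 1*c\nF~~1*F\na~~0*a\nb~~0*b\nc~~0*c"
        )
        assert scale_reliability(spec, "F") == pytest.approx(1.0)

    def test_unit_loadings_unit_errors(self):
        spec = parse_model(
            "F =~ 1*a + 1*b + 1*c\nF~~1*F\na~~1*a\nb~~1*b\nc~~1*c"
        )
        assert scale_reliability(spec, "F") == pytest.approx(0.75)

    def test_single_indicator(self):
        spec = parse_model("F =~ 1*a\nF~~1*F\na~~0.5*a")
        assert scale_reliability(spec, "F") == pytest.approx(2.0 / 3.0)


class TestMonteCarloAgreement:
    """Analytic moments match simulation within 3 Monte-Carlo SEs."""

    def test_latent_moments_vs_simulation(self, study2_spec):
        import dataclasses

        # observe latents directly: drop the measurement model
        spec = dataclasses.replace(study2_spec, measurement={})
        n = 400_000
        s = simulate_dataset(spec, n, seed=99).data
        t = product_moments(study2_spec, [XI1XI2, ETA1XI1])
        for a, b in (("Eta1", "Xi1"), ("Eta2", "Eta2"), ("Eta1", "Eta2")):
            # sample covariance (eta2 has a nonzero mean from its products)
            prod = (s[a] - s[a].mean()) * (s[b] - s[b].mean())
            mc = prod.mean()
            se = prod.std() / np.sqrt(n)
            assert abs(mc - t.cov(a, b)) < 3 * se, (a, b)
        # the model-implied mean of eta2 is the product-term contribution
        assert abs(s["Eta2"].mean() - t.mean("Eta2")) < 3 / np.sqrt(n)
        prod_term = s["Xi1"] * s["Xi2"]
        mc_var = prod_term.var()
        se = prod_term.std() ** 2 * np.sqrt(2.0 / n) * 2  # loose bound
        assert abs(mc_var - t.var(XI1XI2)) < 3 * se
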