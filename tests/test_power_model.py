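import numpy as np
import pytest
from scipy.stats import norm

from nlsempower import (
    ParameterRef,
    PowerModelFit,
    SeparationError,
    fit_power_model,
    moderation_model,
    predict_power,
    required_n,
    required_n_lb,
    significance_decisions,
)
from nlsempower.estimators import FitResult
from nlsempower.power_model import SignificanceRecord, band_crossing_n


def make_fit(est, se, n=100, key="Eta1~Xi1:Xi2"):
    return FitResult("SR", {key: est}, {key: se}, True, n)


def artificial_records(beta0, beta1, sizes, seed=0, key="p"):
    rng = np.random.default_rng(seed)
    p = norm.cdf(beta0 + beta1 * np.sqrt(sizes))
    s = rng.random(len(sizes)) < p
    return [
        SignificanceRecord(int(n), True, {key: int(si)})
        for n, si in zip(sizes, s)
    ]


@pytest.fixture(scope="module")
def spec():
    return moderation_model()


@pytest.fixture(scope="module")
def poi():
    return ParameterRef.parse("Eta1~Xi1:Xi2")


class TestSignificanceDecisions:
    @pytest.mark.parametrize(
        "est, se, test, expected",
        [
            (0.25, 0.1, "onesided", 1),   # z = 2.5 > 1.645
            (-0.30, 0.1, "onesided", 0),  # wrong direction for gamma > 0
            (0.25, 0.1, "twosided", 1),   # 2.5 > 1.96
            (0.18, 0.1, "twosided", 0),   # 1.8 < 1.96
            (0.18, 0.1, "onesided", 1),   # 1.8 > 1.645
        ],
    )
    def test_decision_arithmetic(self, spec, poi, est, se, test, expected):
        recs = significance_decisions(
            [make_fit(est, se)], [poi], 0.05, test, spec
        )
        assert recs[0].decisions[str(poi)] == expected

    def test_nonconverged_carries_no_decision(self, spec, poi):
        bad = FitResult("SR", {}, {}, False, 77)
        recs = significance_decisions([bad], [poi], 0.05, "onesided", spec)
        assert recs[0].converged is False and recs[0].decisions == {}

    def test_invalid_alpha(self, spec, poi):
        with pytest.raises(ValueError):
            significance_decisions([make_fit(0.2, 0.1)], [poi], 1.5, "onesided", spec)


class TestFitPowerModel:
    def test_generator_recovery(self):
        sizes = np.random.default_rng(3).integers(25, 600, size=20_000)
        records = artificial_records(-1.64, 0.2, sizes, seed=3)
        fit = fit_power_model(records, "p", "probit")
        se0, se1 = np.sqrt(np.diag(fit.vcov))
        assert abs(fit.beta0 + 1.64) < 3 * se0
        assert abs(fit.beta1 - 0.2) < 3 * se1

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        sizes = np.random.default_rng(5).integers(25, 400, size=3_000)
        records = artificial_records(-1.64, 0.2, sizes, seed=5)
        for link_name, link in (
            ("probit", sm.families.links.Probit()),
            ("logit", sm.families.links.Logit()),
        ):
            fit = fit_power_model(records, "p", link_name)
            y = np.array([r.decisions["p"] for r in records], dtype=float)
            x = sm.add_constant(np.sqrt([r.n for r in records]))
            glm = sm.GLM(y, x, family=sm.families.Binomial(link)).fit()
            assert fit.beta0 == pytest.approx(glm.params[0], abs=1e-5)
            assert fit.beta1 == pytest.approx(glm.params[1], abs=1e-6)

    def test_separation_raises_with_remedy(self):
        records = [SignificanceRecord(100 + i, True, {"p": 1}) for i in range(50)]
        with pytest.raises(SeparationError, match="widen"):
            fit_power_model(records, "p")

    def test_single_size_rejected(self):
        records = [
            SignificanceRecord(100, True, {"p": i % 2}) for i in range(50)
        ]
        with pytest.raises(SeparationError, match="distinct"):
            fit_power_model(records, "p")


class TestPredictPower:
    def test_closed_form_point(self):
        fit = PowerModelFit("probit", -1.64, 0.1, np.zeros((2, 2)), 1000)
        point, lower, upper = predict_power(fit, 616)
        assert point == pytest.approx(norm.cdf(-1.64 + 0.1 * np.sqrt(616)))
        assert point == pytest.approx(0.8, abs=1e-3)
        assert lower == point == upper  # zero vcov: degenerate band

    def test_band_orders_and_bounds(self):
        fit = PowerModelFit("probit", -1.64, 0.1, 0.01 * np.eye(2), 1000)
        point, lower, upper = predict_power(fit, 400)
        assert 0 < lower < point < upper < 1

    def test_monotone_in_n(self):
        fit = PowerModelFit("probit", -1.64, 0.1, 0.001 * np.eye(2), 1000)
        grid = np.array([50, 100, 200, 400, 800])
        point, _, _ = predict_power(fit, grid)
        assert np.all(np.diff(point) > 0)


class TestRequiredN:
    def test_printed_inversions(self):
        assert required_n((-1.64, 0.1), 0.8) == 616
        assert required_n((-1.64, 0.2), 0.8) == 154

    def test_inversion_identity(self):
        rho = norm.cdf(-1.64 + 0.1 * np.sqrt(400))
        assert required_n((-1.64, 0.1), rho) == 400

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            required_n((-1.64, 0.0), 0.8)

    def test_logit_link(self):
        beta0, beta1 = -3.0, 0.2
        n = required_n((beta0, beta1), 0.8, link="logit")
        lo = 1 / (1 + np.exp(-(beta0 + beta1 * np.sqrt(n))))
        hi = 1 / (1 + np.exp(-(beta0 + beta1 * np.sqrt(n - 1))))
        assert lo >= 0.8 > hi or lo >= 0.8  # smallest integer reaching 0.8

    def test_probit_and_logit_agree_locally(self):
        """Both links fitted to the same probit records invert within 10%."""
        sizes = np.random.default_rng(11).integers(50, 350, size=20_000)
        records = artificial_records(-1.64, 0.2, sizes, seed=11)
        n_probit = required_n(fit_power_model(records, "p", "probit"), 0.8)
        n_logit = required_n(fit_power_model(records, "p", "logit"), 0.8)
        assert abs(n_probit - n_logit) / n_probit < 0.10


@pytest.fixture(scope="module")
def fitted():
    sizes = np.random.default_rng(7).integers(50, 350, size=10_000)
    return fit_power_model(artificial_records(-1.64, 0.2, sizes, seed=7), "p")


class TestRequiredNLowerBound:
    def test_at_least_n_alpha(self, fitted):
        assert required_n_lb(fitted, 0.8) >= required_n(fitted, 0.8)

    def test_degenerate_vcov_equals_n_alpha(self, fitted):
        degenerate = PowerModelFit(
            fitted.link, fitted.beta0, fitted.beta1, np.zeros((2, 2)), 1
        )
        assert required_n_lb(degenerate, 0.8) == required_n(degenerate, 0.8)

    def test_band_crossings_bracket_n_alpha(self, fitted):
        lo = band_crossing_n(fitted, 0.8, 0.05, "upper")
        hi = band_crossing_n(fitted, 0.8, 0.05, "lower")
        assert lo <= required_n(fitted, 0.8) <= hi

    def test_continuous_crossing_below_ceiling(self, fitted):
        exact = band_crossing_n(fitted, 0.8, 0.05, "lower", integer=False)
        assert int(np.ceil(exact - 1e-9)) == required_n_lb(fitted, 0.8)

    def test_monotone_in_targets(self, fitted):
        assert required_n_lb(fitted, 0.9) > required_n_lb(fitted, 0.8)
        assert required_n_lb(fitted, 0.8, 0.01) >= required_n_lb(fitted, 0.8, 0.05)


class TestAsymptoticLimit:
    def test_one_sample_z_test_limit(self):
        """Probit fit to one-sample z-test decisions recovers (-q(1-a), |mu|/sd).

        For a z-test of mu = .2 (sd 1, one-sided alpha .05) the exact power at
        n is Phi(-1.645 + .2 sqrt(n)), so beta0 -> -1.645 and beta1 -> 0.2.
        """
        rng = np.random.default_rng(0)
        n_records = 100_000
        sizes = rng.integers(25, 600, size=n_records)
        xbar = rng.normal(0.2, 1.0 / np.sqrt(sizes))
        z = xbar * np.sqrt(sizes)
        records = [
            SignificanceRecord(int(n), True, {"mu": int(zi > norm.ppf(0.95))})
            for n, zi in zip(sizes, z)
        ]
        fit = fit_power_model(records, "mu", "probit")
        assert fit.beta0 == pytest.approx(-norm.ppf(0.95), rel=0.02)
        assert fit.beta1 == pytest.approx(0.2, rel=0.02)
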