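import numpy as np
import pytest

from nlsempower import (
    SearchConfig,
    allocate_replications,
    draw_sizes,
    make_artificial_backend,
    moderation_model,
    run_adaptive,
    run_brute_force,
    run_mspe,
)
from nlsempower.search import CHANGE_FACTOR


class TestAllocateReplications:
    def test_equal_split(self):
        assert allocate_replications(2000, 10, "equal") == [200] * 10

    def test_increasing_sums_and_monotone(self):
        r = allocate_replications(2000, 10, "increasing")
        assert sum(r) == 2000
        assert all(a <= b for a, b in zip(r, r[1:]))

    def test_u_shaped_two_steps_symmetric(self):
        assert allocate_replications(10, 2, "u_shaped") == [5, 5]

    @pytest.mark.parametrize("dist", ["equal", "increasing", "u_shaped"])
    @pytest.mark.parametrize("R, steps", [(17, 5), (1000, 7), (10, 10)])
    def test_exact_total_and_positivity(self, dist, R, steps):
        r = allocate_replications(R, steps, dist)
        assert sum(r) == R and min(r) >= 1 and len(r) == steps

    def test_too_few_replications(self):
        with pytest.raises(ValueError):
            allocate_replications(5, 10, "equal")


class TestDrawSizes:
    def test_degenerate_interval(self, rng):
        assert list(draw_sizes((100, 100), 5, rng)) == [100] * 5

    def test_within_bounds_and_symmetric_mean(self, rng):
        draws = draw_sizes((50, 150), 10_000, rng)
        assert draws.min() >= 50 and draws.max() <= 150
        se = (150 - 50) / np.sqrt(12) / np.sqrt(10_000)
        assert abs(draws.mean() - 100) < 3 * se

    def test_inverted_interval_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_sizes((10, 5), 3, rng)


class TestArtificialBackend:
    def test_success_probability(self):
        be = make_artificial_backend(-1.64, 0.1)
        assert be.success_probability(616) == pytest.approx(0.8, abs=1e-3)
        flat = make_artificial_backend(-1.0, 0.0)
        from scipy.stats import norm

        assert flat.success_probability(10) == pytest.approx(norm.cdf(-1.0))

    def test_empirical_rate_matches(self):
        be = make_artificial_backend(-1.64, 0.2)
        n = 154
        recs = be.evaluate(np.full(50_000, n), list(range(50_000)))
        rate = np.mean([r.decisions["artificial"] for r in recs])
        p = be.success_probability(n)
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / 50_000)


class TestBruteForce:
    def test_systematic_grid_with_replicates(self):
        """1000 distinct sizes 140..1139 with 2 replications each."""
        cfg = SearchConfig(
            method="bruteforce", R=2000, n_min=140, n_max=1139,
            grid_replicates=2, n_lb=1, seed=4,
        )
        result = run_brute_force(make_artificial_backend(-1.64, 0.1), cfg)
        sizes = sorted(r.n for r in result.records)
        assert len(sizes) == 2000
        assert sizes[0] == 140 and sizes[-1] == 1139
        assert all(sizes.count(n) == 2 for n in (140, 500, 1139))

    def test_interval_validation(self):
        cfg = SearchConfig(method="bruteforce", R=100, n_min=300, n_max=200)
        with pytest.raises(ValueError, match="n_min"):
            run_brute_force(make_artificial_backend(-1.64, 0.2), cfg)

    def test_estimates_near_truth(self):
        cfg = SearchConfig(
            method="bruteforce", R=10_000, n_min=25, n_max=300,
            draw="random", n_lb=1, seed=2,
        )
        result = run_brute_force(make_artificial_backend(-1.64, 0.2), cfg)
        assert abs(result.overall_n_alpha - 154) <= 12
        assert result.overall_n_alpha_lb >= result.overall_n_alpha


class TestAdaptive:
    @pytest.fixture(scope="class")
    def result(self):
        cfg = SearchConfig(
            method="adaptive", R=10_000, steps=10, n_start=150, n_lb=50, seed=9
        )
        return run_adaptive(make_artificial_backend(-1.64, 0.2), cfg)

    def test_total_replications_preserved(self, result):
        assert len(result.records) == 10_000
        assert sum(s.r_j for s in result.step_history) == 10_000

    def test_all_sizes_respect_lower_bound(self, result):
        assert min(r.n for r in result.records) >= 50

    def test_constrained_change_factor(self, result):
        hist = result.step_history
        for prev, cur in zip(hist, hist[1:]):
            assert cur.n_min >= np.floor(prev.n_min / CHANGE_FACTOR)
            assert cur.n_max <= np.ceil(prev.n_max * CHANGE_FACTOR)

    def test_estimate_near_truth_and_conservative(self, result):
        assert abs(result.overall_n_alpha - 154) <= 10
        assert result.overall_n_alpha_lb >= result.overall_n_alpha
        assert result.overall_n_alpha_lb_exact <= result.overall_n_alpha_lb

    def test_narrow_phase_concentrates(self, result):
        widths = [s.n_max - s.n_min for s in result.step_history]
        assert np.mean(widths[5:]) < np.mean(widths[:3])


class TestEndToEnd:
    def test_run_mspe_sr_adaptive(self, moderation_spec):
        cfg = SearchConfig(method="adaptive", R=400, steps=5, seed=3)
        result = run_mspe(
            moderation_spec, ["Eta1~Xi1:Xi2"], estimator="SR", config=cfg
        )
        assert len(result.records) == 400
        assert result.overall_n_alpha_lb >= result.overall_n_alpha > 50
        assert 0.9 < result.convergence_rate <= 1.0

    def test_serial_parallel_identical(self, moderation_spec):
        import dataclasses

        cfg = SearchConfig(method="adaptive", R=240, steps=3, seed=17)
        serial = run_mspe(moderation_spec, ["Eta1~Xi1:Xi2"], "SR", cfg)
        par_cfg = dataclasses.replace(cfg, cores=2)
        parallel = run_mspe(moderation_spec, ["Eta1~Xi1:Xi2"], "SR", par_cfg)
        assert [r.n for r in serial.records] == [r.n for r in parallel.records]
        assert [r.decisions for r in serial.records] == [
            r.decisions for r in parallel.records
        ]
        assert serial.n_alpha_lb == parallel.n_alpha_lb

    def test_unknown_poi_lists_alternatives(self, moderation_spec):
        cfg = SearchConfig(R=50, steps=2, seed=1)
        with pytest.raises(KeyError, match="available"):
            run_mspe(moderation_spec, ["Eta1~Xi1:Xi1"], "SR", cfg)
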