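"""Monte Carlo machinery: truncated sampling, reproducibility, continuity
with the deterministic model, and sensitivity ranking."""

import numpy as np
import pytest
from scipy import stats

from beefdam.core import simulate
from beefdam.montecarlo import (
    ParameterDistribution,
    run_monte_carlo,
    sample_truncated,
    sensitivity_ranking,
)
from beefdam.profiles import default_profile
from beefdam.scenarios import GenericScenarioSpec, build_generic


class TestSampleTruncated:
    def test_zero_sd_returns_mean(self):
        dist = ParameterDistribution("x", 5.0, 0.0)
        assert sample_truncated(dist, np.random.default_rng(0)) == 5.0

    def test_draws_respect_quantile_bounds(self):
        dist = ParameterDistribution("half_life", 108.9, 40.5)
        draws = sample_truncated(dist, np.random.default_rng(1), size=10_000)
        lo, hi = stats.norm(108.9, 40.5).ppf([0.05, 0.95])
        assert draws.min() >= lo and draws.max() <= hi

    def test_symmetric_truncation_preserves_mean(self):
        dist = ParameterDistribution("x", 10.0, 2.0)
        draws = sample_truncated(dist, np.random.default_rng(2), size=200_000)
        assert draws.mean() == pytest.approx(10.0, abs=0.02)

    def test_relative_sd_resolves_at_draw_time(self):
        dist = ParameterDistribution("x", 100.0, 0.5, relative=True)
        draws = sample_truncated(dist, np.random.default_rng(3), size=50_000)
        assert draws.std() == pytest.approx(50.0 * 0.789, rel=0.05)  # truncated SD

    def test_invalid_truncation(self):
        with pytest.raises(ValueError):
            ParameterDistribution("x", 1.0, 1.0, truncation=(0.9, 0.1))


class TestRunMonteCarlo:
    def test_same_seed_is_bit_identical(self, generic_270, profile):
        a = run_monte_carlo(generic_270, profile, n=200, seed=42, forage_cv=0.4)
        b = run_monte_carlo(generic_270, profile, n=200, seed=42, forage_cv=0.4)
        assert a.mean == b.mean and a.sd == b.sd and a.p95 == b.p95
        np.testing.assert_array_equal(a.final_muscle, b.final_muscle)

    def test_all_sds_zero_reproduces_deterministic_run(self, generic_270, profile):
        det = simulate(generic_270, profile).final_muscle_conc
        mc = run_monte_carlo(generic_270, profile, n=50, seed=0, vary_parameters=False)
        assert mc.sd == 0.0
        assert mc.mean == pytest.approx(det, rel=1e-9)

    def test_continuity_at_vanishing_sd_scale(self, generic_270, profile):
        det = simulate(generic_270, profile).final_muscle_conc
        mc = run_monte_carlo(generic_270, profile, n=50, seed=0, sd_scale=1e-6)
        assert mc.mean == pytest.approx(det, rel=1e-4)

    def test_summary_orders_quantiles(self, generic_270, profile):
        mc = run_monte_carlo(generic_270, profile, n=500, seed=1, forage_cv=0.4)
        lo, hi = mc.ci90
        assert lo <= mc.mean <= hi
        assert mc.p95 == hi
        assert mc.p95 == pytest.approx(np.percentile(mc.final_muscle, 95))

    def test_mean_stable_across_seeds(self, generic_270, profile):
        # repeated-run grand mean vs a single run, within 3 MC standard errors
        runs = [run_monte_carlo(generic_270, profile, n=1000, seed=s) for s in range(4)]
        grand = np.mean([r.mean for r in runs])
        se = runs[0].sd / np.sqrt(runs[0].n_iterations)
        assert abs(runs[0].mean - grand) < 3 * se

    def test_forage_noise_scopes(self, generic_270, profile):
        # per-iteration noise on a constant ration cannot average out, so it
        # spreads the output far more than per-day noise does
        per_day = run_monte_carlo(generic_270, profile, n=400, seed=3,
                                  forage_cv=0.4, vary_parameters=False,
                                  forage_noise_scope="per_day")
        per_iter = run_monte_carlo(generic_270, profile, n=400, seed=3,
                                   forage_cv=0.4, vary_parameters=False,
                                   forage_noise_scope="per_iteration")
        per_seg = run_monte_carlo(generic_270, profile, n=400, seed=3,
                                  forage_cv=0.4, vary_parameters=False,
                                  forage_noise_scope="per_segment")
        assert per_iter.sd > 5 * per_day.sd
        # the generic scenario is one constant segment, so per-segment and
        # per-iteration sampling coincide in distribution
        assert per_seg.sd == pytest.approx(per_iter.sd, rel=0.3)

    def test_minimum_iterations(self, generic_270, profile):
        with pytest.raises(ValueError):
            run_monte_carlo(generic_270, profile, n=1)


class TestSensitivity:
    def test_independent_parameter_scores_zero(self, generic_270, profile):
        mc = run_monte_carlo(generic_270, profile, n=300, seed=5)
        ranking = dict(sensitivity_ranking(mc.samples, mc.final_muscle))
        # muscle:serum never enters the muscle concentration
        assert ranking["muscle_serum_ratio"] < 0.2
        assert ranking["muscle_body_ratio"] > 0.5

    def test_constant_parameter_reports_zero(self):
        rng = np.random.default_rng(0)
        outputs = rng.normal(size=200)
        samples = {"const": np.ones(200), "noise": rng.normal(size=200)}
        ranking = dict(sensitivity_ranking(samples, outputs))
        assert ranking["const"] == 0.0

    def test_serum_output_brings_in_muscle_serum_ratio(self, generic_270, profile):
        mc = run_monte_carlo(generic_270, profile, n=500, seed=6)
        muscle = dict(sensitivity_ranking(mc.samples, mc.final_muscle))
        serum = dict(sensitivity_ranking(mc.samples, mc.final_serum))
        assert serum["muscle_serum_ratio"] > 0.2 > muscle["muscle_serum_ratio"]

    def test_requires_enough_iterations(self):
        with pytest.raises(ValueError):
            sensitivity_ranking({"x": np.ones(10)}, np.ones(10))
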