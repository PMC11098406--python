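"""GCP initialization/updating and the dementia proportional-hazards model."""

import numpy as np
import pytest

from chronosim.cognition import (
    DementiaCoxSpec,
    GCPModelSpec,
    StateError,
    TargetIncidenceCurve,
    annual_dementia_probability,
    default_dementia_cox_spec,
    default_gcp_spec,
    dementia_linear_predictor,
    initialize_gcp,
    person_annual_dementia_probability,
    recalibrate_baseline_hazard,
    simulate_dementia_times,
    update_gcp,
)
from chronosim.population import PopulationConfig, generate_population
from chronosim.rng import stream_factory, substream
from chronosim.riskfactors import advance_risk_factors
from chronosim.specs import RegressionSpec


def make_pop(n=500, seed=51, gcp_spec=None):
    return generate_population(PopulationConfig(n=n), substream(seed, "population"),
                               gcp_spec=gcp_spec or default_gcp_spec())


class TestInitializeGCP:
    def test_degenerate_random_effect_equals_fixed_lp(self):
        spec = GCPModelSpec(fixed=default_gcp_spec().fixed, random_intercept_sd=0.0)
        pop = make_pop(gcp_spec=spec)
        assert np.allclose(pop.gcp_random_effect, 0.0)
        pop2 = make_pop(gcp_spec=spec)
        initialize_gcp(pop2, spec, substream(1, "x"))
        assert np.allclose(pop.series["gcp"][0], pop2.series["gcp"][0])

    def test_variance_matches_random_intercept_sd(self):
        sd = 5.0
        spec = GCPModelSpec(
            fixed=RegressionSpec(name="g", family="linear", outcome="gcp",
                                 coefficients={"intercept": 50.0}),
            random_intercept_sd=sd,
        )
        pop = make_pop(n=100_000, gcp_spec=spec)
        var = pop.series["gcp"][0].var(ddof=1)
        se_var = sd**2 * np.sqrt(2.0 / (pop.n - 1))
        assert abs(var - sd**2) < 3 * se_var

    def test_persons_differ_unless_sd_zero(self):
        pop = make_pop(n=10)
        assert len(np.unique(pop.series["gcp"][0])) > 1


class TestUpdateGCP:
    def _advance(self, pop, repo, gcp_spec, seed=3):
        w = pop.wave + 1
        pop.commit_wave(advance_risk_factors(pop, repo, stream_factory(seed, wave=w)))
        update_gcp(pop, gcp_spec, substream(seed, "gcp", w))

    def test_constant_covariates_and_zero_residual_keep_gcp_constant(self, identity_repo):
        fixed = RegressionSpec(name="g", family="linear", outcome="gcp",
                               coefficients={"intercept": 50.0, "lag_bmi": 0.1})
        spec = GCPModelSpec(fixed=fixed, random_intercept_sd=2.0, residual_sd=0.0)
        pop = make_pop(gcp_spec=spec)
        g0 = pop.series["gcp"][0].copy()
        for _ in range(3):
            self._advance(pop, identity_repo, spec)
        assert np.allclose(pop.current("gcp"), g0, atol=1e-9)

    def test_negative_sbp_coefficient_lowers_expected_gcp(self, identity_repo):
        fixed = RegressionSpec(name="g", family="linear", outcome="gcp",
                               coefficients={"intercept": 50.0, "log_sbp": -3.0},
                               covariate_kinds={"log_sbp": "current"})
        spec = GCPModelSpec(fixed=fixed, random_intercept_sd=0.0, residual_sd=0.0)
        pop = make_pop(gcp_spec=spec)
        self._advance(pop, identity_repo, spec)
        before = pop.current("gcp").copy()
        pop.series["sbp"][pop.wave] = pop.series["sbp"][pop.wave] * 1.2
        update_gcp(pop, spec, substream(3, "gcp", pop.wave))
        assert np.all(pop.current("gcp") < before)

    def test_noise_free_age_linear_gcp_slope_equals_age_coefficient(self, identity_repo):
        beta_age = -0.4
        fixed = RegressionSpec(name="g", family="linear", outcome="gcp",
                               coefficients={"intercept": 60.0, "age": beta_age},
                               covariate_kinds={"age": "current"})
        spec = GCPModelSpec(fixed=fixed, random_intercept_sd=3.0, residual_sd=0.0)
        pop = make_pop(gcp_spec=spec)
        for _ in range(5):
            self._advance(pop, identity_repo, spec)
        from chronosim.cognition import gcp_slope

        assert np.allclose(gcp_slope(pop), beta_age, atol=1e-9)


class TestDementiaHazard:
    def test_flat_baseline_hazard_gives_zero_probability(self):
        pop = make_pop()
        cox = default_dementia_cox_spec().with_baseline((-3.0, 0.0, 0.0))
        assert np.allclose(annual_dementia_probability(pop, cox, 0, slope_wave=0), 0.0)

    def test_cumulative_hazard_anchored_and_monotone(self):
        cox = default_dementia_cox_spec()
        t = np.arange(0, 40)
        h = cox.cumulative_hazard(t)
        assert h[0] == 0.0
        assert np.all(np.diff(h) > 0)

    def test_ten_year_age_gap_hazard_ratio(self):
        cox = default_dementia_cox_spec()
        covs = {k: np.zeros(2) for k in cox.hazard_ratios}
        covs["baseline_gcp"] = np.array([50.0, 50.0])
        covs["baseline_age"] = np.array([75.0, 85.0])
        lp = dementia_linear_predictor(cox, covs)
        assert np.exp(lp[1] - lp[0]) == pytest.approx(1.108**10, rel=1e-9)

    def test_one_unit_gcp_multiplies_hazard_by_published_hr(self):
        cox = default_dementia_cox_spec()
        covs = {k: np.zeros(2) for k in cox.hazard_ratios}
        covs["baseline_age"] = np.array([75.0, 75.0])
        covs["baseline_gcp"] = np.array([50.0, 51.0])
        lp = dementia_linear_predictor(cox, covs)
        assert np.exp(lp[1] - lp[0]) == pytest.approx(0.927, rel=1e-9)

    def test_person_wrapper_rejects_prevalent_dementia(self):
        pop = make_pop(n=5)
        pop.dementia_wave[2] = 0
        with pytest.raises(StateError):
            person_annual_dementia_probability(pop.person(2), default_dementia_cox_spec(), 0)

    def test_annual_probability_is_grouped_continuous_hazard(self):
        """The engine's annual probability equals the interval probability of
        the continuous-time hazard the recovery experiment inverts."""
        pop = make_pop(n=1000)
        cox = default_dementia_cox_spec()
        from chronosim.cognition import _cox_covariates

        covs = _cox_covariates(pop, 0)
        lp = dementia_linear_predictor(cox, covs)
        for t in (0, 3, 10):
            p_discrete = annual_dementia_probability(pop, cox, t, slope_wave=0)
            inc = cox.cumulative_hazard(t + 1) - cox.cumulative_hazard(t)
            assert np.allclose(p_discrete, 1.0 - np.exp(-inc * np.exp(lp)), atol=1e-12)

    def test_simulated_times_match_analytic_survival(self):
        # P(T > t) = exp(-H0(t) * e^lp) for a homogeneous covariate profile
        cox = default_dementia_cox_spec()
        covs = {k: np.zeros(200_000) for k in cox.hazard_ratios}
        covs["baseline_gcp"] += 50.0
        covs["baseline_age"] += 80.0
        t, obs = simulate_dementia_times(cox, covs, horizon=15.0, rng=np.random.default_rng(5))
        lp = dementia_linear_predictor(cox, covs)[0]
        for t0 in (5.0, 10.0):
            expected = np.exp(-cox.cumulative_hazard(t0) * np.exp(lp))
            got = np.mean(t > t0)
            assert abs(got - expected) < 3 * np.sqrt(expected * (1 - expected) / t.size)


class TestAbsorbingState:
    def test_no_dementia_draws_after_onset(self, bundle):
        import chronosim as cs

        cfg = cs.SimulationConfig(population=PopulationConfig(n=3000), horizon=15,
                                  master_seed=41)
        res = cs.run(cfg, bundle=bundle)
        dem_events = [e for e in res.population.events if e.kind == "dementia"]
        pids = [e.person_id for e in dem_events]
        assert len(pids) == len(set(pids)), "dementia must be absorbing"
        assert len(pids) > 0


class TestBaselineHazardRecalibration:
    def test_toggle_off_leaves_baseline_untouched(self):
        cox = default_dementia_cox_spec()
        best, report = recalibrate_baseline_hazard(
            lambda abc: (_ for _ in ()).throw(AssertionError("must not simulate")),
            TargetIncidenceCurve(), grid=[(0, 1, 2)], enabled=False, current=cox.baseline,
        )
        assert best == cox.baseline and report["enabled"] is False

    def test_single_candidate_grid(self):
        sim = lambda abc: (np.array([70.0]), np.array([0.01]))
        best, _ = recalibrate_baseline_hazard(sim, TargetIncidenceCurve(), [(-3.0, 0.1, 0.0)])
        assert best == (-3.0, 0.1, 0.0)

    def test_empty_grid_is_config_error(self):
        with pytest.raises(ValueError, match="empty"):
            recalibrate_baseline_hazard(lambda abc: None, TargetIncidenceCurve(), [])

    def test_engine_search_recovers_generating_parameters(self, bundle):
        """Self-consistency: a target produced by the simulator at known
        (a, b, c) is recovered, and the argmin objective cannot exceed any
        grid point's objective."""
        import chronosim as cs
        from chronosim.engine import calibrate_dementia, dementia_incidence_by_age, run

        cfg = cs.SimulationConfig(population=PopulationConfig(n=3000), horizon=15,
                                  master_seed=43)
        res = run(cfg, bundle=bundle)
        ages, inc = dementia_incidence_by_age(res.population)
        target = TargetIncidenceCurve(table=(ages, inc))
        true_abc = bundle.cox.baseline
        grid = [(true_abc[0] + d, true_abc[1], true_abc[2]) for d in (-0.5, 0.0, 0.5)]
        best, report = calibrate_dementia(cfg, target, grid, bundle=bundle)
        assert best == true_abc
        assert report["objective"][best] <= min(report["objective"].values()) + 1e-15


class TestTargetCurve:
    def test_parametric_doubling(self):
        curve = TargetIncidenceCurve(i0=0.001, a0=65.0, doubling_years=5.0)
        assert curve(70.0) == pytest.approx(0.002)
        assert curve(75.0) == pytest.approx(0.004)

    def test_tabulated_validation(self):
        with pytest.raises(ValueError):
            TargetIncidenceCurve(table=([70.0, 65.0], [0.01, 0.02]))([68.0])
        with pytest.raises(ValueError):
            TargetIncidenceCurve(table=([65.0, 70.0], [-0.01, 0.02]))([68.0])
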