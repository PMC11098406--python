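"""Engine orchestration: rule ordering, conservation, determinism, horizon."""

import numpy as np
import pytest

import chronosim as cs
from chronosim.defaults import ModelBundle
from chronosim.engine import advance_year, run
from chronosim.population import CONTINUOUS_FACTORS, PopulationConfig, generate_population
from chronosim.rng import substream


def zero_event_bundle(bundle) -> ModelBundle:
    """Bundle in which no clinical event can occur."""
    from dataclasses import replace

    dead_pce = cs.PCESpec(strata={k: {"intercept": -60.0} for k in
                                  ("female_black", "female_nonblack",
                                   "male_black", "male_nonblack")})
    mort = replace(bundle.mortality.no_history,
                   coefficients={**bundle.mortality.no_history.coefficients,
                                 "intercept": -60.0})
    return ModelBundle(
        repo=bundle.repo, pce=dead_pce, partition=bundle.partition,
        mortality=cs.NonCVMortalitySpec(no_history=mort, dementia=mort),
        cox=bundle.cox.with_baseline((-60.0, 1e-6, 0.0)), gcp=bundle.gcp,
    )


@pytest.fixture()
def cfg():
    return cs.SimulationConfig(population=PopulationConfig(n=1500), horizon=4,
                               master_seed=81)


class TestAdvanceYear:
    def test_null_event_wave_only_updates_factors_and_age(self, cfg, bundle):
        pop = generate_population(cfg.population, substream(81, "population"),
                                  gcp_spec=bundle.gcp)
        age0 = pop.series["age"][0].copy()
        advance_year(pop, zero_event_bundle(bundle), cfg)
        assert np.all(pop.alive)
        assert len(pop.events) == 0
        assert np.array_equal(pop.current("age"), age0 + 1)
        assert pop.wave == 1

    def test_fatal_event_short_circuits_later_rules(self, cfg, bundle):
        """A person dying of a fatal CV event this wave gets no dementia or
        non-CV-death record and accrues 0 QALYs."""
        res = run(cs.SimulationConfig(population=PopulationConfig(n=20_000), horizon=3,
                                      master_seed=83), bundle=bundle)
        pop = res.population
        fatal = {(e.person_id, e.wave) for e in pop.events if e.fatal and not e.rolled_back}
        assert fatal, "expected some fatal CV events"
        for pid, w in fatal:
            others = [e for e in pop.events
                      if e.person_id == pid and e.wave == w and not e.fatal]
            assert not any(e.kind in ("dementia", "non_cv_death") for e in others)
            assert pop.qalys[w][pid] == 0.0

    def test_conservation_every_wave(self, bundle):
        strat = cs.TreatmentStrategy(kind="add_n_meds_once", n_meds=1, start_wave=1)
        cfg = cs.SimulationConfig(population=PopulationConfig(n=30_000), horizon=5,
                                  master_seed=85, strategy=strat)
        res = run(cfg, bundle=bundle)
        for _, row in res.snapshots.iterrows():
            assert row["alive"] == (row["alive_at_start"] - row["cv_deaths"]
                                    - row["non_cv_deaths"] + row["rollback_restorations"])
            assert row["rollback_restorations"] >= 0

    def test_dead_persons_untouched(self, cfg, bundle):
        res = run(cfg, bundle=bundle)
        pop = res.population
        dead = np.flatnonzero(~pop.alive)
        if dead.size:
            i = dead[0]
            w = pop.death_wave[i]
            for f in CONTINUOUS_FACTORS:
                frozen = pop.series[f][w][i]
                assert all(pop.series[f][k][i] == frozen for k in range(w, pop.wave + 1))


class TestDeterminism:
    def test_same_master_seed_bit_identical_snapshots(self, bundle):
        mk = lambda: cs.SimulationConfig(population=PopulationConfig(n=3000), horizon=4,
                                         master_seed=87)
        r1, r2 = run(mk(), bundle=bundle), run(mk(), bundle=bundle)
        assert r1.snapshots.equals(r2.snapshots)
        assert np.array_equal(r1.population.current("sbp"), r2.population.current("sbp"))
        assert np.array_equal(r1.population.death_wave, r2.population.death_wave)

    def test_results_invariant_to_person_storage_order(self, bundle):
        cfg = cs.SimulationConfig(population=PopulationConfig(n=2000), horizon=4,
                                  master_seed=89)
        pop1 = generate_population(cfg.population, substream(89, "population"),
                                   gcp_spec=bundle.gcp)
        pop2 = generate_population(cfg.population, substream(89, "population"),
                                   gcp_spec=bundle.gcp)
        order = np.random.default_rng(0).permutation(pop2.n)
        pop2 = pop2.permuted(order)
        for _ in range(4):
            advance_year(pop1, bundle, cfg)
            advance_year(pop2, bundle, cfg)
        inv = np.argsort(order)
        assert np.allclose(pop1.current("sbp"), pop2.current("sbp")[inv])
        assert np.array_equal(pop1.death_wave, pop2.death_wave[inv])
        assert np.array_equal(pop1.dementia_wave, pop2.dementia_wave[inv])


class TestRun:
    def test_smoke_run_writes_artifacts(self, bundle, tmp_path):
        cfg = cs.SimulationConfig(population=PopulationConfig(n=100), horizon=3,
                                  master_seed=91)
        res = run(cfg, bundle=bundle, out_dir=tmp_path)
        assert len(res.snapshots) == 3
        for name in ("snapshots.csv", "events.csv", "qalys.csv", "manifest.json"):
            assert (tmp_path / name).exists()
        assert res.manifest["master_seed"] == 91

    def test_until_all_dead_terminates(self, bundle):
        cfg = cs.SimulationConfig(population=PopulationConfig(n=150),
                                  horizon="until_all_dead", master_seed=93)
        res = run(cfg, bundle=bundle)
        assert not res.population.alive.any()
        # forced mortality at the terminal age bounds the horizon
        assert res.population.wave <= 110 - 18 + 1

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError):
            cs.SimulationConfig(horizon="forever")
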