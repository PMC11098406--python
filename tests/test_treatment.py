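"""BP treatment application and trial-anchored event rollback."""

import numpy as np
import pytest

from chronosim.events import OutcomeEvent
from chronosim.population import PopulationConfig, generate_population
from chronosim.rng import substream
from chronosim.treatment import (
    RecalibrationStandard,
    TreatmentStrategy,
    apply_bp_treatment,
    recalibrate_treatment_effects,
    usual_care,
)


@pytest.fixture()
def pop(bundle):
    return generate_population(PopulationConfig(n=100), substream(61, "population"),
                               gcp_spec=bundle.gcp)


class TestApplyTreatment:
    def test_one_med_lowers_bp_by_trial_means(self, pop):
        pop.series["sbp"][0][:] = 140.0
        pop.series["dbp"][0][:] = 90.0
        strat = TreatmentStrategy(kind="add_n_meds_once", n_meds=1, start_wave=0)
        apply_bp_treatment(pop, strat, 0)
        assert np.allclose(pop.series["sbp"][0], 134.5)
        assert np.allclose(pop.series["dbp"][0], 86.9)
        assert np.allclose(pop.strategy_meds, 1.0)

    def test_usual_care_is_noop(self, pop):
        before = pop.series["sbp"][0].copy()
        apply_bp_treatment(pop, usual_care(), 0)
        assert np.array_equal(pop.series["sbp"][0], before)
        assert pop.strategy_meds.sum() == 0

    def test_two_meds_scale_linearly(self, pop):
        sbp0 = pop.series["sbp"][0].copy()
        dbp0 = pop.series["dbp"][0].copy()
        strat = TreatmentStrategy(kind="add_n_meds_once", n_meds=2, start_wave=0)
        apply_bp_treatment(pop, strat, 0)
        assert np.allclose(sbp0 - pop.series["sbp"][0], 11.0)
        assert np.allclose(dbp0 - pop.series["dbp"][0], 6.2)

    def test_eligibility_predicate_restricts_treated_set(self, pop):
        mask = np.zeros(pop.n, bool)
        mask[:10] = True
        strat = TreatmentStrategy(kind="add_n_meds_once", n_meds=1, start_wave=0,
                                  eligibility=lambda p: mask)
        apply_bp_treatment(pop, strat, 0)
        assert pop.strategy_meds.sum() == 10

    def test_reapply_every_wave_accumulates(self, pop):
        strat = TreatmentStrategy(kind="add_n_meds_every_wave", n_meds=1, start_wave=0)
        apply_bp_treatment(pop, strat, 0)
        apply_bp_treatment(pop, strat, 0)  # same wave index; strategy logic drives it
        assert np.allclose(pop.strategy_meds, 2.0)

    def test_invalid_strategy_rejected(self):
        with pytest.raises(ValueError):
            TreatmentStrategy(kind="sprinkle_meds")
        with pytest.raises(ValueError):
            RecalibrationStandard(rr_stroke_per_med=1.2)


def setup_rollback_pop(bundle, n=10, p_event=0.05):
    """Toy population: everyone treated, equal untreated risks, stroke events
    pre-recorded for all."""
    pop = generate_population(PopulationConfig(n=n), substream(62, "population"),
                              gcp_spec=bundle.gcp)
    pop.strategy_meds[:] = 1.0
    for i in range(n):
        pop.events.append(OutcomeEvent(person_id=i, kind="stroke", wave=0))
        pop.first_stroke_wave[i] = 0
    return pop


class TestRollback:
    def test_no_treated_individuals_is_noop(self, pop, bundle):
        audits = recalibrate_treatment_effects(pop, RecalibrationStandard(), 0,
                                               substream(1, "rb"), bundle.pce,
                                               bundle.partition)
        assert audits == []

    def test_null_treatment_rr_one_no_rollback(self, bundle):
        pop = setup_rollback_pop(bundle, n=10)
        # rr = 1 and no BP effect: target equals expected events; with tiny
        # per-person probabilities the deficit is ~ E_real - sum(p) > 0, so
        # force equality by monkey-setting rr=1 and p_untreated ~ realized.
        std = RecalibrationStandard(rr_stroke_per_med=1.0, rr_mi_per_med=1.0,
                                    sbp_lowering_per_med=0.0, dbp_lowering_per_med=0.0)
        import chronosim.treatment as tr

        orig = tr.untreated_event_probabilities
        tr.untreated_event_probabilities = lambda *a, **k: (np.full(pop.n, 1.0),
                                                            np.zeros(pop.n))
        try:
            audits = recalibrate_treatment_effects(pop, std, 0, substream(2, "rb"),
                                                   bundle.pce, bundle.partition)
        finally:
            tr.untreated_event_probabilities = orig
        stroke = next(a for a in audits if a["kind"] == "stroke")
        assert stroke["deficit"] == pytest.approx(0.0)
        assert stroke["n_rolled_back"] == 0

    def test_exact_deficit_rolls_back_exactly(self, bundle):
        """10 treated with equal risks, E_real = 10, E_target = 8 -> exactly
        2 rolled back; reported = organic - rolled back."""
        pop = setup_rollback_pop(bundle, n=10)
        import chronosim.treatment as tr

        orig = tr.untreated_event_probabilities
        tr.untreated_event_probabilities = lambda *a, **k: (np.full(pop.n, 0.8),
                                                            np.zeros(pop.n))
        try:
            std = RecalibrationStandard(rr_stroke_per_med=1.0)
            audits = recalibrate_treatment_effects(pop, std, 0, substream(3, "rb"),
                                                   bundle.pce, bundle.partition)
        finally:
            tr.untreated_event_probabilities = orig
        stroke = next(a for a in audits if a["kind"] == "stroke")
        assert stroke["e_target"] == pytest.approx(8.0)
        assert stroke["n_rolled_back"] == 2
        assert pop.event_count("stroke") == 8
        assert pop.event_count("stroke", include_rolled_back=True) == 10

    def test_equal_weights_selection_is_uniform(self, bundle):
        """With equal untreated risks every event-haver is equally likely to
        be rolled back (checked against the exhaustive uniform frequency)."""
        n, reps = 6, 1000
        counts = np.zeros(n)
        for r in range(reps):
            pop = setup_rollback_pop(bundle, n=n)
            import chronosim.treatment as tr

            orig = tr.untreated_event_probabilities
            tr.untreated_event_probabilities = lambda *a, **k: (np.full(pop.n, 0.5),
                                                                np.zeros(pop.n))
            try:
                recalibrate_treatment_effects(pop, RecalibrationStandard(rr_stroke_per_med=1.0),
                                              0, substream(r, "rb"), bundle.pce,
                                              bundle.partition)
            finally:
                tr.untreated_event_probabilities = orig
            for e in pop.events:
                if e.rolled_back:
                    counts[e.person_id] += 1
        # each person selected in 3/6 of draws (3 of 6 rolled back each rep)
        freq = counts / reps
        se = np.sqrt(0.5 * 0.5 / reps)
        assert np.all(np.abs(freq - 0.5) < 4 * se)

    def test_higher_risk_selected_less_often(self, bundle):
        """Inverse-risk weighting: rollback frequency decreases with
        untreated risk (negative rank correlation over repeated draws)."""
        from scipy.stats import spearmanr

        n, reps = 8, 800
        risks = np.linspace(0.55, 0.95, n)
        counts = np.zeros(n)
        for r in range(reps):
            pop = setup_rollback_pop(bundle, n=n)
            import chronosim.treatment as tr

            orig = tr.untreated_event_probabilities
            tr.untreated_event_probabilities = lambda *a, **k: (risks.copy(),
                                                                np.zeros(pop.n))
            try:
                recalibrate_treatment_effects(pop, RecalibrationStandard(rr_stroke_per_med=1.0),
                                              0, substream(r, "rb"), bundle.pce,
                                              bundle.partition)
            finally:
                tr.untreated_event_probabilities = orig
            for e in pop.events:
                if e.rolled_back:
                    counts[e.person_id] += 1
        rho = spearmanr(risks, counts).statistic
        assert rho < -0.8

    def test_rolled_back_fatal_event_restores_life(self, bundle):
        pop = setup_rollback_pop(bundle, n=4)
        pop.events[0].fatal = True
        pop.alive[0] = False
        pop.death_wave[0] = 0
        pop.death_cause[0] = 1
        import chronosim.treatment as tr

        orig = tr.untreated_event_probabilities
        tr.untreated_event_probabilities = lambda *a, **k: (np.full(pop.n, 1e-6),
                                                            np.zeros(pop.n))
        try:
            recalibrate_treatment_effects(pop, RecalibrationStandard(), 0,
                                          substream(5, "rb"), bundle.pce, bundle.partition)
        finally:
            tr.untreated_event_probabilities = orig
        # nearly all events rolled back, including the fatal one
        assert pop.events[0].rolled_back
        assert pop.alive[0] and pop.death_wave[0] == -1 and pop.death_cause[0] == 0

    def test_deficit_beyond_candidates_rolls_back_all_with_shortfall(self, bundle):
        pop = setup_rollback_pop(bundle, n=3)
        import chronosim.treatment as tr

        orig = tr.untreated_event_probabilities
        tr.untreated_event_probabilities = lambda *a, **k: (np.full(pop.n, 1e-9),
                                                            np.zeros(pop.n))
        try:
            # fake extra realized events to push the deficit beyond candidates
            pop.events.append(OutcomeEvent(person_id=0, kind="stroke", wave=0))
            audits = recalibrate_treatment_effects(pop, RecalibrationStandard(), 0,
                                                   substream(6, "rb"), bundle.pce,
                                                   bundle.partition)
        finally:
            tr.untreated_event_probabilities = orig
        stroke = next(a for a in audits if a["kind"] == "stroke")
        assert stroke["n_rolled_back"] == 4
        assert pop.event_count("stroke") == 0
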