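"""The annual simulation loop, run orchestration and calibration runners.

Rules are applied sequentially each wave: risk factors are updated from a
frozen snapshot of the prior wave, treatment is applied, cognition advances,
then clinical outcomes are assigned from the updated factor levels (ASCVD
events with fatality, dementia onset, non-CV death), then population-level
treatment recalibration rolls back excess events, and finally QALYs accrue.
A fatal CV event short-circuits the later draws in that wave; dementia and
death are absorbing.

Every stochastic component draws from a named (master_seed, stream, wave)
substream in person-id order, so runs are bit-reproducible, invariant to
person storage order, and toggling one component does not perturb the draws
of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .ascvd import FatalitySpec, assign_ascvd_events
from .cognition import (
    TargetIncidenceCurve,
    annual_dementia_probability,
    recalibrate_baseline_hazard,
    update_gcp,
)
from .defaults import ModelBundle, default_bundle
from .events import OutcomeEvent
from .mortality import (
    LifeTable,
    age_specific_death_probability,
    non_cv_death_probability,
    recalibrate_age_coefficients,
)
from .population import Population, PopulationConfig, generate_population
from .qaly import UtilityTable, annual_qaly_wave
from .riskfactors import advance_counterfactual_bp, advance_risk_factors
from .rng import person_uniform, stream_factory, substream
from .treatment import (
    RecalibrationStandard,
    TreatmentStrategy,
    apply_bp_treatment,
    recalibrate_treatment_effects,
    usual_care,
)

__all__ = ["SimulationConfig", "RunResult", "advance_year", "run",
           "calibrate_mortality", "calibrate_dementia", "add_one_med_experiment"]


@dataclass
class SimulationConfig:
    """Everything one simulation run needs.

    ``horizon`` is a number of annual waves or ``"until_all_dead"``
    (termination is guaranteed by ``max_age``, the age at which death is
    forced, mirroring the life table's terminal qx of 1).
    """

    population: PopulationConfig = field(default_factory=PopulationConfig)
    horizon: int | str = 10
    master_seed: int = 0
    strategy: TreatmentStrategy = field(default_factory=usual_care)
    standard: RecalibrationStandard = field(default_factory=RecalibrationStandard)
    fatality: FatalitySpec = field(default_factory=FatalitySpec)
    utility: UtilityTable = field(default_factory=UtilityTable)
    annualization: str = "constant_hazard"
    recalibrate_treatment: bool = True
    max_age: float = 110.0
    model_dir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.horizon, str) and self.horizon != "until_all_dead":
            raise ValueError("horizon must be an integer or 'until_all_dead'")

    def n_waves_limit(self) -> int:
        if self.horizon == "until_all_dead":
            return 200  # safety rail; max_age forces termination well before
        return int(self.horizon)


@dataclass
class RunResult:
    population: Population
    snapshots: pd.DataFrame
    audits: list[dict]
    manifest: dict[str, Any]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.snapshots.to_csv(out / "snapshots.csv", index=False)
        events = pd.DataFrame(
            [
                {"person_id": e.person_id, "wave": e.wave, "kind": e.kind,
                 "fatal": e.fatal, "rolled_back": e.rolled_back}
                for e in self.population.events
            ]
        )
        events.to_csv(out / "events.csv", index=False)
        qalys = pd.DataFrame(
            {"person_id": self.population.ids,
             "lifetime_qalys": np.sum(self.population.qalys, axis=0)
             if self.population.qalys else np.zeros(self.population.n)}
        )
        qalys.to_csv(out / "qalys.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)


def advance_year(
    pop: Population,
    bundle: ModelBundle,
    config: SimulationConfig,
) -> dict[str, Any]:
    """Advance the population one wave; returns a snapshot record."""
    t = pop.wave
    w = t + 1
    rng_for = stream_factory(config.master_seed, wave=w)
    alive_at_start = int(pop.alive.sum())

    # 1. risk factors from the frozen wave-t snapshot, committed atomically
    values = advance_risk_factors(pop, bundle.repo, rng_for)
    pop.commit_wave(values)
    advance_counterfactual_bp(pop, bundle.repo, rng_for, w)

    # 2. treatment strategy (modifies the just-committed wave)
    apply_bp_treatment(pop, config.strategy, w, config.standard)

    # 3. cognition at the new factor levels
    update_gcp(pop, bundle.gcp, rng_for("gcp"))

    # 4. ASCVD events at updated risk-factor levels (fatal events kill now)
    stroke_now, mi_now = assign_ascvd_events(
        pop, bundle.pce, bundle.partition, w,
        rng_for("ascvd_event"), rng_for("ascvd_partition"), rng_for("fatality"),
        config.fatality, config.annualization,
    )
    cv_deaths = int((pop.death_wave == w).sum())

    # 5. dementia onset (absorbing; skipped for this wave's CV deaths)
    p_dem = annual_dementia_probability(pop, bundle.cox, interval_start=t, slope_wave=w)
    eligible = pop.alive & ~pop.has_dementia
    onset = eligible & (person_uniform(rng_for("dementia"), pop) < p_dem)
    pop.dementia_wave[onset] = w
    for i in np.flatnonzero(onset):
        pop.events.append(OutcomeEvent(person_id=int(i), kind="dementia", wave=w))

    # 6. non-CV mortality for survivors; force death above max_age
    p_mort = non_cv_death_probability(pop, bundle.mortality, w)
    dying = pop.alive & (person_uniform(rng_for("mortality"), pop) < p_mort)
    dying |= pop.alive & (pop.series["age"][w] >= config.max_age)
    for i in np.flatnonzero(dying):
        pop.events.append(OutcomeEvent(person_id=int(i), kind="non_cv_death", wave=w))
    pop.alive[dying] = False
    pop.death_wave[dying] = w
    pop.death_cause[dying] = 2
    non_cv_deaths = int(dying.sum())

    # 7. population-level treatment recalibration (event rollback)
    audits: list[dict] = []
    if config.recalibrate_treatment and config.strategy.kind != "usual_care":
        audits = recalibrate_treatment_effects(
            pop, config.standard, w, rng_for("treatment_rollback"),
            bundle.pce, bundle.partition, config.annualization,
        )
        for a in audits:
            now = stroke_now if a["kind"] == "stroke" else mi_now
            for pid in a["rolled_back_ids"]:
                now[pid] = False
    # 8. QALYs after recalibration so rolled-back events never count
    pop.qalys.append(annual_qaly_wave(pop, config.utility, w, stroke_now, mi_now))

    alive_now = int(pop.alive.sum())
    return {
        "wave": w,
        "year": pop.start_year + w,
        "alive_at_start": alive_at_start,
        "alive": alive_now,
        "cv_deaths": cv_deaths,
        "non_cv_deaths": non_cv_deaths,
        "rollback_restorations": alive_now - (alive_at_start - cv_deaths - non_cv_deaths),
        "strokes": int(stroke_now.sum()),
        "mis": int(mi_now.sum()),
        "dementia_onsets": int(onset.sum()),
        "mean_qaly": float(pop.qalys[-1].mean()),
        "audits": audits,
    }


def run(
    config: SimulationConfig,
    bundle: ModelBundle | None = None,
    population: Population | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Initialize (or reuse) a population and advance it to the horizon."""
    bundle = bundle or default_bundle(config.model_dir)
    if population is None:
        rng = substream(config.master_seed, "population")
        population = generate_population(config.population, rng, gcp_spec=bundle.gcp)
    pop = population
    pop.qalys.append(annual_qaly_wave(pop, config.utility, 0,
                                      np.zeros(pop.n, bool), np.zeros(pop.n, bool)))

    records: list[dict] = []
    audits: list[dict] = []
    limit = config.n_waves_limit()
    for _ in range(limit):
        if not pop.alive.any():
            break
        rec = advance_year(pop, bundle, config)
        audits.extend(rec.pop("audits"))
        records.append(rec)

    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "n": pop.n,
        "start_year": pop.start_year,
        "horizon": config.horizon,
        "waves_run": pop.wave,
        "strategy": config.strategy.kind,
        "recalibrate_treatment": config.recalibrate_treatment,
        "annualization": config.annualization,
    }
    result = RunResult(pop, pd.DataFrame(records), audits, manifest)
    if out_dir is not None:
        result.write(out_dir)
    return result


# ---------------------------------------------------------------------------
# calibration runners


def _death_probability_by_age(pop: Population) -> tuple[np.ndarray, np.ndarray]:
    """All-cause age-specific death probability from one finished run."""
    deaths: dict[float, float] = {}
    py: dict[float, float] = {}
    for w in range(1, pop.wave + 1):
        at_risk = (pop.death_wave < 0) | (pop.death_wave >= w)
        ages = np.floor(pop.series["age"][w][at_risk])
        for a in ages:
            py[a] = py.get(a, 0.0) + 1.0
        died = pop.death_wave == w
        for a in np.floor(pop.series["age"][w][died]):
            deaths[a] = deaths.get(a, 0.0) + 1.0
    return age_specific_death_probability(deaths, py)


def calibrate_mortality(
    config: SimulationConfig,
    life_table: LifeTable,
    age_grid,
    age2_grid,
    bundle: ModelBundle | None = None,
) -> tuple[tuple[float, float], dict]:
    """Grid-search the age/age^2 mortality coefficients against a life table.

    Each candidate runs a reduced simulation under the same master seed, so
    the search is deterministic.
    """
    base = bundle or default_bundle(config.model_dir)

    def simulate(beta_age: float, beta_age2: float):
        from dataclasses import replace as _replace

        cand = ModelBundle(
            repo=base.repo, pce=base.pce, partition=base.partition,
            mortality=base.mortality.shifted_age_coefficients(beta_age, beta_age2),
            cox=base.cox, gcp=base.gcp,
        )
        res = run(config, bundle=cand)
        return _death_probability_by_age(res.population)

    return recalibrate_age_coefficients(simulate, life_table, age_grid, age2_grid)


def dementia_incidence_by_age(
    pop: Population, band_width: float = 5.0, age_range=(60.0, 95.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Dementia onsets per person-year at risk by attained-age band."""
    lo, hi = age_range
    edges = np.arange(lo, hi + band_width, band_width)
    onsets = np.zeros(len(edges) - 1)
    py = np.zeros(len(edges) - 1)
    for w in range(1, pop.wave + 1):
        at_risk = ((pop.death_wave < 0) | (pop.death_wave >= w)) & (
            (pop.dementia_wave < 0) | (pop.dementia_wave >= w)
        )
        ages = pop.series["age"][w]
        idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, -1, len(py) - 1)
        ok = (ages >= lo) & (ages < edges[-1]) & at_risk
        np.add.at(py, idx[ok], 1.0)
        new = ok & (pop.dementia_wave == w)
        np.add.at(onsets, idx[new], 1.0)
    mids = (edges[:-1] + edges[1:]) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = np.where(py > 0, onsets / np.maximum(py, 1.0), np.nan)
    keep = py > 0
    return mids[keep], inc[keep]


def calibrate_dementia(
    config: SimulationConfig,
    target: TargetIncidenceCurve,
    grid,
    bundle: ModelBundle | None = None,
    enabled: bool = True,
) -> tuple[tuple[float, float, float], dict]:
    """Grid-search the baseline-hazard quadratic against a target incidence
    curve (self-consistent reduced simulations under a fixed master seed)."""
    base = bundle or default_bundle(config.model_dir)

    def simulate(abc):
        cand = ModelBundle(
            repo=base.repo, pce=base.pce, partition=base.partition,
            mortality=base.mortality, cox=base.cox.with_baseline(abc), gcp=base.gcp,
        )
        res = run(config, bundle=cand)
        return dementia_incidence_by_age(res.population)

    return recalibrate_baseline_hazard(
        simulate, target, grid, enabled=enabled, current=base.cox.baseline
    )


# ---------------------------------------------------------------------------
# the add-one-medication treatment experiment


def _event_rate(pop: Population, kind: str) -> float:
    """Reported (non-rolled-back) events per person-year over the run."""
    events = pop.event_count(kind)
    py = 0.0
    for w in range(1, pop.wave + 1):
        py += float(((pop.death_wave < 0) | (pop.death_wave >= w)).sum())
    return events / py if py else float("nan")


def add_one_med_experiment(
    config: SimulationConfig,
    n_replicates: int = 15,
    bundle: ModelBundle | None = None,
) -> dict[str, Any]:
    """Two-arm experiment: usual care vs one added BP medication for all.

    Each replicate runs both arms under a shared replicate seed (common
    random numbers) and reports the realized stroke/MI rate ratios; the
    across-replicate mean is the quantity anchored to the trial relative
    risks by the rollback recalibration.
    """
    from dataclasses import replace as _replace

    bundle = bundle or default_bundle(config.model_dir)
    rr_stroke, rr_mi = [], []
    for rep in range(n_replicates):
        seed = (config.master_seed + 104729 * (rep + 1)) % (2**31)
        control_cfg = _replace(config, master_seed=seed, strategy=usual_care())
        treated_cfg = _replace(
            config, master_seed=seed,
            strategy=TreatmentStrategy(kind="add_n_meds_once", n_meds=1, start_wave=1),
        )
        control = run(control_cfg, bundle=bundle)
        treated = run(treated_cfg, bundle=bundle)
        for kind, acc in (("stroke", rr_stroke), ("mi", rr_mi)):
            ra = _event_rate(treated.population, kind)
            rb = _event_rate(control.population, kind)
            acc.append(ra / rb if rb else float("nan"))
    return {
        "rr_stroke_mean": float(np.mean(rr_stroke)),
        "rr_stroke_range": (float(np.min(rr_stroke)), float(np.max(rr_stroke))),
        "rr_mi_mean": float(np.mean(rr_mi)),
        "rr_mi_range": (float(np.min(rr_mi)), float(np.max(rr_mi))),
        "replicates": n_replicates,
        "rr_stroke": [float(x) for x in rr_stroke],
        "rr_mi": [float(x) for x in rr_mi],
    }
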