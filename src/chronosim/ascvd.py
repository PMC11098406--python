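"""Annual atherosclerotic cardiovascular disease (ASCVD) events.

Ten-year ASCVD risk is evaluated with a revised Pooled-Cohort-Equations-style
logistic risk model (sex x race coefficient strata over age, treated/untreated
SBP, cholesterol, glycemia, smoking), annualized under a constant-hazard
assumption, and drawn as a Bernoulli event.  Assigned events are partitioned
into stroke vs MI by the inverse logit of a stroke-prediction model over
lagged covariates, and fatality is assigned with fixed case-fatality
probabilities (0.15 stroke, 0.13 MI).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import expit

from .events import OutcomeEvent
from .population import Population
from .rng import person_uniform
from .specs import RegressionSpec, event_probability, linear_predictor

__all__ = [
    "PCESpec",
    "FatalitySpec",
    "ten_year_ascvd_risk",
    "annual_ascvd_probability",
    "stroke_partition_probability",
    "assign_ascvd_events",
    "assign_fatality",
]

# stratum keys: (sex, black?) -> name
_STRATA = {
    (0, True): "female_black",
    (0, False): "female_nonblack",
    (1, True): "male_black",
    (1, False): "male_nonblack",
}
_DEFAULT_STRATUM = "male_nonblack"


@dataclass(frozen=True)
class PCESpec:
    """Stratified 10-year ASCVD risk coefficients (inputs, not computed).

    ``strata`` maps stratum name -> coefficient dict over {intercept, age,
    sbp_untreated, sbp_treated, total_chol, hdl, a1c, smoking_current}.
    Risk = inverse logit of the stratum linear predictor, so output is always
    a probability.
    """

    strata: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, coeffs in self.strata.items():
            if "intercept" not in coeffs:
                raise ValueError(f"PCE stratum {name!r} missing intercept")

    def stratum_for(self, sex: int, is_black: bool) -> str:
        name = _STRATA.get((int(sex), bool(is_black)), _DEFAULT_STRATUM)
        if name not in self.strata:
            warnings.warn(
                f"PCE stratum {name!r} unavailable; falling back to {_DEFAULT_STRATUM!r}"
            )
            name = _DEFAULT_STRATUM
        return name

    @classmethod
    def from_json(cls, path: str | Path) -> "PCESpec":
        with open(path) as fh:
            return cls(strata=json.load(fh))


def ten_year_ascvd_risk(
    pop: Population,
    pce: PCESpec,
    wave: int | None = None,
    sbp: np.ndarray | None = None,
    n_antihypertensives: np.ndarray | None = None,
) -> np.ndarray:
    """Ten-year ASCVD risk per person from current risk-factor levels.

    ``sbp`` / ``n_antihypertensives`` overrides support counterfactual
    (untreated) risk evaluation by the treatment-recalibration step.
    """
    t = pop.wave if wave is None else wave
    sbp = pop.series["sbp"][t] if sbp is None else np.asarray(sbp, dtype=float)
    meds = (
        pop.series["n_antihypertensives"][t]
        if n_antihypertensives is None
        else np.asarray(n_antihypertensives, dtype=float)
    )
    treated = meds > 0
    covs = {
        "age": pop.series["age"][t],
        "sbp_untreated": np.where(treated, 0.0, sbp),
        "sbp_treated": np.where(treated, sbp, 0.0),
        "total_chol": pop.series["total_chol"][t],
        "hdl": pop.series["hdl"][t],
        "a1c": pop.series["a1c"][t],
        "smoking_current": (pop.series["smoking_status"][t] == 2).astype(float),
    }
    lp = np.zeros(pop.n)
    is_black = pop.race == 1
    for (sex, black), _ in _STRATA.items():
        mask = (pop.sex == sex) & (is_black == black)
        if not mask.any():
            continue
        coeffs = pce.strata[pce.stratum_for(sex, black)]
        s = coeffs["intercept"]
        for cov, beta in coeffs.items():
            if cov == "intercept":
                continue
            s = s + beta * covs[cov][mask]
        lp[mask] = s
    return expit(lp)


def annual_ascvd_probability(p10, method: str = "constant_hazard"):
    """Convert 10-year risk to an annual event probability.

    ``constant_hazard`` (default): 1 - (1 - p10)**(1/10); ``linear``: p10/10.
    """
    p10 = np.asarray(p10, dtype=float)
    if method == "constant_hazard":
        out = 1.0 - np.power(1.0 - p10, 0.1)
    elif method == "linear":
        out = p10 / 10.0
    else:
        raise ValueError(f"unknown annualization method {method!r}")
    return out if out.shape else float(out)


def stroke_partition_probability(
    pop: Population, partition_spec: RegressionSpec, wave: int
) -> np.ndarray:
    """P(event is a stroke | ASCVD event), from the stroke-prediction model
    evaluated at lagged covariate values."""
    from .riskfactors import resolve_covariates

    lp = linear_predictor(partition_spec, resolve_covariates(pop, partition_spec, wave))
    return np.asarray(event_probability(partition_spec, lp), dtype=float) * np.ones(pop.n)


@dataclass(frozen=True)
class FatalitySpec:
    """Case-fatality probabilities for acute events."""

    p_stroke: float = 0.15
    p_mi: float = 0.13


def assign_fatality(
    event: OutcomeEvent, rng: np.random.Generator, fatality: FatalitySpec = FatalitySpec()
) -> OutcomeEvent:
    """Randomly mark a stroke/MI event fatal with the calibrated probability."""
    if event.kind not in ("stroke", "mi"):
        raise ValueError(f"fatality applies to stroke/mi, not {event.kind!r}")
    p = fatality.p_stroke if event.kind == "stroke" else fatality.p_mi
    event.fatal = bool(rng.random() < p)
    return event


def assign_ascvd_events(
    pop: Population,
    pce: PCESpec,
    partition_spec: RegressionSpec,
    wave: int,
    rng_event: np.random.Generator,
    rng_partition: np.random.Generator,
    rng_fatality: np.random.Generator,
    fatality: FatalitySpec = FatalitySpec(),
    annualization: str = "constant_hazard",
    annual_probability_override: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw at most one ASCVD event per living person for this wave.

    Risk is evaluated at the just-updated factor levels (wave ``wave``);
    the stroke/MI partition uses lagged (wave - 1) covariates.  Fatal events
    kill the person in this wave (CV death) and short-circuit later rules.
    Returns boolean arrays (stroke_now, mi_now) of organic events.
    """
    if annual_probability_override is not None:
        p_annual = np.asarray(annual_probability_override, dtype=float) * np.ones(pop.n)
    else:
        p10 = ten_year_ascvd_risk(pop, pce, wave)
        p_annual = annual_ascvd_probability(p10, annualization)
    u = person_uniform(rng_event, pop)
    has_event = pop.alive & (u < p_annual)

    p_stroke = stroke_partition_probability(pop, partition_spec, max(wave - 1, 0))
    is_stroke = person_uniform(rng_partition, pop) < p_stroke
    u_fatal = person_uniform(rng_fatality, pop)

    stroke_now = has_event & is_stroke
    mi_now = has_event & ~is_stroke
    fatal = np.where(is_stroke, u_fatal < fatality.p_stroke, u_fatal < fatality.p_mi) & has_event

    for i in np.flatnonzero(has_event):
        kind = "stroke" if is_stroke[i] else "mi"
        pop.events.append(
            OutcomeEvent(person_id=int(i), kind=kind, wave=wave, fatal=bool(fatal[i]))
        )
    pop.first_stroke_wave[stroke_now & (pop.first_stroke_wave < 0)] = wave
    pop.first_mi_wave[mi_now & (pop.first_mi_wave < 0)] = wave
    died = np.flatnonzero(fatal)
    pop.alive[died] = False
    pop.death_wave[died] = wave
    pop.death_cause[died] = 1  # CV death
    return stroke_now, mi_now
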