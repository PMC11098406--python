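"""Non-cardiovascular mortality and its life-table recalibration.

Annual non-CV death is drawn from a logistic model over age, age squared,
demographics, long-run mean blood pressure and other vascular covariates.
Two variants exist — one for persons with no dementia history and one for
persons with dementia (higher mortality) — selected per person each wave.

Because a logistic model fitted at the person-year level under-predicts
old-age mortality when embedded in the full simulation, the age and
age-squared coefficients are recalibrated by grid search: candidate
coefficient pairs are evaluated by running reduced simulations and choosing
the pair whose age-specific simulated death probabilities deviate least (in
summed squared error) from a reference life table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .population import Population
from .specs import RegressionSpec, event_probability, linear_predictor

__all__ = [
    "LifeTable",
    "NonCVMortalitySpec",
    "non_cv_death_probability",
    "age_specific_death_probability",
    "recalibrate_age_coefficients",
]


@dataclass(frozen=True)
class LifeTable:
    """Age-specific annual death probabilities (qx)."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        qx = np.asarray(self.qx, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("life-table ages must be strictly increasing")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life-table qx must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    def __call__(self, ages) -> np.ndarray:
        return np.interp(np.asarray(ages, dtype=float), self.ages, self.qx)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


@dataclass(frozen=True)
class NonCVMortalitySpec:
    """Variant-selected logistic mortality model.

    ``dementia`` defaults to the no-history spec shifted by a log-odds
    offset when explicit dementia-specific coefficients are unavailable.
    """

    no_history: RegressionSpec
    dementia: RegressionSpec

    @classmethod
    def with_offset(cls, no_history: RegressionSpec, dementia_log_odds_offset: float = 1.5):
        coeffs = dict(no_history.coefficients)
        coeffs["intercept"] = coeffs["intercept"] + dementia_log_odds_offset
        dem = replace(no_history, name=no_history.name + "_dementia", coefficients=coeffs)
        return cls(no_history=no_history, dementia=dem)

    def select(self, has_dementia: bool) -> RegressionSpec:
        return self.dementia if has_dementia else self.no_history

    def shifted_age_coefficients(self, beta_age: float, beta_age2: float) -> "NonCVMortalitySpec":
        """Copy with the age/age-squared coefficients replaced in both variants."""
        def patch(spec: RegressionSpec) -> RegressionSpec:
            coeffs = dict(spec.coefficients)
            coeffs["age"] = beta_age
            coeffs["age_squared"] = beta_age2
            return replace(spec, coefficients=coeffs)

        return NonCVMortalitySpec(no_history=patch(self.no_history), dementia=patch(self.dementia))


def non_cv_death_probability(
    pop: Population, spec: NonCVMortalitySpec, wave: int
) -> np.ndarray:
    """Inverse-logit annual non-CV death probability, variant-selected by
    dementia status, evaluated at wave ``wave`` covariates."""
    from .riskfactors import resolve_covariates

    p_no = event_probability(
        spec.no_history,
        linear_predictor(spec.no_history, resolve_covariates(pop, spec.no_history, wave)),
    )
    p_dem = event_probability(
        spec.dementia,
        linear_predictor(spec.dementia, resolve_covariates(pop, spec.dementia, wave)),
    )
    return np.where(pop.has_dementia, p_dem, p_no)


def age_specific_death_probability(
    deaths_by_age: dict[float, float],
    person_years_by_age: dict[float, float],
    min_person_years: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Death probability per 1-year age bin, merging sparse bins upward.

    Bins with fewer than ``min_person_years`` person-years are pooled into the
    next-higher bin; a sparse terminal bin is reported as-is.
    """
    ages = np.array(sorted(person_years_by_age))
    merged_ages, merged_d, merged_py = [], [], []
    carry_d = carry_py = 0.0
    for a in ages:
        carry_d += deaths_by_age.get(a, 0.0)
        carry_py += person_years_by_age[a]
        if carry_py >= min_person_years:
            merged_ages.append(a)
            merged_d.append(carry_d)
            merged_py.append(carry_py)
            carry_d = carry_py = 0.0
    if carry_py > 0 and merged_ages:
        merged_d[-1] += carry_d
        merged_py[-1] += carry_py
    elif carry_py > 0:
        merged_ages.append(ages[-1])
        merged_d.append(carry_d)
        merged_py.append(carry_py)
    merged_py = np.asarray(merged_py, dtype=float)
    return np.asarray(merged_ages, dtype=float), np.asarray(merged_d) / merged_py


def recalibrate_age_coefficients(
    simulate_mortality: Callable[[float, float], tuple[np.ndarray, np.ndarray]],
    life_table: LifeTable,
    age_grid,
    age2_grid,
) -> tuple[tuple[float, float], dict]:
    """Grid-search (beta_age, beta_age2) against the life table.

    ``simulate_mortality(beta_age, beta_age2)`` runs a reduced simulation and
    returns (ages, age-specific death probability).  The candidate minimizing
    the summed squared deviation from the life table over the simulated age
    span wins; the caller is responsible for using a fixed master seed per
    candidate so the search is deterministic.
    """
    grid = [(float(b1), float(b2)) for b1 in age_grid for b2 in age2_grid]
    if not grid:
        raise ValueError("empty recalibration grid")
    objective = {}
    for b1, b2 in grid:
        ages, phat = simulate_mortality(b1, b2)
        objective[(b1, b2)] = float(np.sum((phat - life_table(ages)) ** 2))
    best = min(objective, key=objective.get)
    return best, {"grid": grid, "objective": objective, "argmin": best}
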