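"""Global cognitive performance (GCP) dynamics and all-cause dementia risk.

GCP is a co-calibrated continuous cognition factor score (1 point = 0.1 SD of
the pooled cognition distribution; higher is better).  Each person carries a
time-constant random intercept drawn at baseline; annual GCP is the fixed
linear prediction from vascular/demographic covariates plus that random
effect plus a residual draw.

Annual dementia risk comes from a proportional-hazards model whose covariates
are baseline GCP, realized GCP slope, baseline age, sex, education and
race/ethnicity, with an exp-quadratic baseline cumulative hazard

    H0(t) = exp(a + b*t + c*t^2) - exp(a)

anchored so H0(0) = 0 and nondecreasing while b + 2*c*t >= 0.  The (a, b, c)
parameters are subject to grid-search recalibration against a target
age-incidence curve; that recalibration can be switched off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .population import EDUCATION_LEVELS, Population
from .specs import RegressionSpec, linear_predictor

__all__ = [
    "GCPModelSpec",
    "DementiaCoxSpec",
    "TargetIncidenceCurve",
    "default_gcp_spec",
    "default_dementia_cox_spec",
    "initialize_gcp",
    "update_gcp",
    "dementia_linear_predictor",
    "annual_dementia_probability",
    "simulate_dementia_times",
    "cox_recovery_experiment",
    "recalibrate_baseline_hazard",
]


class StateError(RuntimeError):
    pass


@dataclass(frozen=True)
class GCPModelSpec:
    """Mixed-model specification for GCP: fixed effects + variance components.

    ``random_intercept_sd`` and ``residual_sd`` are in GCP points.
    """

    fixed: RegressionSpec
    random_intercept_sd: float = 7.0
    residual_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("GCP variance components must be >= 0")


def default_gcp_spec() -> GCPModelSpec:
    """Illustrative GCP fixed-effects model (coefficients are inputs, not
    cohort-fitted ground truth); intercept set so the default baseline cohort
    averages about 50 points."""
    from .population import (
        DEFAULT_EDUCATION_FREQS,
        DEFAULT_MARGINALS,
        DEFAULT_RACE_FREQS,
        DEFAULT_SEX_FREQS,
    )

    coeffs = {
        "age": -0.30,
        "sex_male": -1.0,
        "log_sbp": -3.0,
        "bmi": -0.05,
        "education_less_than_high_school": -5.0,
        "education_some_high_school": -4.0,
        "education_high_school_grad": -2.5,
        "education_some_college": -1.0,
        "race_nh_black": -3.0,
        "race_hispanic": -2.0,
        "race_other": -1.0,
    }
    means = {
        "age": DEFAULT_MARGINALS["age"].mean,
        "sex_male": DEFAULT_SEX_FREQS["male"],
        "log_sbp": float(np.log(DEFAULT_MARGINALS["sbp"].mean)),
        "bmi": DEFAULT_MARGINALS["bmi"].mean,
        "education_less_than_high_school": DEFAULT_EDUCATION_FREQS["less_than_high_school"],
        "education_some_high_school": DEFAULT_EDUCATION_FREQS["some_high_school"],
        "education_high_school_grad": DEFAULT_EDUCATION_FREQS["high_school_grad"],
        "education_some_college": DEFAULT_EDUCATION_FREQS["some_college"],
        "race_nh_black": DEFAULT_RACE_FREQS["nh_black"],
        "race_hispanic": DEFAULT_RACE_FREQS["hispanic"],
        "race_other": DEFAULT_RACE_FREQS["other"],
    }
    intercept = 50.0 - sum(coeffs[k] * means[k] for k in coeffs)
    kinds = {k: ("static" if k.startswith(("sex_", "race_", "education_")) else "current") for k in coeffs}
    fixed = RegressionSpec(
        name="gcp_fixed_effects",
        family="linear",
        outcome="gcp",
        coefficients={"intercept": intercept, **coeffs},
        covariate_kinds=kinds,
    )
    return GCPModelSpec(fixed=fixed)


def initialize_gcp(pop: Population, gcp_spec: GCPModelSpec, rng: np.random.Generator) -> None:
    """Assign baseline GCP: fixed linear prediction + per-person random effect.

    The random effect is drawn once and stored; no residual is added at
    baseline.
    """
    from .riskfactors import resolve_covariates

    from .rng import person_normal

    pop.gcp_random_effect = person_normal(rng, pop, 0.0, gcp_spec.random_intercept_sd)
    lp = linear_predictor(gcp_spec.fixed, resolve_covariates(pop, gcp_spec.fixed, 0))
    pop.series["gcp"][0] = np.broadcast_to(np.asarray(lp, dtype=float), (pop.n,)) + pop.gcp_random_effect


def update_gcp(pop: Population, gcp_spec: GCPModelSpec, rng: np.random.Generator) -> None:
    """Recompute GCP at the last committed wave.

    GCP_t = fixed linear prediction (wave-t covariates) + stored random
    effect + residual draw.  Dead persons keep their carried-forward value.
    """
    from .riskfactors import resolve_covariates

    t = pop.wave
    lp = linear_predictor(gcp_spec.fixed, resolve_covariates(pop, gcp_spec.fixed, t))
    from .rng import person_normal

    eps = person_normal(rng, pop, 0.0, gcp_spec.residual_sd)
    new = np.broadcast_to(np.asarray(lp, dtype=float), (pop.n,)) + pop.gcp_random_effect + eps
    pop.series["gcp"][t] = np.where(pop.alive, new, pop.series["gcp"][t])


def gcp_slope(pop: Population, wave: int | None = None) -> np.ndarray:
    """Realized GCP change per year since baseline: (GCP_t - GCP_0) / t."""
    t = pop.wave if wave is None else wave
    if t <= 0:
        return np.zeros(pop.n)
    return (pop.series["gcp"][t] - pop.series["gcp"][0]) / t


@dataclass(frozen=True)
class DementiaCoxSpec:
    """Proportional-hazards dementia model: hazard ratios + baseline hazard.

    ``hazard_ratios`` maps covariate names to HRs (logs are taken at
    evaluation time).  ``references`` centers continuous covariates so the
    baseline hazard refers to an interpretable reference profile.
    ``baseline`` holds the exp-quadratic parameters (a, b, c).
    """

    hazard_ratios: dict[str, float]
    references: dict[str, float] = field(default_factory=dict)
    baseline: tuple[float, float, float] = (-3.06, 0.10259, 0.0)

    def log_hrs(self) -> dict[str, float]:
        return {k: float(np.log(v)) for k, v in self.hazard_ratios.items()}

    def cumulative_hazard(self, t) -> np.ndarray:
        a, b, c = self.baseline
        t = np.asarray(t, dtype=float)
        return np.exp(a + b * t + c * t * t) - np.exp(a)

    def with_baseline(self, abc) -> "DementiaCoxSpec":
        return replace(self, baseline=tuple(float(x) for x in abc))

    def to_dict(self) -> dict:
        return {
            "hazard_ratios": dict(self.hazard_ratios),
            "references": dict(self.references),
            "baseline": list(self.baseline),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "DementiaCoxSpec":
        return cls(
            hazard_ratios={str(k): float(v) for k, v in payload["hazard_ratios"].items()},
            references={str(k): float(v) for k, v in payload.get("references", {}).items()},
            baseline=tuple(payload.get("baseline", (-3.06, 0.10259, 0.0))),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DementiaCoxSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_dementia_cox_spec() -> DementiaCoxSpec:
    """Published pooled-cohort hazard ratios for all-cause dementia.

    Hispanic and other race/ethnicity contrasts are unavailable from the
    source model and are treated as HR 1.0 (a known limitation).  The
    baseline (a, b, c) defaults give a reference-profile annual hazard that
    doubles roughly every 7 years of simulation time; it is the quantity the
    incidence recalibration searches over.
    """
    return DementiaCoxSpec(
        hazard_ratios={
            "baseline_gcp": 0.927,
            "gcp_slope": 0.999,
            "baseline_age": 1.108,
            "sex_female": 1.1,
            "education_less_than_high_school": 1.032,
            "education_some_high_school": 1.088,
            "education_high_school_grad": 0.919,
            "education_some_college": 0.797,
            "race_nh_black": 1.214,
        },
        references={"baseline_gcp": 50.0, "baseline_age": 75.0},
    )


def _cox_covariates(pop: Population, slope_wave: int) -> dict[str, np.ndarray]:
    covs = {
        "baseline_gcp": pop.series["gcp"][0],
        "gcp_slope": gcp_slope(pop, slope_wave),
        "baseline_age": pop.series["age"][0],
        "sex_female": (pop.sex == 0).astype(float),
        "race_nh_black": (pop.race == 1).astype(float),
    }
    for i, level in enumerate(EDUCATION_LEVELS[:-1]):
        covs[f"education_{level}"] = (pop.education == i).astype(float)
    return covs


def dementia_linear_predictor(cox: DementiaCoxSpec, covariates: Mapping[str, np.ndarray]):
    """Sum of log-HR * (covariate - reference) over the model's covariates."""
    lp = 0.0
    for name, log_hr in cox.log_hrs().items():
        x = np.asarray(covariates[name], dtype=float) - cox.references.get(name, 0.0)
        lp = lp + log_hr * x
    return lp


def annual_dementia_probability(
    pop: Population,
    cox: DementiaCoxSpec,
    interval_start: int,
    slope_wave: int | None = None,
) -> np.ndarray:
    """Probability of dementia onset in (t, t+1] for every person.

    p = 1 - exp(-(H0(t+1) - H0(t)) * exp(lp)).  The engine masks to alive,
    dementia-free persons; dementia is absorbing.
    """
    t = interval_start
    increment = cox.cumulative_hazard(t + 1) - cox.cumulative_hazard(t)
    covs = _cox_covariates(pop, pop.wave if slope_wave is None else slope_wave)
    lp = dementia_linear_predictor(cox, covs)
    return 1.0 - np.exp(-increment * np.exp(lp))


def person_annual_dementia_probability(person, cox: DementiaCoxSpec, interval_start: int) -> float:
    """Per-person wrapper; raises StateError if the person already has dementia."""
    pop = person._pop
    if pop.dementia_wave[person.id] >= 0:
        raise StateError(f"person {person.id} already has dementia")
    return float(annual_dementia_probability(pop, cox, interval_start)[person.id])


def simulate_dementia_times(
    cox: DementiaCoxSpec,
    covariates: Mapping[str, np.ndarray],
    horizon: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw continuous event times from the implemented hazard by inversion.

    Solves H0(T) = E / exp(lp) with E ~ Exp(1) in closed form (the
    exp-quadratic cumulative hazard inverts via a quadratic in T).  Times
    past ``horizon`` are censored there.  Returns (time, observed).
    """
    lp = np.asarray(dementia_linear_predictor(cox, covariates), dtype=float)
    n = lp.shape[0]
    a, b, c = cox.baseline
    q = rng.exponential(size=n) / np.exp(lp)
    rhs = np.log(q + np.exp(a))  # = a + b*T + c*T^2
    if c == 0.0:
        t_event = (rhs - a) / b
    else:
        disc = b * b - 4.0 * c * (a - rhs)
        t_event = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * c)
    observed = t_event <= horizon
    return np.where(observed, t_event, horizon), observed


def recalibrate_baseline_hazard(
    simulate_incidence: Callable[[tuple[float, float, float]], tuple[np.ndarray, np.ndarray]],
    target: "TargetIncidenceCurve",
    grid,
    enabled: bool = True,
    current: tuple[float, float, float] | None = None,
) -> tuple[tuple[float, float, float], dict]:
    """Grid-search (a, b, c) minimizing squared deviation from a target curve.

    ``simulate_incidence(abc)`` must run a reduced simulation and return
    (ages, incidence per person-year).  With ``enabled=False`` the current
    parameters are returned untouched.  Returns (argmin, report).
    """
    grid = [tuple(float(x) for x in g) for g in grid]
    if not enabled:
        if current is None:
            raise ValueError("recalibration disabled but no current parameters supplied")
        return tuple(current), {"enabled": False, "grid": grid, "objective": {}}
    if not grid:
        raise ValueError("empty recalibration grid")
    objective = {}
    for abc in grid:
        ages, incidence = simulate_incidence(abc)
        objective[abc] = float(np.sum((np.asarray(incidence) - target(np.asarray(ages))) ** 2))
    best = min(objective, key=objective.get)
    return best, {"enabled": True, "grid": grid, "objective": objective, "argmin": best}


def cox_recovery_experiment(
    cox: DementiaCoxSpec | None = None,
    n: int = 100_000,
    horizon: float = 20.0,
    seed: int = 0,
) -> dict:
    """Simulate-then-refit parameter recovery for the dementia hazard.

    Draws a synthetic covariate sample (ages 65-90, GCP ~ N(50, 10), fixed
    per-person GCP slopes), simulates continuous onset times from the
    implemented hazard, refits a proportional-hazards model with the same
    covariates (lifelines), and reports fitted hazard ratios with 95% CIs.
    """
    import pandas as pd
    from lifelines import CoxPHFitter

    cox = cox or default_dementia_cox_spec()
    rng = np.random.default_rng(seed)
    covs = {
        "baseline_gcp": rng.normal(50.0, 10.0, n),
        "gcp_slope": rng.normal(0.0, 1.0, n),
        "baseline_age": rng.uniform(65.0, 90.0, n),
        "sex_female": (rng.random(n) < 0.55).astype(float),
        "race_nh_black": (rng.random(n) < 0.12).astype(float),
    }
    edu = rng.integers(0, 5, n)
    for i, level in enumerate(EDUCATION_LEVELS[:-1]):
        covs[f"education_{level}"] = (edu == i).astype(float)
    times, observed = simulate_dementia_times(cox, covs, horizon, rng)
    df = pd.DataFrame(covs)
    df["time"] = times
    df["observed"] = observed
    fit = CoxPHFitter().fit(df, duration_col="time", event_col="observed")
    out = {"n": n, "events": int(observed.sum()), "hazard_ratios": {}}
    for name in cox.hazard_ratios:
        row = fit.summary.loc[name]
        out["hazard_ratios"][name] = {
            "hr": float(np.exp(row["coef"])),
            "lo": float(np.exp(row["coef lower 95%"])),
            "hi": float(np.exp(row["coef upper 95%"])),
            "configured": cox.hazard_ratios[name],
        }
    return out


@dataclass(frozen=True)
class TargetIncidenceCurve:
    """Target age-specific dementia incidence (events per person-year).

    Either parametric exponential-doubling, I(a) = I0 * 2**((a - a0) / d),
    or tabulated (ages, rates) with linear interpolation.
    """

    i0: float = 0.0015
    a0: float = 65.0
    doubling_years: float = 5.1
    table: tuple | None = None  # (ages array-like, rates per person-year)

    def __call__(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if self.table is not None:
            xs, ys = (np.asarray(v, dtype=float) for v in self.table)
            if np.any(np.diff(xs) <= 0):
                raise ValueError("tabulated ages must be strictly increasing")
            if np.any(ys < 0):
                raise ValueError("tabulated incidence must be >= 0")
            return np.interp(ages, xs, ys)
        return self.i0 * np.power(2.0, (ages - self.a0) / self.doubling_years)

    @classmethod
    def from_csv(cls, path: str | Path, per: float = 100_000.0) -> "TargetIncidenceCurve":
        """Load a tabulated curve from CSV columns (age, incidence per ``per``)."""
        import pandas as pd

        df = pd.read_csv(path)
        return cls(table=(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy() / per))
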