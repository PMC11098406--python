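"""Annual advancement of time-varying risk factors (rule step 1).

Each continuous factor is advanced by a linear regression spec whose
covariates are the person's demographics plus *lagged* values (the factor at
the immediately prior time point), *lagged-mean* values (the mean over all
prior time points including baseline) and lagged values of the other
time-varying factors.  SBP and DBP are modelled on the log scale and
de-transformed after the residual draw.

All next-wave values are computed from a frozen snapshot of the current wave
and committed atomically, so within-wave update order cannot leak same-wave
values between factors.
"""

from __future__ import annotations

import numpy as np

from .population import (
    CONTINUOUS_FACTORS,
    EDUCATION_LEVELS,
    RACE_LEVELS,
    Population,
)
from .rng import person_uniform
from .specs import ModelRepository, RegressionSpec, draw_linear_outcome, event_probability, linear_predictor

__all__ = [
    "lagged_mean",
    "resolve_covariates",
    "advance_risk_factors",
    "DYNAMIC_FACTORS",
]

# Factors advanced through regression specs (age increments deterministically,
# gcp belongs to the cognition module).
DYNAMIC_FACTORS = CONTINUOUS_FACTORS + (
    "smoking_status",
    "n_antihypertensives",
    "statin",
    "other_lipid_agent",
)

# Physiologic floors/ceilings applied after the residual draw; the SBP/DBP
# floor guards pathological draws after de-transformation.
FACTOR_BOUNDS = {
    "sbp": (1.0, 300.0),
    "dbp": (1.0, 200.0),
    "total_chol": (40.0, 500.0),
    "trig": (20.0, 2000.0),
    "ldl": (10.0, 400.0),
    "hdl": (5.0, 200.0),
    "a1c": (3.0, 20.0),
    "bmi": (10.0, 80.0),
    "waist": (40.0, 250.0),
    "physical_activity": (0.0, 60.0),
}


class StateError(RuntimeError):
    """Raised when person state cannot support the requested computation."""


def lagged_mean(source, factor: str, upto_wave: int | None = None):
    """Mean of a factor over all waves strictly before the wave being computed.

    ``source`` may be a :class:`Population` (vectorized, returns an array) or
    a :class:`~chronosim.population.Person` (returns a float).  The history
    includes baseline; a singleton history returns the baseline value.
    """
    if isinstance(source, Population):
        series = source.series[factor]
        t = source.wave if upto_wave is None else upto_wave
        if t < 0 or not series:
            raise StateError(f"no history for factor {factor!r}")
        return np.mean(series[: t + 1], axis=0)
    history = source.history(factor)
    if upto_wave is not None:
        history = history[: upto_wave + 1]
    if not history:
        raise StateError(f"no history for factor {factor!r}")
    return float(np.mean(history))


def _series_value(pop: Population, factor: str, kind: str, wave: int) -> np.ndarray:
    if kind in ("current", "lagged"):
        return pop.series[factor][wave]
    if kind == "lagged_mean":
        return lagged_mean(pop, factor, upto_wave=wave)
    raise KeyError(kind)


def resolve_covariate(pop: Population, name: str, kind: str, wave: int) -> np.ndarray:
    """Resolve one covariate name against population state as of ``wave``.

    Naming conventions:

    - ``lag_<...>`` / ``lagmean_<...>`` prefixes override ``kind`` (so one
      spec can carry both the lagged value and the lagged mean of a factor).
    - ``log_<factor>``: natural log of the factor value.
    - ``age_squared``: square of age.
    - ``baseline_<factor>``: the wave-0 value regardless of ``wave``.
    - indicators: ``sex_male``, ``race_<level>``, ``education_<level>``,
      ``smoking_current``, ``smoking_former``.
    """
    if name.startswith("lagmean_"):
        name, kind = name[len("lagmean_"):], "lagged_mean"
    elif name.startswith("lag_"):
        name, kind = name[len("lag_"):], "lagged"
    if kind == "static" or kind == "indicator":
        if name == "sex_male":
            return (pop.sex == 1).astype(float)
        if name.startswith("race_"):
            level = name[len("race_"):]
            return (pop.race == RACE_LEVELS.index(level)).astype(float)
        if name.startswith("education_"):
            level = name[len("education_"):]
            return (pop.education == EDUCATION_LEVELS.index(level)).astype(float)
        if name == "smoking_current":
            return (pop.series["smoking_status"][wave] == 2).astype(float)
        if name == "smoking_former":
            return (pop.series["smoking_status"][wave] == 1).astype(float)
        raise KeyError(f"unknown static/indicator covariate {name!r}")
    if name == "age_squared":
        return _series_value(pop, "age", kind, wave) ** 2
    if name.startswith("baseline_"):
        return pop.series[name[len("baseline_"):]][0]
    if name.startswith("log_"):
        factor = name[len("log_"):]
        if kind == "lagged_mean":
            # log-transformed-throughout factors average on the log scale
            return np.mean([np.log(a) for a in pop.series[factor][: wave + 1]], axis=0)
        return np.log(_series_value(pop, factor, kind, wave))
    return _series_value(pop, name, kind, wave)


def resolve_covariates(pop: Population, spec: RegressionSpec, wave: int) -> dict[str, np.ndarray]:
    """Covariate arrays for every non-intercept coefficient of ``spec``."""
    out = {}
    for cov in spec.covariates:
        kind = spec.covariate_kinds.get(cov, "lagged")
        out[cov] = resolve_covariate(pop, cov, kind, wave)
    return out


def _advance_continuous(pop, spec, wave, rng) -> np.ndarray:
    from .rng import person_normal

    lp = linear_predictor(spec, resolve_covariates(pop, spec, wave))
    nxt = np.broadcast_to(np.asarray(lp, dtype=float), (pop.n,)) + person_normal(
        rng, pop, spec.residual_mean, spec.residual_sd
    )
    if spec.transform == "log-outcome":
        nxt = np.exp(nxt)
    lo, hi = FACTOR_BOUNDS[spec.outcome]
    return np.clip(nxt, lo, hi)


def advance_risk_factors(
    pop: Population,
    repo: ModelRepository,
    rng_for,
) -> dict[str, np.ndarray]:
    """Compute next-wave values for every dynamic factor from the snapshot.

    ``rng_for(name)`` must return a Generator for the named substream, so each
    factor consumes an independent, reproducible stream.  Returns the proposed
    wave (age incremented, gcp carried forward for the cognition module to
    overwrite); callers commit it with :meth:`Population.commit_wave`.

    Categorical/count factors use logistic specs: smoking may quit
    (current -> former), antihypertensive count may gain one medication,
    statin/other-lipid use persists or switches via a Bernoulli draw.
    """
    t = pop.wave
    values: dict[str, np.ndarray] = {}
    for factor in CONTINUOUS_FACTORS:
        spec = repo.get(factor)
        values[factor] = _advance_continuous(pop, spec, t, rng_for(f"factor/{factor}"))
    values["dbp"] = np.minimum(values["dbp"], values["sbp"] - 1.0)

    # smoking: current smokers may quit to former; never smokers stay never
    spec = repo.get("smoking_status")
    p_quit = event_probability(spec, linear_predictor(spec, resolve_covariates(pop, spec, t)))
    u = person_uniform(rng_for("factor/smoking_status"), pop)
    smoking = pop.series["smoking_status"][t].copy()
    quitting = (smoking == 2) & (u < p_quit)
    smoking[quitting] = 1
    values["smoking_status"] = smoking

    # antihypertensive count: monotone, at most one added per wave
    spec = repo.get("n_antihypertensives")
    p_add = event_probability(spec, linear_predictor(spec, resolve_covariates(pop, spec, t)))
    u = person_uniform(rng_for("factor/n_antihypertensives"), pop)
    values["n_antihypertensives"] = pop.series["n_antihypertensives"][t] + (u < p_add)

    for flag in ("statin", "other_lipid_agent"):
        spec = repo.get(flag)
        p_on = event_probability(spec, linear_predictor(spec, resolve_covariates(pop, spec, t)))
        u = person_uniform(rng_for(f"factor/{flag}"), pop)
        values[flag] = (u < p_on).astype(float)

    values["age"] = pop.series["age"][t] + 1.0
    values["gcp"] = pop.series["gcp"][t].copy()
    return values


def advance_counterfactual_bp(pop: Population, repo: ModelRepository, rng_for, wave: int) -> None:
    """Advance the counterfactual untreated SBP/DBP series one wave.

    Uses the same dynamics specs and the same residual substreams as the real
    update, with the shadow series standing in for treated blood pressure, so
    the shadow reproduces the untreated trajectory exactly under common
    random numbers.  Non-BP covariates come from the real (treated) series.
    """
    if pop.shadow is None:
        return
    saved = pop.series["sbp"], pop.series["dbp"]
    pop.series["sbp"], pop.series["dbp"] = pop.shadow["sbp"], pop.shadow["dbp"]
    try:
        new_sbp = _advance_continuous(pop, repo.get("sbp"), wave - 1, rng_for("factor/sbp"))
        new_dbp = _advance_continuous(pop, repo.get("dbp"), wave - 1, rng_for("factor/dbp"))
    finally:
        pop.series["sbp"], pop.series["dbp"] = saved
    new_dbp = np.minimum(new_dbp, new_sbp - 1.0)
    dead = ~pop.alive
    for factor, arr in (("sbp", new_sbp), ("dbp", new_dbp)):
        prev = pop.shadow[factor][-1]
        arr = arr.copy()
        arr[dead] = prev[dead]
        pop.shadow[factor].append(arr)
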