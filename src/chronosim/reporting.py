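"""Validation/reporting surfaces: incidence, standardization, summaries.

Person-year convention: a person contributes one person-year to every wave
they are alive at the start of (the wave of death or of an event still counts
a full year), matching the annual-cycle granularity of the engine.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .population import RACE_LEVELS, Population

__all__ = [
    "standard_population",
    "age_standardized_rate",
    "events_and_person_years",
    "incidence_report",
    "arm_relative_risk",
    "distribution_summary",
]


def standard_population(path: str | Path | None = None) -> pd.DataFrame:
    """US 2000 projected standard million (config-replaceable via CSV)."""
    from .defaults import data_path

    return pd.read_csv(path or data_path("standard_population_us2000.csv"))


def _poisson_ci(count: float, scale: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact Poisson CI on a count, returned on the rate scale (x scale)."""
    if count == 0:
        lo = 0.0
    else:
        lo = stats.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (count + 1)) / 2
    return lo * scale, hi * scale


def age_standardized_rate(
    events: np.ndarray,
    person_years: np.ndarray,
    weights: np.ndarray,
    per: float = 100_000.0,
) -> dict[str, float]:
    """Directly age-standardized rate with 95% CI.

    rate = sum_b w_b * (events_b / PY_b) * per, with weights renormalized to
    1.  Bands with zero person-years but nonzero weight are excluded with a
    warning.  CI: exact Poisson when total events < 100, else a normal
    approximation on the weighted-rate variance.
    """
    events = np.asarray(events, dtype=float)
    py = np.asarray(person_years, dtype=float)
    w = np.asarray(weights, dtype=float)
    undefined = (py <= 0) & (w > 0)
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} band(s) with zero person-years excluded")
    use = py > 0
    w = w[use] / w[use].sum()
    e, p = events[use], py[use]
    rate = float(np.sum(w * e / p) * per)
    crude = float(e.sum() / p.sum() * per)
    total = float(e.sum())
    if total < 100:
        # exact bounds on the total count, scaled by standardized/crude ratio
        scale = (rate / crude if crude > 0 else per / p.sum()) / p.sum() * per
        lo, hi = _poisson_ci(total, (rate / total) if total > 0 else per / p.sum())
    else:
        var = float(np.sum(w**2 * e / p**2) * per**2)
        half = 1.96 * np.sqrt(var)
        lo, hi = rate - half, rate + half
    return {"rate": rate, "lo": max(lo, 0.0), "hi": hi, "crude": crude,
            "events": total, "person_years": float(p.sum())}


def events_and_person_years(
    pop: Population,
    kind: str,
    band_edges: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reported events and person-years per age band over the whole run."""
    band_edges = np.asarray(band_edges, dtype=float)
    nb = len(band_edges) - 1
    events = np.zeros(nb)
    py = np.zeros(nb)
    include = np.ones(pop.n, bool) if mask is None else np.asarray(mask, bool)
    event_waves: dict[int, list[int]] = {}
    for e in pop.events:
        if e.kind == kind and not e.rolled_back and include[e.person_id]:
            event_waves.setdefault(e.wave, []).append(e.person_id)
    for w in range(1, pop.wave + 1):
        at_risk = include & ((pop.death_wave < 0) | (pop.death_wave >= w))
        ages = pop.series["age"][w]
        idx = np.searchsorted(band_edges, ages, side="right") - 1
        ok = at_risk & (idx >= 0) & (idx < nb)
        np.add.at(py, idx[ok], 1.0)
        for pid in event_waves.get(w, []):
            if 0 <= idx[pid] < nb:
                events[idx[pid]] += 1.0
    return events, py


def incidence_report(
    pop: Population,
    kinds: tuple[str, ...] = ("stroke", "mi"),
    standard: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Crude and age-standardized incidence per 100,000, overall and by race."""
    std = standard if standard is not None else standard_population()
    edges = np.append(std["age_lo"].to_numpy(float), std["age_hi"].to_numpy(float)[-1] + 1)
    weights = std["weight"].to_numpy(float)
    strata = {"all": None,
              "nh_white": pop.race == RACE_LEVELS.index("nh_white"),
              "nh_black": pop.race == RACE_LEVELS.index("nh_black")}
    rows = []
    for kind in kinds:
        for name, mask in strata.items():
            e, p = events_and_person_years(pop, kind, edges, mask)
            if p.sum() == 0:
                continue
            r = age_standardized_rate(e, p, weights)
            rows.append({"kind": kind, "stratum": name, **r})
    return pd.DataFrame(rows)


def arm_relative_risk(
    rates_a: list[float] | float, rates_b: list[float] | float
) -> dict[str, float]:
    """Relative risk between arms; with replicate lists, mean and min-max
    range across replicates."""
    ra = np.atleast_1d(np.asarray(rates_a, dtype=float))
    rb = np.atleast_1d(np.asarray(rates_b, dtype=float))
    if np.any(rb == 0):
        raise ZeroDivisionError("zero denominator rate; RR undefined")
    rr = ra / rb
    return {"rr": float(rr.mean()), "lo": float(rr.min()), "hi": float(rr.max()),
            "replicates": int(rr.size)}


def distribution_summary(
    pop_or_values, factor: str | None = None, wave: int = -1, bins: int = 20
) -> dict:
    """Mean, SD and histogram bins of one factor (for risk-factor validation
    plots)."""
    if isinstance(pop_or_values, Population):
        values = pop_or_values.series[factor][wave]
        alive = (pop_or_values.death_wave < 0) | (
            pop_or_values.death_wave >= (pop_or_values.wave if wave == -1 else wave)
        )
        values = values[alive]
    else:
        values = np.asarray(pop_or_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to summarize")
    counts, edges = np.histogram(values, bins=bins)
    return {"mean": float(values.mean()), "sd": float(values.std(ddof=1)),
            "n": int(values.size), "bin_edges": edges.tolist(),
            "bin_counts": counts.tolist()}
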