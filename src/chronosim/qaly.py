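"""Quality-adjusted life year accrual (rule step 3).

Each wave a living person accrues base utility for their age multiplied by
condition multipliers: 0.67 in the year of an incident stroke (0.9 in later
years), 0.88 in the year of an incident MI (0.9 later), and for dementia
0.80 in the onset year declining by 0.01 per subsequent year (floored).
Multiple conditions combine multiplicatively by default.  The year of death
accrues 0 QALYs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Population

__all__ = ["UtilityTable", "dementia_multiplier", "annual_qaly", "annual_qaly_wave"]


@dataclass(frozen=True)
class UtilityTable:
    """Age-based base utilities and event multipliers.

    Base utility is 1.0 up to ``full_health_age``, declining linearly to
    ``old_age_utility`` at ``old_age``, flat after (the published age-utility
    table behind the original choice is configuration, not ground truth).
    """

    full_health_age: float = 40.0
    old_age: float = 90.0
    old_age_utility: float = 0.70
    stroke_incident: float = 0.67
    stroke_subsequent: float = 0.90
    mi_incident: float = 0.88
    mi_subsequent: float = 0.90
    dementia_first_year: float = 0.80
    dementia_decrement: float = 0.01
    dementia_floor: float = 0.0
    combination: str = "multiplicative"  # or "minimum"

    def __post_init__(self) -> None:
        for m in (
            self.stroke_incident,
            self.stroke_subsequent,
            self.mi_incident,
            self.mi_subsequent,
            self.dementia_first_year,
        ):
            if not 0 < m <= 1:
                raise ValueError("event multipliers must lie in (0, 1]")
        if self.dementia_floor < 0:
            raise ValueError("dementia floor must be >= 0")
        if self.combination not in ("multiplicative", "minimum"):
            raise ValueError("combination must be 'multiplicative' or 'minimum'")

    def base_utility(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        frac = np.clip(
            (age - self.full_health_age) / (self.old_age - self.full_health_age), 0.0, 1.0
        )
        out = 1.0 - frac * (1.0 - self.old_age_utility)
        return out if out.shape else float(out)


def dementia_multiplier(years_since_onset: int, table: UtilityTable = UtilityTable()) -> float:
    """Dementia utility multiplier k years after onset (k = 0 in the
    incident year): max(0.80 - 0.01 * k, floor)."""
    if years_since_onset < 0:
        raise ValueError("years since onset must be >= 0")
    return max(
        table.dementia_first_year - table.dementia_decrement * years_since_onset,
        table.dementia_floor,
    )


def _combine(multipliers: list, table: UtilityTable):
    if not multipliers:
        return 1.0
    if table.combination == "minimum":
        return np.minimum.reduce(multipliers)
    out = multipliers[0]
    for m in multipliers[1:]:
        out = out * m
    return out


def annual_qaly_wave(
    pop: Population,
    table: UtilityTable,
    wave: int,
    stroke_now: np.ndarray,
    mi_now: np.ndarray,
) -> np.ndarray:
    """Vectorized QALY accrual for one wave (0 for persons dead or dying)."""
    age = pop.series["age"][wave]
    base = table.base_utility(age)

    stroke_mult = np.where(
        stroke_now,
        table.stroke_incident,
        np.where(
            (pop.first_stroke_wave >= 0) & (pop.first_stroke_wave < wave),
            table.stroke_subsequent,
            1.0,
        ),
    )
    mi_mult = np.where(
        mi_now,
        table.mi_incident,
        np.where((pop.first_mi_wave >= 0) & (pop.first_mi_wave < wave), table.mi_subsequent, 1.0),
    )
    k = wave - pop.dementia_wave
    dem_mult = np.where(
        pop.has_dementia & (k >= 0),
        np.maximum(
            table.dementia_first_year - table.dementia_decrement * np.maximum(k, 0),
            table.dementia_floor,
        ),
        1.0,
    )
    qaly = base * _combine([stroke_mult, mi_mult, dem_mult], table)
    dead_or_dying = (~pop.alive) | ((pop.death_wave >= 0) & (pop.death_wave <= wave))
    return np.where(dead_or_dying, 0.0, qaly)


def annual_qaly(person, table: UtilityTable, wave: int) -> float:
    """Per-person QALY for one wave, computed from the person's outcome
    history (dead before or during the wave -> 0)."""
    pop = person._pop
    if pop.death_wave[person.id] >= 0 and pop.death_wave[person.id] <= wave:
        return 0.0
    base = float(table.base_utility(pop.series["age"][wave][person.id]))
    outcomes = person.outcomes
    mults = []
    for kind, incident_m, subsequent_m in (
        ("stroke", table.stroke_incident, table.stroke_subsequent),
        ("mi", table.mi_incident, table.mi_subsequent),
    ):
        waves = [e.wave for e in outcomes.get(kind, [])]
        if any(w == wave for w in waves):
            mults.append(incident_m)
        elif any(w < wave for w in waves):
            mults.append(subsequent_m)
    dw = pop.dementia_wave[person.id]
    if dw >= 0 and wave >= dw:
        mults.append(dementia_multiplier(int(wave - dw), table))
    return base * float(_combine(mults, table))
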