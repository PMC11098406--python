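"""Synthetic baseline cohort generation and the Population/Person containers.

The generator emulates the joint distribution of demographics, vascular risk
factors, biometrics, behaviors and medications in a cross-sectional survey of
US adults 18+ free of stroke, MI and dementia.  Continuous factors are drawn
from a Gaussian copula over configurable marginals (so cross-factor
correlation structure is preserved), then clipped to physiologic ranges;
categorical factors come from configurable frequencies.  Antihypertensive
medication count is driven by a latent factor inside the copula so that
medication use correlates with age and blood pressure.

State is stored columnarly on :class:`Population` (one numpy array per factor
per wave); :class:`Person` is a lightweight per-individual view over those
arrays.  This keeps whole-population wave updates vectorized while preserving
a per-person interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import norm

from .events import OutcomeEvent

__all__ = [
    "SEX_LEVELS",
    "RACE_LEVELS",
    "EDUCATION_LEVELS",
    "SMOKING_LEVELS",
    "CONTINUOUS_FACTORS",
    "Marginal",
    "PopulationConfig",
    "Population",
    "Person",
    "generate_population",
    "filter_hypertensive",
]

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("nh_white", "nh_black", "hispanic", "other")
EDUCATION_LEVELS = (
    "less_than_high_school",
    "some_high_school",
    "high_school_grad",
    "some_college",
    "college_grad",
)
SMOKING_LEVELS = ("never", "former", "current")

# Continuous time-varying factors advanced by regression dynamics.
CONTINUOUS_FACTORS = (
    "sbp",
    "dbp",
    "total_chol",
    "trig",
    "ldl",
    "hdl",
    "a1c",
    "bmi",
    "waist",
    "physical_activity",
)

# All per-wave series carried on the population (age advances
# deterministically; gcp is advanced by the cognition module).
SERIES_FACTORS = (
    ("age",)
    + CONTINUOUS_FACTORS
    + ("smoking_status", "n_antihypertensives", "statin", "other_lipid_agent", "gcp")
)


@dataclass(frozen=True)
class Marginal:
    """Marginal distribution of one continuous factor.

    ``dist`` is ``"normal"`` or ``"lognormal"`` (mean/sd are always on the
    natural scale); draws are clipped to ``[lower, upper]``.
    """

    mean: float
    sd: float
    lower: float
    upper: float
    dist: str = "normal"

    def from_z(self, z: np.ndarray) -> np.ndarray:
        if self.sd == 0:
            x = np.full_like(z, self.mean, dtype=float)
        elif self.dist == "normal":
            x = self.mean + self.sd * z
        elif self.dist == "lognormal":
            sigma2 = np.log1p((self.sd / self.mean) ** 2)
            mu = np.log(self.mean) - sigma2 / 2.0
            x = np.exp(mu + np.sqrt(sigma2) * z)
        else:
            raise ValueError(f"unknown marginal dist {self.dist!r}")
        return np.clip(x, self.lower, self.upper)


# Default marginals: mean age / %female / BMI anchored to published NHANES
# 2007-2010 summaries; all other moments are plausible survey-level values and
# are configuration, not ground truth.
DEFAULT_MARGINALS: dict[str, Marginal] = {
    "age": Marginal(45.9, 17.5, 18.0, 95.0),
    "sbp": Marginal(122.0, 16.0, 70.0, 250.0),
    "dbp": Marginal(72.0, 11.0, 40.0, 150.0),
    "total_chol": Marginal(196.0, 41.0, 80.0, 450.0),
    "trig": Marginal(130.0, 90.0, 30.0, 1000.0, dist="lognormal"),
    "ldl": Marginal(115.0, 34.0, 30.0, 300.0),
    "hdl": Marginal(53.0, 15.0, 15.0, 150.0),
    "a1c": Marginal(5.6, 0.9, 3.5, 16.0),
    "bmi": Marginal(28.5, 6.5, 14.0, 70.0),
    "waist": Marginal(97.0, 16.0, 50.0, 200.0),
    "physical_activity": Marginal(5.0, 3.5, 0.0, 40.0),
}

# Copula column order (med_latent drives the antihypertensive count).
_COPULA_FACTORS = tuple(DEFAULT_MARGINALS) + ("med_latent",)

DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("age", "sbp", 0.45),
    ("age", "dbp", 0.10),
    ("age", "a1c", 0.30),
    ("age", "physical_activity", -0.20),
    ("sbp", "dbp", 0.60),
    ("bmi", "waist", 0.85),
    ("bmi", "dbp", 0.15),
    ("bmi", "a1c", 0.25),
    ("bmi", "physical_activity", -0.20),
    ("total_chol", "ldl", 0.90),
    ("total_chol", "hdl", 0.15),
    ("total_chol", "trig", 0.30),
    ("trig", "hdl", -0.30),
    ("med_latent", "age", 0.50),
    ("med_latent", "sbp", 0.35),
)

DEFAULT_SEX_FREQS = {"female": 0.517, "male": 0.483}
DEFAULT_RACE_FREQS = {"nh_white": 0.684, "nh_black": 0.115, "hispanic": 0.136, "other": 0.065}
DEFAULT_EDUCATION_FREQS = {
    "less_than_high_school": 0.15,
    "some_high_school": 0.10,
    "high_school_grad": 0.25,
    "some_college": 0.30,
    "college_grad": 0.20,
}
DEFAULT_SMOKING_FREQS = {"never": 0.55, "former": 0.25, "current": 0.20}
# P(antihypertensive count = k) for k = 0..3, mapped through the latent factor.
DEFAULT_MED_COUNT_FREQS = (0.78, 0.12, 0.07, 0.03)
DEFAULT_STATIN_PREVALENCE = 0.16
DEFAULT_OTHER_LIPID_PREVALENCE = 0.05


class ConfigError(ValueError):
    """Raised for invalid population configuration."""


@dataclass
class PopulationConfig:
    """Configuration of the synthetic baseline cohort."""

    n: int = 1000
    start_year: int = 1999
    marginals: dict[str, Marginal] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    correlations: tuple = DEFAULT_CORRELATIONS
    sex_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_FREQS))
    race_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_FREQS))
    education_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EDUCATION_FREQS))
    smoking_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SMOKING_FREQS))
    med_count_freqs: tuple = DEFAULT_MED_COUNT_FREQS
    statin_prevalence: float = DEFAULT_STATIN_PREVALENCE
    other_lipid_prevalence: float = DEFAULT_OTHER_LIPID_PREVALENCE
    hypertension_filter: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("population size must be >= 1")
        if not 1999 <= self.start_year <= 2017:
            raise ConfigError("start_year must lie in 1999-2017")

    def correlation_matrix(self) -> np.ndarray:
        """Assemble and validate the copula correlation matrix."""
        k = len(_COPULA_FACTORS)
        idx = {f: i for i, f in enumerate(_COPULA_FACTORS)}
        r = np.eye(k)
        for f1, f2, rho in self.correlations:
            i, j = idx[f1], idx[f2]
            r[i, j] = r[j, i] = rho
        eigvals = np.linalg.eigvalsh(r)
        if eigvals.min() < -1e-10:
            raise ConfigError(
                f"correlation matrix is not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
            )
        return r


class Population:
    """A cohort of simulated persons with columnar per-wave state.

    Per-wave series are lists of equal-length numpy arrays, one per committed
    wave (index 0 = baseline).  Dead persons' trailing array entries are
    frozen carry-forwards; the :class:`Person` view truncates each series at
    the wave of death, so per-person series lengths equal waves survived.
    """

    def __init__(self, sex, race, education, start_year: int = 1999):
        self.sex = np.asarray(sex, dtype=np.int64)
        self.n = self.sex.shape[0]
        self.ids = np.arange(self.n)
        # stable person identity: preserved under subset/permutation so that
        # uid-indexed RNG draws make results storage-order invariant
        self.uid = np.arange(self.n)
        self.uid_span = self.n
        self.race = np.asarray(race, dtype=np.int64)
        self.education = np.asarray(education, dtype=np.int64)
        self.start_year = start_year
        self.series: dict[str, list[np.ndarray]] = {f: [] for f in SERIES_FACTORS}
        self.gcp_random_effect = np.zeros(self.n)
        self.alive = np.ones(self.n, dtype=bool)
        self.death_wave = np.full(self.n, -1, dtype=np.int64)
        # 0 = alive, 1 = cardiovascular death, 2 = non-CV death
        self.death_cause = np.zeros(self.n, dtype=np.int64)
        self.dementia_wave = np.full(self.n, -1, dtype=np.int64)
        self.first_stroke_wave = np.full(self.n, -1, dtype=np.int64)
        self.first_mi_wave = np.full(self.n, -1, dtype=np.int64)
        self.events: list[OutcomeEvent] = []
        self.qalys: list[np.ndarray] = []
        # Cumulative medications added by a treatment strategy (not usual care).
        self.strategy_meds = np.zeros(self.n)
        # Counterfactual untreated SBP/DBP series (created on first strategy
        # treatment; advanced through the same dynamics with shared residuals)
        self.shadow: dict[str, list[np.ndarray]] | None = None

    # -- wave bookkeeping -------------------------------------------------
    @property
    def wave(self) -> int:
        """Index of the last committed wave (0 = baseline)."""
        return len(self.series["age"]) - 1

    def current(self, factor: str) -> np.ndarray:
        return self.series[factor][-1]

    def commit_baseline(self, baseline: Mapping[str, np.ndarray]) -> None:
        for f in SERIES_FACTORS:
            if f not in baseline:
                raise ConfigError(f"baseline is missing series {f!r}")
            arr = np.asarray(baseline[f], dtype=float)
            if arr.shape != (self.n,):
                raise ConfigError(f"baseline series {f!r} has wrong shape")
            self.series[f].append(arr)

    def commit_wave(self, values: Mapping[str, np.ndarray]) -> None:
        """Append one wave of values for every series atomically.

        Dead persons carry their last value forward so arrays stay
        rectangular; their Person views truncate at the death wave.
        """
        dead = ~self.alive
        for f in SERIES_FACTORS:
            prev = self.series[f][-1]
            arr = np.asarray(values[f], dtype=float).copy()
            arr[dead] = prev[dead]
            self.series[f].append(arr)

    # -- derived state ----------------------------------------------------
    @property
    def has_dementia(self) -> np.ndarray:
        return self.dementia_wave >= 0

    def event_count(self, kind: str, include_rolled_back: bool = False) -> int:
        return sum(
            1
            for e in self.events
            if e.kind == kind and (include_rolled_back or not e.rolled_back)
        )

    def survived_waves(self) -> np.ndarray:
        """Per person, number of committed waves lived (series length)."""
        out = np.full(self.n, self.wave + 1, dtype=np.int64)
        dead = self.death_wave >= 0
        out[dead] = self.death_wave[dead] + 1
        return out

    def person(self, i: int) -> "Person":
        return Person(self, int(i))

    def __len__(self) -> int:
        return self.n

    # -- restructuring ----------------------------------------------------
    def subset(self, index: np.ndarray) -> "Population":
        """New population containing the selected persons (ids renumbered)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        sub = Population(self.sex[index], self.race[index], self.education[index], self.start_year)
        sub.uid = self.uid[index].copy()
        sub.uid_span = self.uid_span
        for f in SERIES_FACTORS:
            sub.series[f] = [arr[index] for arr in self.series[f]]
        sub.gcp_random_effect = self.gcp_random_effect[index]
        sub.alive = self.alive[index].copy()
        sub.death_wave = self.death_wave[index].copy()
        sub.death_cause = self.death_cause[index].copy()
        sub.dementia_wave = self.dementia_wave[index].copy()
        sub.first_stroke_wave = self.first_stroke_wave[index].copy()
        sub.first_mi_wave = self.first_mi_wave[index].copy()
        sub.qalys = [q[index] for q in self.qalys]
        sub.strategy_meds = self.strategy_meds[index].copy()
        if self.shadow is not None:
            sub.shadow = {f: [a[index] for a in s] for f, s in self.shadow.items()}
        remap = {int(old): new for new, old in enumerate(index)}
        sub.events = [
            replace(e, person_id=remap[e.person_id]) for e in self.events if e.person_id in remap
        ]
        return sub

    def permuted(self, order: np.ndarray) -> "Population":
        """Population with persons stored in a different order (same cohort)."""
        return self.subset(np.asarray(order))

    def to_frame(self):
        """Long-format person-wave table (one row per person per wave lived)."""
        import pandas as pd

        survived = self.survived_waves()
        rows = []
        for w in range(self.wave + 1):
            live = survived > w
            idx = np.flatnonzero(live)
            frame = {
                "person_id": idx,
                "wave": w,
                "year": self.start_year + w,
                "sex": np.asarray(SEX_LEVELS)[self.sex[idx]],
                "race_ethnicity": np.asarray(RACE_LEVELS)[self.race[idx]],
                "education": np.asarray(EDUCATION_LEVELS)[self.education[idx]],
            }
            for f in SERIES_FACTORS:
                frame[f] = self.series[f][w][idx]
            rows.append(pd.DataFrame(frame))
        return pd.concat(rows, ignore_index=True)


class Person:
    """Per-individual view over the columnar population state."""

    def __init__(self, population: Population, i: int):
        self._pop = population
        self.id = i

    @property
    def sex(self) -> str:
        return SEX_LEVELS[self._pop.sex[self.id]]

    @property
    def race_ethnicity(self) -> str:
        return RACE_LEVELS[self._pop.race[self.id]]

    @property
    def education(self) -> str:
        return EDUCATION_LEVELS[self._pop.education[self.id]]

    @property
    def alive(self) -> bool:
        return bool(self._pop.alive[self.id])

    @property
    def gcp_random_effect(self) -> float:
        return float(self._pop.gcp_random_effect[self.id])

    @property
    def waves_survived(self) -> int:
        return int(self._pop.survived_waves()[self.id])

    def history(self, factor: str) -> list[float]:
        k = self.waves_survived
        return [float(arr[self.id]) for arr in self._pop.series[factor][:k]]

    @property
    def age(self) -> float:
        return self.history("age")[-1]

    @property
    def outcomes(self) -> dict[str, list[OutcomeEvent]]:
        out: dict[str, list[OutcomeEvent]] = {}
        for e in self._pop.events:
            if e.person_id == self.id and not e.rolled_back:
                out.setdefault(e.kind, []).append(e)
        return out

    @property
    def qalys(self) -> list[float]:
        k = self.waves_survived
        return [float(q[self.id]) for q in self._pop.qalys[:k]]

    def __getattr__(self, name: str):
        pop = object.__getattribute__(self, "_pop")
        if name in pop.series:
            return self.history(name)
        raise AttributeError(name)


def _draw_categorical(rng: np.random.Generator, freqs: Mapping[str, float], levels, n: int):
    p = np.array([freqs[l] for l in levels], dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ConfigError(f"categorical frequencies sum to {p.sum():.4f}, expected 1")
    return rng.choice(len(levels), size=n, p=p / p.sum())


def generate_population(
    config: PopulationConfig,
    rng: np.random.Generator,
    gcp_spec=None,
) -> Population:
    """Generate a baseline cohort of adults 18+ free of stroke/MI/dementia.

    Continuous factors are drawn through a Gaussian copula (Cholesky factor of
    the configured correlation matrix), mapped to the configured marginals and
    clipped to physiologic ranges.  Reproducible given ``rng``.
    """
    n = config.n
    r = config.correlation_matrix()
    # eigh-based square root tolerates the semi-definite (degenerate) case
    w, v = np.linalg.eigh(r)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(_COPULA_FACTORS))) @ root.T

    cols = {f: z[:, i] for i, f in enumerate(_COPULA_FACTORS)}
    values = {f: config.marginals[f].from_z(cols[f]) for f in config.marginals}
    # keep diastolic below systolic
    values["dbp"] = np.minimum(values["dbp"], values["sbp"] - 5.0)

    sex = _draw_categorical(rng, config.sex_freqs, SEX_LEVELS, n)
    race = _draw_categorical(rng, config.race_freqs, RACE_LEVELS, n)
    education = _draw_categorical(rng, config.education_freqs, EDUCATION_LEVELS, n)
    smoking = _draw_categorical(rng, config.smoking_freqs, SMOKING_LEVELS, n)

    # medication count via thresholds on the latent factor
    cum = np.cumsum(config.med_count_freqs)
    if not np.isclose(cum[-1], 1.0, atol=1e-6):
        raise ConfigError("med_count_freqs must sum to 1")
    thresholds = norm.ppf(np.clip(cum[:-1], 1e-12, 1 - 1e-12))
    n_meds = np.searchsorted(thresholds, cols["med_latent"], side="left").astype(float)

    statin = (rng.random(n) < config.statin_prevalence).astype(float)
    other_lipid = (rng.random(n) < config.other_lipid_prevalence).astype(float)

    pop = Population(sex, race, education, config.start_year)
    baseline = dict(values)
    baseline["smoking_status"] = smoking.astype(float)
    baseline["n_antihypertensives"] = n_meds
    baseline["statin"] = statin
    baseline["other_lipid_agent"] = other_lipid
    baseline["gcp"] = np.zeros(n)
    pop.commit_baseline(baseline)

    from .cognition import default_gcp_spec, initialize_gcp

    initialize_gcp(pop, gcp_spec or default_gcp_spec(), rng)

    if config.hypertension_filter:
        pop = filter_hypertensive(pop)
    return pop


def filter_hypertensive(population: Population) -> Population:
    """Subset with baseline SBP > 140, DBP > 90, or any antihypertensive."""
    sbp = population.series["sbp"][0]
    dbp = population.series["dbp"][0]
    meds = population.series["n_antihypertensives"][0]
    keep = (sbp > 140.0) | (dbp > 90.0) | (meds > 0)
    return population.subset(keep)
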