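"""Declarative regression-model specifications and their evaluation.

Every linear predictor in the simulation — risk-factor dynamics, the
stroke-vs-MI partition, non-cardiovascular mortality, the cognition model —
is evaluated through one pathway: a :class:`RegressionSpec` loaded from a
JSON file (or built in code) plus the three evaluation functions
:func:`linear_predictor`, :func:`draw_linear_outcome` and
:func:`event_probability`.

The JSON schema is strict: unknown keys are rejected so that a typo in a
coefficient name fails loudly instead of silently dropping a covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "RegressionSpec",
    "ModelRepository",
    "SpecError",
    "load_spec",
    "save_spec",
    "linear_predictor",
    "draw_linear_outcome",
    "event_probability",
]

FAMILIES = ("linear", "logistic", "cox-hazard")
TRANSFORMS = ("none", "log-outcome")
COVARIATE_KINDS = ("current", "lagged", "lagged_mean", "static", "indicator")

_SCHEMA_KEYS = {
    "name",
    "family",
    "outcome",
    "coefficients",
    "residual",
    "transform",
    "covariate_kinds",
}


class SpecError(ValueError):
    """Raised when a model specification violates the schema."""


@dataclass(frozen=True)
class RegressionSpec:
    """A serialized statistical model evaluated by the simulation engine.

    Parameters
    ----------
    name : str
        Identifier of the model.
    family : str
        One of ``linear``, ``logistic``, ``cox-hazard``.
    outcome : str
        Name of the quantity the model predicts.
    coefficients : dict
        Covariate name -> coefficient; must contain ``"intercept"``.
    residual_mean, residual_sd : float
        Moments of the (normal) residual distribution; ignored for the
        logistic family.
    transform : str
        ``"log-outcome"`` if the outcome was modelled on the log scale and
        must be exponentiated after drawing, else ``"none"``.
    covariate_kinds : dict
        Covariate name -> one of ``current``, ``lagged``, ``lagged_mean``,
        ``static``, ``indicator``; tells the engine how to resolve the
        covariate against person state.
    """

    name: str
    family: str
    outcome: str
    coefficients: dict[str, float]
    residual_mean: float = 0.0
    residual_sd: float = 0.0
    transform: str = "none"
    covariate_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        if self.transform not in TRANSFORMS:
            raise SpecError(f"unknown transform {self.transform!r}")
        if "intercept" not in self.coefficients:
            raise SpecError(f"spec {self.name!r} is missing an 'intercept' coefficient")
        if self.residual_sd < 0:
            raise SpecError(f"spec {self.name!r} has negative residual_sd")
        for cov, kind in self.covariate_kinds.items():
            if kind not in COVARIATE_KINDS:
                raise SpecError(f"covariate {cov!r}: unknown kind {kind!r}")

    @property
    def covariates(self) -> list[str]:
        """Non-intercept covariate names, in insertion order."""
        return [c for c in self.coefficients if c != "intercept"]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "family": self.family,
            "outcome": self.outcome,
            "coefficients": dict(self.coefficients),
            "residual": {"mean": self.residual_mean, "sd": self.residual_sd},
            "transform": self.transform,
            "covariate_kinds": dict(self.covariate_kinds),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RegressionSpec":
        unknown = set(payload) - _SCHEMA_KEYS
        if unknown:
            raise SpecError(f"unknown spec fields: {sorted(unknown)}")
        for required in ("name", "family", "outcome", "coefficients"):
            if required not in payload:
                raise SpecError(f"spec is missing required field {required!r}")
        residual = payload.get("residual", {"mean": 0.0, "sd": 0.0})
        extra = set(residual) - {"mean", "sd"}
        if extra:
            raise SpecError(f"unknown residual fields: {sorted(extra)}")
        return cls(
            name=payload["name"],
            family=payload["family"],
            outcome=payload["outcome"],
            coefficients={str(k): float(v) for k, v in payload["coefficients"].items()},
            residual_mean=float(residual.get("mean", 0.0)),
            residual_sd=float(residual.get("sd", 0.0)),
            transform=payload.get("transform", "none"),
            covariate_kinds={str(k): str(v) for k, v in payload.get("covariate_kinds", {}).items()},
        )


def load_spec(path: str | Path) -> RegressionSpec:
    """Load and validate a model specification from a JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    return RegressionSpec.from_dict(payload)


def save_spec(spec: RegressionSpec, path: str | Path) -> None:
    """Write a specification as JSON (round-trips losslessly with load_spec)."""
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1, sort_keys=True)


def linear_predictor(spec: RegressionSpec, covariates: Mapping[str, float | np.ndarray]):
    """Intercept + sum of coefficient * covariate value.

    ``covariates`` values may be scalars or equal-length arrays (the same
    pathway serves per-person and whole-population evaluation).
    """
    lp = spec.coefficients["intercept"]
    for cov in spec.coefficients:
        if cov == "intercept":
            continue
        try:
            x = covariates[cov]
        except KeyError:
            raise KeyError(
                f"model {spec.name!r} requires covariate {cov!r}, not supplied"
            ) from None
        lp = lp + spec.coefficients[cov] * x
    return lp


def draw_linear_outcome(spec: RegressionSpec, lp, rng: np.random.Generator):
    """Linear predictor plus a residual draw, de-transformed if needed.

    For ``transform="log-outcome"`` the model operates on the log scale and
    the result is exponentiated after adding the residual.
    """
    if spec.family != "linear":
        raise SpecError(f"draw_linear_outcome requires a linear spec, got {spec.family!r}")
    lp = np.asarray(lp, dtype=float)
    if spec.residual_sd > 0 or spec.residual_mean != 0:
        eps = rng.normal(spec.residual_mean, spec.residual_sd, size=lp.shape)
        out = lp + eps
    else:
        out = lp.copy()
    if spec.transform == "log-outcome":
        out = np.exp(out)
    return out if out.shape else float(out)


def event_probability(spec_or_lp, lp=None):
    """Inverse-logit of a linear predictor: 1 / (1 + exp(-lp)).

    Accepts either ``event_probability(spec, lp)`` (validating the family)
    or ``event_probability(lp)``.
    """
    if lp is None:
        lp = spec_or_lp
    else:
        spec = spec_or_lp
        if spec.family != "logistic":
            raise SpecError(f"event_probability requires a logistic spec, got {spec.family!r}")
    p = expit(np.asarray(lp, dtype=float))
    return p if p.shape else float(p)


class ModelRepository:
    """Store of regression specs keyed by outcome, with optional selectors.

    A plain entry maps an outcome name to one :class:`RegressionSpec`. A
    *selector* entry maps an outcome name to a callable
    ``selector(state) -> RegressionSpec`` so the applicable model can depend
    on person state (e.g. dementia-status-specific mortality models).
    """

    def __init__(self) -> None:
        self._models: dict[str, RegressionSpec] = {}
        self._selectors: dict[str, Callable] = {}

    def add(self, spec: RegressionSpec, outcome: str | None = None) -> None:
        self._models[outcome or spec.outcome] = spec

    def add_selector(self, outcome: str, selector: Callable) -> None:
        self._selectors[outcome] = selector

    def add_from_file(self, path: str | Path, outcome: str | None = None) -> None:
        self.add(load_spec(path), outcome)

    def outcomes(self) -> list[str]:
        return sorted(set(self._models) | set(self._selectors))

    def get(self, outcome: str, state=None) -> RegressionSpec:
        """Return the spec for ``outcome``; selectors receive ``state``."""
        if outcome in self._selectors:
            return self._selectors[outcome](state)
        try:
            return self._models[outcome]
        except KeyError:
            raise KeyError(f"no model registered for outcome {outcome!r}") from None

    def __contains__(self, outcome: str) -> bool:
        return outcome in self._models or outcome in self._selectors
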