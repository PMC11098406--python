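"""Load the packaged default model inputs.

The shipped coefficient sets are illustrative inputs with the documented
structure (the engine treats them as data); replace any of them by pointing
the corresponding loader at your own files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .ascvd import PCESpec
from .cognition import DementiaCoxSpec, GCPModelSpec, default_gcp_spec
from .mortality import LifeTable, NonCVMortalitySpec
from .riskfactors import DYNAMIC_FACTORS
from .specs import ModelRepository, RegressionSpec, load_spec

__all__ = [
    "data_path",
    "default_repository",
    "default_pce_spec",
    "default_partition_spec",
    "default_mortality_spec",
    "default_life_table",
    "default_cox_spec",
    "ModelBundle",
    "default_bundle",
]


def data_path(*parts: str) -> Path:
    return Path(resources.files("chronosim").joinpath("data", *parts))


def default_repository(model_dir: str | Path | None = None) -> ModelRepository:
    """Repository with one dynamics model per time-varying factor."""
    base = Path(model_dir) if model_dir else data_path("models")
    repo = ModelRepository()
    for factor in DYNAMIC_FACTORS:
        repo.add(load_spec(base / f"{factor}.json"), outcome=factor)
    return repo


def default_pce_spec() -> PCESpec:
    return PCESpec.from_json(data_path("pce_coefficients.json"))


def default_partition_spec(model_dir: str | Path | None = None) -> RegressionSpec:
    base = Path(model_dir) if model_dir else data_path("models")
    return load_spec(base / "stroke_partition.json")


def default_mortality_spec(
    model_dir: str | Path | None = None, dementia_log_odds_offset: float = 1.5
) -> NonCVMortalitySpec:
    base = Path(model_dir) if model_dir else data_path("models")
    return NonCVMortalitySpec.with_offset(
        load_spec(base / "non_cv_mortality.json"), dementia_log_odds_offset
    )


def default_life_table() -> LifeTable:
    return LifeTable.from_csv(data_path("life_table_synthetic.csv"))


def default_cox_spec() -> DementiaCoxSpec:
    return DementiaCoxSpec.from_json(data_path("dementia_cox.json"))


@dataclass
class ModelBundle:
    """All model inputs the engine needs for one run."""

    repo: ModelRepository
    pce: PCESpec
    partition: RegressionSpec
    mortality: NonCVMortalitySpec
    cox: DementiaCoxSpec
    gcp: GCPModelSpec


def default_bundle(model_dir: str | Path | None = None) -> ModelBundle:
    return ModelBundle(
        repo=default_repository(model_dir),
        pce=default_pce_spec(),
        partition=default_partition_spec(model_dir),
        mortality=default_mortality_spec(model_dir),
        cox=default_cox_spec(),
        gcp=default_gcp_spec(),
    )
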