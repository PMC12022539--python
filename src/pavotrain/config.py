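"""YAML run configuration: validation, defaults, and provenance hashing.

A run config is a mapping with optional ``lattice``, ``expansion``,
``classify``, ``growth``, ``specimens`` and top-level ``seed`` /
``output_dir`` / ``log_level`` entries.  Unknown keys are rejected so typos
fail loudly.  Every artifact a command writes is accompanied by a sidecar
JSON embedding the canonical config hash, seed and package version, giving
each output a full reproducibility chain.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import InvalidParameterError
from .growth_model import GrowthParams
from .synthetic_specimens import SpecimenParams
from .train_expansion import ExpansionGeometry

_LATTICE_KEYS = {"scheme", "n_rows", "row_pitch", "within_row_pitch", "first_row_size"}
_EXPANSION_KEYS = {"fan_span", "base_radius", "radial_pitch", "midline_angle"}
_CLASSIFY_KEYS = {"n_fishtail_rows", "n_minor_rows"}
_GROWTH_KEYS = {
    "rows_per_year",
    "max_rows",
    "n_fishtail_rows",
    "n_minor_rows",
    "length_asymptote",
    "length_rate",
    "first_row_size",
    "max_age",
}
_SPECIMEN_KEYS = {
    "species",
    "n",
    "n_rows_support",
    "fishtail_rows_support",
    "minor_rows_support",
    "damage_rate",
    "esl_mean",
    "esl_sd",
    "ftl_mean",
    "ftl_sd",
    "first_row_size",
}
_TOP_KEYS = {
    "lattice",
    "expansion",
    "classify",
    "growth",
    "specimens",
    "seed",
    "output_dir",
    "log_level",
}


def _check_keys(block: dict, allowed: set, where: str) -> dict:
    extra = set(block) - allowed
    if extra:
        raise InvalidParameterError(f"unknown {where} config keys: {sorted(extra)}")
    return dict(block)


@dataclass
class RunConfig:
    """Validated configuration for the command-line pipeline."""

    lattice: dict = field(default_factory=dict)
    expansion: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    specimens: dict = field(default_factory=dict)
    seed: int | None = None
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.lattice = _check_keys(self.lattice, _LATTICE_KEYS, "lattice")
        self.expansion = _check_keys(self.expansion, _EXPANSION_KEYS, "expansion")
        self.classify = _check_keys(self.classify, _CLASSIFY_KEYS, "classify")
        self.growth = _check_keys(self.growth, _GROWTH_KEYS, "growth")
        self.specimens = _check_keys(self.specimens, _SPECIMEN_KEYS, "specimens")
        # eager validation: building the parameter objects runs their checks
        self.expansion_geometry()
        self.growth_params()
        self.specimen_params()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InvalidParameterError("config must be a YAML mapping")
        raw = _check_keys(raw, _TOP_KEYS, "top-level")
        return cls(**raw)

    def expansion_geometry(self) -> ExpansionGeometry:
        return ExpansionGeometry(**self.expansion)

    def growth_params(self) -> GrowthParams:
        kwargs = {k: v for k, v in self.growth.items() if k != "max_age"}
        return GrowthParams(**kwargs)

    def specimen_params(self) -> SpecimenParams:
        base = self.specimens.get("species", "cristatus")
        kwargs = {k: v for k, v in self.specimens.items() if k != "n"}
        for key in ("n_rows_support", "fishtail_rows_support", "minor_rows_support"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        defaults = asdict(SpecimenParams.for_species(base))
        defaults.update(kwargs)
        return SpecimenParams(**defaults)

    def canonical_json(self) -> str:
        return json.dumps(
            {
                "lattice": self.lattice,
                "expansion": self.expansion,
                "classify": self.classify,
                "growth": self.growth,
                "specimens": self.specimens,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]
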