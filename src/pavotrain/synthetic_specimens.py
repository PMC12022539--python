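"""Synthetic museum-specimen generator.

Museum skins summarize into a small table: 17-19 follicle rows of 10/11
feathers, eyespot-feather counts spread over roughly 101-161 by age and
damage, fishtail counts around the 3-row/4-row modes (~30/~40), and feather
lengths reported as means and SDs (ESL = eyespot-feather length, FTL =
fishtail-feather length, in cm).  This module draws whole synthetic
specimens consistent with those summaries so downstream code — the accretion
model, the summary tables, the constraint claim that within-cohort variance
is zero — is testable without any museum data.

The generative story per specimen: sample a row count and class-row counts,
take the *deterministic* lattice prediction for each feather class, then
remove feathers by independent per-feather damage (Bernoulli), and draw
lengths from zero-truncated Normals.  Damage only ever removes feathers, so
observed counts never exceed the lattice prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, InvalidParameterError
from .follicle_lattice import ArrangementScheme, RowSizes

__all__ = [
    "SpecimenParams",
    "SpecimenRecord",
    "SpecimenSummary",
    "generate_specimens",
    "records_to_dataframe",
    "summarize",
]

#: Columns summarized in the Table-1-style layout.
_SUMMARY_COLUMNS = [
    "n_rows",
    "eyespot_feather_count",
    "fishtail_feather_count",
    "esl_cm",
    "ftl_cm",
]


@dataclass(frozen=True)
class SpecimenParams:
    """Sampling distributions for one species' specimens.

    Defaults are the blue peafowl (*Pavo cristatus*) summary values: rows
    uniform on {17, 18, 19}, fishtail rows on {3, 4}, minor rows on {2, 3},
    and length Normals with the reported means/SDs.  Use
    :meth:`for_species` for the green peafowl (*P. muticus*)
    parameterization — same model, different numbers.
    """

    species: str = "cristatus"
    n_rows_support: tuple[int, ...] = (17, 18, 19)
    fishtail_rows_support: tuple[int, ...] = (3, 4)
    minor_rows_support: tuple[int, ...] = (2, 3)
    damage_rate: float = 0.05
    esl_mean: float = 112.68
    esl_sd: float = 25.58
    ftl_mean: float = 134.15
    ftl_sd: float = 32.17
    first_row_size: int = 10

    def __post_init__(self) -> None:
        for name in ("n_rows_support", "fishtail_rows_support", "minor_rows_support"):
            support = tuple(int(v) for v in getattr(self, name))
            if len(support) == 0 or any(v < 0 for v in support):
                raise InvalidParameterError(f"{name} must be non-empty, non-negative")
            object.__setattr__(self, name, support)
        if any(v < 1 for v in self.n_rows_support):
            raise InvalidParameterError("n_rows_support values must be >= 1")
        if not (0.0 <= self.damage_rate <= 1.0):
            raise InvalidParameterError(
                f"damage_rate must be in [0, 1], got {self.damage_rate}"
            )
        if self.esl_sd < 0 or self.ftl_sd < 0:
            raise InvalidParameterError("length SDs must be >= 0")
        if self.first_row_size not in (10, 11):
            raise InvalidParameterError("first_row_size must be 10 or 11")

    @classmethod
    def for_species(cls, species: str) -> "SpecimenParams":
        if species == "cristatus":
            return cls()
        if species == "muticus":
            return cls(
                species="muticus",
                n_rows_support=(19,),
                esl_mean=101.66,
                esl_sd=25.53,
                ftl_mean=120.16,
                ftl_sd=29.49,
            )
        raise InvalidParameterError(f"unknown species {species!r}")

    @property
    def scheme(self) -> ArrangementScheme:
        return ArrangementScheme(
            row_sizes=RowSizes.ALT_10_11, first_row_size=self.first_row_size
        )


@dataclass(frozen=True)
class SpecimenRecord:
    """One synthetic specimen.

    ``*_intact`` counts are the deterministic lattice predictions (damage
    corrected, i.e. counting a broken feather as if present); the plain
    counts are post-damage observations.
    """

    species: str
    n_rows: int
    n_fishtail_rows: int
    n_minor_rows: int
    eyespot_feather_count: int
    eyespot_feather_count_intact: int
    fishtail_feather_count: int
    n_damaged: int
    esl_cm: float
    ftl_cm: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero, deterministic under ``rng``."""
    if sd == 0.0:
        return float(max(mean, 0.0))
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def generate_specimens(
    n: int, params: SpecimenParams = SpecimenParams(), seed: int | None = None
) -> list[SpecimenRecord]:
    """Draw ``n`` synthetic specimens.

    Identical ``(n, params, seed)`` give identical records.  ``seed`` may be
    an integer or an already-constructed :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scheme = params.scheme
    records: list[SpecimenRecord] = []
    for _ in range(n):
        n_rows = int(rng.choice(params.n_rows_support))
        n_fish = int(rng.choice(params.fishtail_rows_support))
        n_minor = int(rng.choice(params.minor_rows_support))
        n_fish = min(n_fish, n_rows)
        n_minor = min(n_minor, n_rows - n_fish)
        sizes = scheme.sizes(n_rows)
        fishtail = sum(sizes[n_rows - n_fish:])
        eyespot_intact = sum(sizes[n_minor:n_rows - n_fish])
        n_damaged = int(rng.binomial(eyespot_intact, params.damage_rate))
        records.append(
            SpecimenRecord(
                species=params.species,
                n_rows=n_rows,
                n_fishtail_rows=n_fish,
                n_minor_rows=n_minor,
                eyespot_feather_count=eyespot_intact - n_damaged,
                eyespot_feather_count_intact=eyespot_intact,
                fishtail_feather_count=fishtail,
                n_damaged=n_damaged,
                esl_cm=_truncated_normal(rng, params.esl_mean, params.esl_sd),
                ftl_cm=_truncated_normal(rng, params.ftl_mean, params.ftl_sd),
            )
        )
    return records


def records_to_dataframe(records) -> pd.DataFrame:
    records = list(records)
    if not records:
        raise EmptyInputError("no specimen records")
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass(frozen=True)
class SpecimenSummary:
    """Per-species N / Mean / SD / Min / Max table (Table-1-style layout).

    SD is the sample standard deviation (n - 1 denominator), reported as 0
    for a single record.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def summarize(records) -> SpecimenSummary:
    """Summarize specimen records per species.

    Returns one row per (species, statistic) with statistic in
    N / Mean / SD / Min / Max, over the measured columns.
    """
    df = records_to_dataframe(records)
    rows = []
    for species, grp in df.groupby("species", sort=True):
        n = len(grp)
        stats_rows = {
            "N": {c: float(n) for c in _SUMMARY_COLUMNS},
            "Mean": {c: float(grp[c].mean()) for c in _SUMMARY_COLUMNS},
            "SD": {
                c: (float(grp[c].std(ddof=1)) if n > 1 else 0.0)
                for c in _SUMMARY_COLUMNS
            },
            "Min": {c: float(grp[c].min()) for c in _SUMMARY_COLUMNS},
            "Max": {c: float(grp[c].max()) for c in _SUMMARY_COLUMNS},
        }
        for stat, values in stats_rows.items():
            rows.append({"species": species, "statistic": stat, **values})
    return SpecimenSummary(table=pd.DataFrame(rows))
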