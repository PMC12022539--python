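"""Age-accretion model of train growth.

Eyespot number is not a free-floating trait: follicle rows are added
annually in the alternating 10/11 scheme, so the count a male carries is
fixed by his age (and row cap), with zero variation inside an age cohort.
Train length, by contrast, grows continuously and saturates.  This module
makes both claims computable: row accretion with a cap, the derived
eyespot/fishtail/minor counts per age class, and a saturating-exponential
length curve

    L(age) = L_inf * (1 - exp(-k * age)),

the simplest monotone bounded form for a trait described as asymptotic in
age (the functional form is this package's choice; only "asymptotic" is
biologically given).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .follicle_lattice import ArrangementScheme, RowSizes

__all__ = [
    "GrowthParams",
    "GrowthTrajectory",
    "rows_at_age",
    "eyespot_count_at_age",
    "class_counts_at_age",
    "train_length",
    "grow_trajectory",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the accretion model.

    Attributes
    ----------
    rows_per_year:
        Follicle rows added per breeding season (1 or occasionally 2).
    max_rows:
        Cap on the number of rows; museum plates show 17-19, so the default
        ceiling is 19.  Set high (or to the age horizon) to explore the
        uncapped ">200 eyespots over a ~20-year lifetime" scenario.
    n_fishtail_rows:
        Oldest rows bearing eyespot-less fishtail feathers (3-5 with age).
    n_minor_rows:
        Newest rows whose eyespots are still minor (2-3).
    length_asymptote, length_rate:
        Saturating-exponential train-length parameters: asymptote in cm
        (defaults near the longest museum feather lengths) and rate per
        year (default 0.5/yr puts the train at ~95% of asymptote by age 6,
        when displays mature).
    first_row_size:
        Size of the first-grown row (10 or 11); unknown in vivo, default 10.
    """

    rows_per_year: int = 1
    max_rows: int = 19
    n_fishtail_rows: int = 4
    n_minor_rows: int = 2
    length_asymptote: float = 160.0
    length_rate: float = 0.5
    first_row_size: int = 10

    def __post_init__(self) -> None:
        if self.rows_per_year < 1:
            raise InvalidParameterError(
                f"rows_per_year must be >= 1, got {self.rows_per_year}"
            )
        if self.max_rows < 1:
            raise InvalidParameterError(f"max_rows must be >= 1, got {self.max_rows}")
        if self.n_fishtail_rows < 0 or self.n_minor_rows < 0:
            raise InvalidParameterError("class row counts must be >= 0")
        if self.n_fishtail_rows + self.n_minor_rows > self.max_rows:
            raise InvalidParameterError(
                "fishtail + minor rows exceed max_rows"
            )
        if self.length_asymptote <= 0 or self.length_rate <= 0:
            raise InvalidParameterError("length parameters must be > 0")
        if self.first_row_size not in (10, 11):
            raise InvalidParameterError(
                f"first_row_size must be 10 or 11, got {self.first_row_size}"
            )

    @property
    def scheme(self) -> ArrangementScheme:
        return ArrangementScheme(
            row_sizes=RowSizes.ALT_10_11, first_row_size=self.first_row_size
        )


def rows_at_age(age: float, params: GrowthParams = GrowthParams()) -> int:
    """Number of follicle rows at a given age: min(rows_per_year * age, cap)."""
    if age < 0:
        raise InvalidParameterError(f"age must be >= 0, got {age}")
    return int(min(params.rows_per_year * int(age), params.max_rows))


def class_counts_at_age(
    age: float, params: GrowthParams = GrowthParams()
) -> dict[str, int]:
    """Feather counts by class (eyespot / fishtail / minor) at a given age.

    Fishtail rows are taken from the oldest end first, minor rows from the
    newest end; the remainder bears full eyespots.  The three classes always
    partition the total follicle count.
    """
    n = rows_at_age(age, params)
    sizes = params.scheme.sizes(n)
    n_fish = min(params.n_fishtail_rows, n)
    n_minor = min(params.n_minor_rows, n - n_fish)
    fishtail = sum(sizes[n - n_fish:])
    minor = sum(sizes[:n_minor])
    eyespot = sum(sizes[n_minor:n - n_fish])
    return {
        "eyespot": eyespot,
        "fishtail": fishtail,
        "minor": minor,
        "total": sum(sizes),
    }


def eyespot_count_at_age(age: float, params: GrowthParams = GrowthParams()) -> int:
    """Full (non-minor, non-fishtail) eyespot count at a given age.

    With the default 4 fishtail and 2 minor rows, a capped 19-row male keeps
    13 eyespot-bearing rows; 16 eyespot-bearing rows give 168, inside the
    165-170 band typical of mature males.
    """
    return class_counts_at_age(age, params)["eyespot"]


def train_length(age: float, params: GrowthParams = GrowthParams()) -> float:
    """Saturating train length L_inf * (1 - exp(-k * age)) in cm."""
    if age < 0:
        raise InvalidParameterError(f"age must be >= 0, got {age}")
    return float(params.length_asymptote * (1.0 - np.exp(-params.length_rate * age)))


@dataclass(frozen=True)
class GrowthTrajectory:
    """Per-age records of the accretion model."""

    params: GrowthParams
    table: pd.DataFrame  # age, n_rows, total_follicles, visible_eyespots, ...

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def grow_trajectory(
    max_age: int = 20, params: GrowthParams = GrowthParams()
) -> GrowthTrajectory:
    """Tabulate the model from age 0 to ``max_age`` inclusive."""
    if max_age < 0:
        raise InvalidParameterError(f"max_age must be >= 0, got {max_age}")
    records = []
    for age in range(max_age + 1):
        counts = class_counts_at_age(age, params)
        records.append(
            {
                "age": age,
                "n_rows": rows_at_age(age, params),
                "total_follicles": counts["total"],
                "visible_eyespots": counts["eyespot"],
                "fishtail_count": counts["fishtail"],
                "minor_count": counts["minor"],
                "train_length": train_length(age, params),
            }
        )
    return GrowthTrajectory(params=params, table=pd.DataFrame(records))
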