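"""Condensed lattice of feather-follicle insertion points on the uropygial anchor plate.

The peacock's train coverts anchor on the ventral face of the uropygium in
tightly packed rows of 10 or 11 follicles.  Consecutive rows alternate 10/11
and are staggered by half the within-row pitch (a zigzag), which is the 2-D
analogue of densest sphere packing.  This module builds that condensed layout
for the alternating scheme and for the contrast schemes (parallel alignment,
constant row sizes) used to probe what the zigzag buys developmentally.

Coordinate convention: the anchor-plate plane has its midline at x = 0, the
anterior (newest, smallest-follicle) row at y = 0, and posterior rows at
increasing y.  All lengths are abstract units unless stated otherwise.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "Alignment",
    "RowSizes",
    "ArrangementScheme",
    "Follicle",
    "FollicleLattice",
    "build_lattice",
    "total_follicles",
    "anchor_outline",
]


class Alignment(str, enum.Enum):
    """Row-to-row alignment: staggered (zigzag) or unstaggered (parallel)."""

    ZIGZAG = "zigzag"
    PARALLEL = "parallel"


class RowSizes(str, enum.Enum):
    """Row-size scheme: alternating 10/11 or a constant size."""

    ALT_10_11 = "alt_10_11"
    CONST_10 = "const_10"
    CONST_11 = "const_11"


#: The four arrangement contrasts of interest, by short name.
_SCHEME_NAMES = {
    "zigzag_10_11": (Alignment.ZIGZAG, RowSizes.ALT_10_11),
    "parallel_10_11": (Alignment.PARALLEL, RowSizes.ALT_10_11),
    "zigzag_10_10": (Alignment.ZIGZAG, RowSizes.CONST_10),
    "zigzag_11_11": (Alignment.ZIGZAG, RowSizes.CONST_11),
    "parallel_10_10": (Alignment.PARALLEL, RowSizes.CONST_10),
    "parallel_11_11": (Alignment.PARALLEL, RowSizes.CONST_11),
}


@dataclass(frozen=True)
class ArrangementScheme:
    """How follicle rows are sized and aligned.

    Parameters
    ----------
    alignment:
        ``zigzag`` (consecutive rows staggered by half the within-row pitch)
        or ``parallel`` (no stagger).
    row_sizes:
        ``alt_10_11`` for the observed alternating scheme, or ``const_10`` /
        ``const_11`` for the constant-size contrasts.
    first_row_size:
        Size of the anterior row (row 0); only meaningful for ``alt_10_11``.
    """

    alignment: Alignment = Alignment.ZIGZAG
    row_sizes: RowSizes = RowSizes.ALT_10_11
    first_row_size: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "alignment", Alignment(self.alignment))
        object.__setattr__(self, "row_sizes", RowSizes(self.row_sizes))
        if self.row_sizes is RowSizes.ALT_10_11 and self.first_row_size not in (10, 11):
            raise InvalidParameterError(
                f"first_row_size must be 10 or 11 for alt_10_11, got {self.first_row_size}"
            )

    @classmethod
    def from_name(cls, name: str, first_row_size: int = 10) -> "ArrangementScheme":
        """Build a scheme from a short name such as ``zigzag_10_11``."""
        try:
            alignment, row_sizes = _SCHEME_NAMES[name]
        except KeyError:
            raise InvalidParameterError(
                f"unknown scheme {name!r}; one of {sorted(_SCHEME_NAMES)}"
            ) from None
        return cls(alignment, row_sizes, first_row_size)

    @property
    def name(self) -> str:
        for name, pair in _SCHEME_NAMES.items():
            if pair == (self.alignment, self.row_sizes):
                return name
        raise AssertionError("unreachable")

    def row_size(self, row_index: int) -> int:
        """Number of follicles in the row at ``row_index`` (0 = anterior)."""
        if self.row_sizes is RowSizes.CONST_10:
            return 10
        if self.row_sizes is RowSizes.CONST_11:
            return 11
        return self.first_row_size if row_index % 2 == 0 else 21 - self.first_row_size

    def sizes(self, n_rows: int) -> list[int]:
        return [self.row_size(r) for r in range(n_rows)]

    def to_dict(self) -> dict:
        return {
            "alignment": self.alignment.value,
            "row_sizes": self.row_sizes.value,
            "first_row_size": self.first_row_size,
        }


@dataclass(frozen=True)
class Follicle:
    """One follicle insertion point on the anchor plate."""

    row_index: int
    position_index: int
    x: float
    y: float
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError(f"diameter must be > 0, got {self.diameter}")


@dataclass(frozen=True)
class FollicleLattice:
    """The condensed follicle layout: rows of insertion points on the plate.

    Invariants (enforced by :func:`build_lattice`): the follicle count equals
    the closed-form row-size sum, diameters are non-decreasing with row index
    (anterior smaller, posterior larger), and every row is mirror-symmetric
    about the midline x = 0.
    """

    scheme: ArrangementScheme
    n_rows: int
    row_pitch: float
    within_row_pitch: float
    follicles: tuple[Follicle, ...]

    def __len__(self) -> int:
        return len(self.follicles)

    def positions(self) -> np.ndarray:
        """(N, 2) array of follicle centers."""
        return np.array([[f.x, f.y] for f in self.follicles], dtype=float).reshape(-1, 2)

    def row_x(self, row_index: int) -> np.ndarray:
        """Sorted x coordinates of the follicles in one row."""
        xs = [f.x for f in self.follicles if f.row_index == row_index]
        return np.sort(np.asarray(xs, dtype=float))

    def diameters(self) -> np.ndarray:
        return np.asarray([f.diameter for f in self.follicles], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_index": [f.row_index for f in self.follicles],
                "position_index": [f.position_index for f in self.follicles],
                "x": [f.x for f in self.follicles],
                "y": [f.y for f in self.follicles],
                "diameter": [f.diameter for f in self.follicles],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self) -> str:
        """Serialize the scheme and geometry parameters (not the point list)."""
        return json.dumps(
            {
                "scheme": self.scheme.to_dict(),
                "n_rows": self.n_rows,
                "row_pitch": self.row_pitch,
                "within_row_pitch": self.within_row_pitch,
                "n_follicles": len(self),
            },
            sort_keys=True,
        )


def total_follicles(
    row_sizes: RowSizes | str, n_rows: int, first_row_size: int = 10
) -> int:
    """Closed-form follicle count for ``n_rows`` rows of the given scheme.

    For the alternating scheme the sum pairs up as 21 per two rows, so an
    18-row plate carries 9x10 + 9x11 = 189 follicles, and 16 eyespot-bearing
    rows carry 168 -- inside the 165-170 band reported for mature males.
    """
    row_sizes = RowSizes(row_sizes)
    if n_rows < 0:
        raise InvalidParameterError(f"n_rows must be >= 0, got {n_rows}")
    if row_sizes is RowSizes.CONST_10:
        return 10 * n_rows
    if row_sizes is RowSizes.CONST_11:
        return 11 * n_rows
    if first_row_size not in (10, 11):
        raise InvalidParameterError(
            f"first_row_size must be 10 or 11, got {first_row_size}"
        )
    # pairs of consecutive rows always sum to 21
    return 21 * (n_rows // 2) + (n_rows % 2) * first_row_size


def _centered_row_x(n: int, pitch: float) -> np.ndarray:
    """Uniformly spaced, midline-centered row: offsets +-(i - (n-1)/2) * pitch.

    Odd n lands on the "integer" grid (one follicle exactly on the midline);
    even n lands on the "half-integer" grid.  Offsets are exact mirror pairs
    in floating point by construction.
    """
    return (np.arange(n, dtype=float) - (n - 1) / 2.0) * pitch


def _outward_shifted_row_x(n: int, pitch: float) -> np.ndarray:
    """Centered row with each off-midline follicle displaced half a pitch
    away from the midline (the midline follicle, if any, stays put).

    This is the mirror-symmetric stagger used for constant-size zigzag
    schemes, where a plain half-pitch translation would break bilateral
    symmetry: for even n it yields the skip-center grid (e.g. +-1..+-5 for
    n = 10, i.e. the gap midpoints of the reference row plus one slot beyond
    each end), every point exactly half a pitch from the nearest reference
    follicle.
    """
    base = _centered_row_x(n, pitch)
    return base + np.sign(base) * 0.5 * pitch


def _zigzag_row_x(scheme: ArrangementScheme, row_index: int, pitch: float) -> np.ndarray:
    n = scheme.row_size(row_index)
    if scheme.row_sizes is RowSizes.ALT_10_11:
        # 10s and 11s alternate parity, so the centered grids interleave at
        # exactly half a pitch on their own: 11-rows sit on integer multiples
        # of the pitch (five follicles either side of the mid-feather),
        # 10-rows on the midpoints.
        return _centered_row_x(n, pitch)
    if row_index % 2 == 0:
        return _centered_row_x(n, pitch)
    return _outward_shifted_row_x(n, pitch)


def _parallel_row_x(scheme: ArrangementScheme, row_index: int, pitch: float) -> np.ndarray:
    n = scheme.row_size(row_index)
    max_size = max(scheme.sizes(2))
    span = (max_size - 1) * pitch
    if n == 1:
        return np.zeros(1)
    # every row stretched over the same span; unequal row sizes therefore get
    # unequal pitches and no stagger arises (centered grid keeps the offsets
    # exact mirror pairs, unlike linspace)
    return _centered_row_x(n, span / (n - 1))


def _default_diameter_profile(n_rows: int) -> Callable[[int], float]:
    """Linear gradient 0.5 -> 1.0 units from anterior to posterior."""
    if n_rows == 1:
        return lambda r: 0.75
    return lambda r: 0.5 + 0.5 * r / (n_rows - 1)


def build_lattice(
    scheme: ArrangementScheme | str = ArrangementScheme(),
    n_rows: int = 18,
    row_pitch: float = 1.0,
    within_row_pitch: float = 1.0,
    diameter_profile: Callable[[int], float] | None = None,
) -> FollicleLattice:
    """Construct the condensed follicle lattice.

    Parameters
    ----------
    scheme:
        Arrangement scheme, or its short name (``zigzag_10_11`` etc.).
    n_rows:
        Number of follicle rows (museum plates show 17-19).
    row_pitch, within_row_pitch:
        Row-to-row and within-row spacing in abstract plate units.
    diameter_profile:
        Monotone map ``row_index -> diameter``; default is a linear gradient
        from 0.5 (anterior, newest) to 1.0 (posterior, oldest) units.

    Raises
    ------
    InvalidParameterError
        For non-positive ``n_rows`` or pitches, or a non-monotone profile.
    """
    if isinstance(scheme, str):
        scheme = ArrangementScheme.from_name(scheme)
    if n_rows < 1:
        raise InvalidParameterError(f"n_rows must be >= 1, got {n_rows}")
    if row_pitch <= 0 or within_row_pitch <= 0:
        raise InvalidParameterError(
            f"pitches must be > 0, got row_pitch={row_pitch}, "
            f"within_row_pitch={within_row_pitch}"
        )
    if diameter_profile is None:
        diameter_profile = _default_diameter_profile(n_rows)

    row_fn = (
        _zigzag_row_x if scheme.alignment is Alignment.ZIGZAG else _parallel_row_x
    )
    follicles: list[Follicle] = []
    prev_d = -np.inf
    for r in range(n_rows):
        d = float(diameter_profile(r))
        if d < prev_d:
            raise InvalidParameterError(
                f"diameter_profile must be non-decreasing; row {r} has {d} < {prev_d}"
            )
        prev_d = d
        xs = row_fn(scheme, r, within_row_pitch)
        y = r * row_pitch
        for i, x in enumerate(xs):
            follicles.append(Follicle(r, i, float(x), float(y), d))

    lattice = FollicleLattice(
        scheme=scheme,
        n_rows=n_rows,
        row_pitch=float(row_pitch),
        within_row_pitch=float(within_row_pitch),
        follicles=tuple(follicles),
    )
    expected = sum(scheme.sizes(n_rows))
    assert len(lattice) == expected, "row construction lost follicles"
    return lattice


def anchor_outline(lattice: FollicleLattice, n_vertices: int = 64) -> np.ndarray:
    """Closed oval polygon (the uropygial plate boundary) enclosing the lattice.

    Returns an ``(n_vertices, 2)`` ellipse strictly containing every follicle
    center, for rendering and plate-area estimates.

    Raises
    ------
    EmptyInputError
        If the lattice holds no follicles.
    """
    if len(lattice) == 0:
        raise EmptyInputError("cannot outline an empty lattice")
    pts = lattice.positions()
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    center = (lo + hi) / 2.0
    pad = 0.75 * max(lattice.within_row_pitch, lattice.row_pitch, lattice.diameters().max())
    # semi-axes: half-extent scaled out so that even corner points satisfy
    # (dx/a)^2 + (dy/b)^2 < 1
    half = (hi - lo) / 2.0
    a = half[0] * np.sqrt(2.0) + pad
    b = half[1] * np.sqrt(2.0) + pad
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.c_[center[0] + a * np.cos(t), center[1] + b * np.sin(t)]
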