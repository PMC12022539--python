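"""Bilateral expansion of the follicle lattice into the erected display fan.

Each follicle corresponds to one covert feather whose tip carries an eyespot,
so expanding the condensed plate layout radially — rows onto concentric arcs,
oldest (posterior) row outermost, dot sizes growing outward — predicts the
2-D eyespot arrangement seen on the erected train.  The half-pitch stagger of
the zigzag lattice maps to exactly half the angular pitch, which is what
turns the plate's dense packing into the hexagonal eyespot packing of the
display.  Only the flat frontal projection is modelled, not the train's 3-D
convexity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError
from .follicle_lattice import ArrangementScheme, FollicleLattice

__all__ = [
    "FeatherClass",
    "ExpansionGeometry",
    "TrainPoint",
    "TrainPattern",
    "expand",
    "classify_feathers",
    "render",
]

_FULL_CIRCLE_TOL = 1e-9


class FeatherClass(str, enum.Enum):
    """Covert feather classes on the erected train."""

    EYESPOT = "eyespot"  # full ocellus at the feather tip
    FISHTAIL = "fishtail"  # eyespot-less fringe from the oldest rows
    MINOR = "minor"  # immature small ocelli on the newest rows


@dataclass(frozen=True)
class ExpansionGeometry:
    """Geometry of the fan transform.

    Attributes
    ----------
    fan_span:
        Angular width of the fan in degrees (0 < span <= 360).  The display
        fan is roughly a half disc, so the default is 180.
    base_radius:
        Radius of the innermost (anterior, newest) row arc.  The default of
        3 units makes the inner-arc spacing comparable to the radial pitch,
        as on the animal.
    radial_pitch:
        Radial distance between consecutive row arcs.
    midline_angle:
        Direction of the fan's mirror axis in degrees (90 = straight up).
    dot_size_profile:
        Monotone map ``row_index -> dot diameter``; default linear 0.5 -> 1.0
        from the innermost to the outermost row.
    """

    fan_span: float = 180.0
    base_radius: float = 3.0
    radial_pitch: float = 1.0
    midline_angle: float = 90.0
    dot_size_profile: Callable[[int], float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fan_span <= 360.0):
            raise InvalidParameterError(
                f"fan_span must be in (0, 360], got {self.fan_span}"
            )
        if self.base_radius < 0:
            raise InvalidParameterError(
                f"base_radius must be >= 0, got {self.base_radius}"
            )
        if self.radial_pitch <= 0:
            raise InvalidParameterError(
                f"radial_pitch must be > 0, got {self.radial_pitch}"
            )


@dataclass(frozen=True)
class TrainPoint:
    """One eyespot/feather-tip position on the expanded train."""

    angle_deg: float
    radius: float
    dot_diameter: float
    feather_class: FeatherClass
    source_row: int
    source_position: int

    @property
    def xy(self) -> tuple[float, float]:
        t = np.deg2rad(self.angle_deg)
        return (self.radius * np.cos(t), self.radius * np.sin(t))


@dataclass(frozen=True)
class TrainPattern:
    """The expanded 2-D display pattern.

    Point count equals the source lattice's follicle count, the pattern is
    mirror-symmetric about the midline by construction, and dot diameters are
    non-decreasing with radius across rows.
    """

    points: tuple[TrainPoint, ...]
    geometry: ExpansionGeometry
    scheme: ArrangementScheme
    n_rows: int

    def __len__(self) -> int:
        return len(self.points)

    def angles(self) -> np.ndarray:
        return np.asarray([p.angle_deg for p in self.points], dtype=float)

    def radii(self) -> np.ndarray:
        return np.asarray([p.radius for p in self.points], dtype=float)

    def xy(self) -> np.ndarray:
        """(N, 2) cartesian coordinates."""
        t = np.deg2rad(self.angles())
        r = self.radii()
        return np.c_[r * np.cos(t), r * np.sin(t)]

    def select(self, *classes: FeatherClass | str) -> "TrainPattern":
        """Sub-pattern restricted to the given feather classes."""
        wanted = {FeatherClass(c) for c in classes}
        pts = tuple(p for p in self.points if p.feather_class in wanted)
        return replace(self, points=pts)

    def class_counts(self) -> dict[str, int]:
        counts = {c.value: 0 for c in FeatherClass}
        for p in self.points:
            counts[p.feather_class.value] += 1
        return counts

    def min_angular_pitch(self) -> float:
        """Smallest within-row angular spacing (degrees) over all rows."""
        best = np.inf
        for r in range(self.n_rows):
            a = np.sort([p.angle_deg for p in self.points if p.source_row == r])
            if len(a) >= 2:
                best = min(best, float(np.diff(a).min()))
        if not np.isfinite(best):
            raise InvalidParameterError("pattern has no multi-point rows")
        return best

    def to_dataframe(self) -> pd.DataFrame:
        xy = self.xy()
        return pd.DataFrame(
            {
                "angle_deg": self.angles(),
                "radius": self.radii(),
                "x": xy[:, 0],
                "y": xy[:, 1],
                "dot_diameter": [p.dot_diameter for p in self.points],
                "feather_class": [p.feather_class.value for p in self.points],
                "source_row": [p.source_row for p in self.points],
                "source_position": [p.source_position for p in self.points],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _default_dot_profile(n_rows: int) -> Callable[[int], float]:
    if n_rows == 1:
        return lambda r: 0.75
    return lambda r: 0.5 + 0.5 * r / (n_rows - 1)


def expand(
    lattice: FollicleLattice, geometry: ExpansionGeometry = ExpansionGeometry()
) -> TrainPattern:
    """Map the condensed lattice onto the fan.

    A single affine map sends plate x-coordinates to angles for *all* rows
    (``angle = midline + x * span / (2 * x_max)``), so the lattice's
    half-pitch x-offsets become exactly half the angular pitch and the
    stagger survives expansion.  Row ``r`` lands on the arc of radius
    ``base_radius + r * radial_pitch``; since row index grows with follicle
    age, the oldest row is outermost.  For a full 360-degree span the angular
    scale adds one within-row pitch of clearance so the two fan edges do not
    overlap and points space uniformly around the circle.
    """
    if len(lattice) == 0:
        raise EmptyInputError("cannot expand an empty lattice")
    profile = geometry.dot_size_profile or _default_dot_profile(lattice.n_rows)

    xs = lattice.positions()[:, 0]
    x_max = float(np.abs(xs).max())
    if x_max == 0.0:  # degenerate: all follicles on the midline
        deg_per_unit = 0.0
    elif abs(geometry.fan_span - 360.0) < _FULL_CIRCLE_TOL:
        deg_per_unit = 360.0 / (2.0 * x_max + lattice.within_row_pitch)
    else:
        deg_per_unit = geometry.fan_span / (2.0 * x_max)

    points: list[TrainPoint] = []
    prev_d = -np.inf
    for f in lattice.follicles:
        d = float(profile(f.row_index))
        if f.row_index > 0 and d < prev_d and f.position_index == 0:
            raise InvalidParameterError("dot_size_profile must be non-decreasing")
        if f.position_index == 0:
            prev_d = d
        points.append(
            TrainPoint(
                angle_deg=geometry.midline_angle + f.x * deg_per_unit,
                radius=geometry.base_radius + f.row_index * geometry.radial_pitch,
                dot_diameter=d,
                feather_class=FeatherClass.EYESPOT,
                source_row=f.row_index,
                source_position=f.position_index,
            )
        )
    return TrainPattern(
        points=tuple(points),
        geometry=geometry,
        scheme=lattice.scheme,
        n_rows=lattice.n_rows,
    )


def classify_feathers(
    pattern: TrainPattern, n_fishtail_rows: int = 4, n_minor_rows: int = 2
) -> TrainPattern:
    """Label rows by feather class.

    The outermost (oldest) ``n_fishtail_rows`` rows become fishtails — the
    eyespot-less fringe, 3-5 rows depending on age — and the innermost
    (newest) ``n_minor_rows`` rows become minor, the 2-3 rows whose ocelli
    are still developmentally immature.  Everything between is a full
    eyespot feather.
    """
    if n_fishtail_rows < 0 or n_minor_rows < 0:
        raise InvalidParameterError("class row counts must be >= 0")
    if n_fishtail_rows + n_minor_rows > pattern.n_rows:
        raise InvalidParameterError(
            f"fishtail ({n_fishtail_rows}) + minor ({n_minor_rows}) rows exceed "
            f"total rows ({pattern.n_rows})"
        )
    first_fishtail = pattern.n_rows - n_fishtail_rows
    relabelled = []
    for p in pattern.points:
        if p.source_row >= first_fishtail:
            cls = FeatherClass.FISHTAIL
        elif p.source_row < n_minor_rows:
            cls = FeatherClass.MINOR
        else:
            cls = FeatherClass.EYESPOT
        relabelled.append(replace(p, feather_class=cls))
    return replace(pattern, points=tuple(relabelled))


_DEFAULT_COLORS = {
    FeatherClass.EYESPOT: "#1f77b4",
    FeatherClass.FISHTAIL: "#2ca02c",
    FeatherClass.MINOR: "#9467bd",
}


def render(
    pattern: TrainPattern,
    path,
    fmt: str | None = None,
    colors: dict | None = None,
    scale: float = 20.0,
):
    """Render the pattern: one filled dot per point, colored by class.

    ``fmt`` is inferred from the path suffix when omitted; ``svg`` output is
    a deterministic text file (identical input gives byte-identical output),
    ``png`` goes through matplotlib.
    """
    if len(pattern) == 0:
        raise EmptyInputError("cannot render an empty pattern")
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    cmap = dict(_DEFAULT_COLORS)
    if colors:
        cmap.update({FeatherClass(k): v for k, v in colors.items()})

    xy = pattern.xy()
    diam = np.asarray([p.dot_diameter for p in pattern.points])
    if fmt == "svg":
        from ._svg import SvgCanvas

        lo = xy.min(axis=0) - diam.max()
        hi = xy.max(axis=0) + diam.max()
        canvas = SvgCanvas(lo, hi, scale=scale)
        for (x, y), d, p in zip(xy, diam, pattern.points):
            canvas.circle(x, y, d / 2.0, fill=cmap[p.feather_class])
        canvas.save(path)
    elif fmt == "png":
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 6))
        for cls in FeatherClass:
            mask = np.asarray([p.feather_class is cls for p in pattern.points])
            if mask.any():
                ax.scatter(
                    xy[mask, 0],
                    xy[mask, 1],
                    s=(scale * diam[mask]) ** 2 / 4.0,
                    c=cmap[cls],
                    label=cls.value,
                    linewidths=0,
                )
        ax.set_aspect("equal")
        ax.legend(loc="lower right", frameon=False)
        ax.set_axis_off()
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    else:
        raise InvalidParameterError(f"unsupported render format {fmt!r}")
    return path
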