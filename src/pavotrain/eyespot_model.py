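"""Palindromic follicle-type model of eyespot ring formation.

An 11-feather row can be read as a central follicle flanked by five
structurally distinct follicle types mirrored on either side — an inverted
tandem duplication, hence a palindrome:

    T5 T4 T3 T2 T1 C T1 T2 T3 T4 T5

Walking outward from the center of that palindrome reproduces, type by
type, the concentric color zones of a single eyespot (center plus one ring
per flanking type), so the same positional information that lays out a row
of follicles can lay out an ocellus.  This module implements that
structural core: building the palindrome, collapsing it to a ring sequence,
placing it on the shared 11-position row grid, and rendering the nested
ovals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, InvalidParameterError
from .follicle_lattice import _centered_row_x

__all__ = [
    "FolliclePalindrome",
    "RingSequence",
    "build_palindrome",
    "palindrome_to_rings",
    "place_on_row",
    "render_eyespot",
]


@dataclass(frozen=True)
class FolliclePalindrome:
    """A mirror-symmetric row of follicle-type labels around a unique center."""

    row: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.row) % 2 != 1:
            raise InvalidParameterError("palindrome length must be odd")
        if tuple(reversed(self.row)) != self.row:
            raise InvalidParameterError("row is not palindromic")
        center = self.row[len(self.row) // 2]
        if self.row.count(center) != 1:
            raise InvalidParameterError("center label must be unique")

    @property
    def follicle_types(self) -> int:
        return len(self.row) // 2

    @property
    def center(self) -> str:
        return self.row[len(self.row) // 2]


@dataclass(frozen=True)
class RingSequence:
    """Concentric eyespot zones, center outward (zone 0 = central follicle type)."""

    zones: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.zones) < 1:
            raise EmptyInputError("a ring sequence needs at least one zone")

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    def to_json(self) -> str:
        return json.dumps({"zones": list(self.zones)})


def build_palindrome(
    follicle_types: int = 5, labels=None, center: str = "C"
) -> FolliclePalindrome:
    """Build the inverted-tandem-duplication row for ``follicle_types`` types.

    The default of 5 types gives an 11-element row, matching an 11-feather
    lattice row with its five structurally different follicles on each side
    of the central feather.
    """
    if follicle_types < 1:
        raise InvalidParameterError(
            f"follicle_types must be >= 1, got {follicle_types}"
        )
    if labels is None:
        labels = tuple(f"T{i}" for i in range(1, follicle_types + 1))
    labels = tuple(labels)
    if len(labels) != follicle_types or len(set(labels)) != follicle_types:
        raise InvalidParameterError("labels must be distinct and match follicle_types")
    if center in labels:
        raise InvalidParameterError("center label must differ from type labels")
    return FolliclePalindrome(row=tuple(reversed(labels)) + (center,) + labels)


def palindrome_to_rings(palindrome: FolliclePalindrome) -> RingSequence:
    """Collapse a palindrome to its concentric-ring reading.

    Zone i takes the type at distance i from the palindrome's center, so a
    k-type palindrome yields k + 1 zones (central follicle plus one ring per
    flanking type).
    """
    mid = len(palindrome.row) // 2
    return RingSequence(zones=tuple(palindrome.row[mid:]))


def place_on_row(
    palindrome: FolliclePalindrome, within_row_pitch: float = 1.0
) -> list[tuple[float, str]]:
    """Lay the palindrome onto the same centered row grid the lattice uses.

    Returns ``(x, type_label)`` pairs; for 5 types this is exactly the
    11-position integer grid of an 11-follicle lattice row, with the center
    type on the midline.
    """
    xs = _centered_row_x(len(palindrome.row), within_row_pitch)
    return [(float(x), label) for x, label in zip(xs, palindrome.row)]


#: Abstract peacock-ish palette keyed by zone order; presentation only.
_DEFAULT_PALETTE = [
    "#1a1a6e",  # deep blue center
    "#0f6e5a",  # blue-green
    "#3c8c3c",  # green
    "#a8842c",  # bronze
    "#6e3ca0",  # purple
    "#c8b43c",  # outer gold
]


def render_eyespot(
    rings: RingSequence,
    path,
    ellipse_aspect: float = 1.4,
    palette=None,
    scale: float = 40.0,
) -> str:
    """Render the ring sequence as nested concentric ellipses (SVG).

    ``ellipse_aspect`` is the height/width ratio of the ovals (1.0 draws
    circles).  Output is deterministic: identical input yields byte-identical
    SVG.
    """
    if rings.n_zones < 1:
        raise EmptyInputError("cannot render an empty ring sequence")
    if ellipse_aspect <= 0:
        raise InvalidParameterError(f"ellipse_aspect must be > 0, got {ellipse_aspect}")
    palette = list(palette) if palette is not None else _DEFAULT_PALETTE
    if len(palette) < rings.n_zones:
        palette = [palette[i % len(palette)] for i in range(rings.n_zones)]

    from ._svg import SvgCanvas

    n = rings.n_zones
    rx_max = 1.0
    ry_max = rx_max * ellipse_aspect
    lo = np.array([-rx_max * 1.1, -ry_max * 1.1])
    hi = -lo
    canvas = SvgCanvas(lo, hi, scale=scale)
    # paint outermost zone first so inner zones stay visible on top
    for i in reversed(range(n)):
        frac = (i + 1) / n
        canvas.ellipse(0.0, 0.0, rx_max * frac, ry_max * frac, fill=palette[i])
    canvas.save(path)
    return str(path)
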