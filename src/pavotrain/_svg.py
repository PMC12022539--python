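"""Minimal deterministic SVG writer.

Emits plain-text SVG with fixed number formatting so identical input always
produces byte-identical output, which keeps renders reproducible and
diffable.  Only the primitives the package draws (circles, ellipses,
polygons) are supported.
"""

from __future__ import annotations

import numpy as np


def _fmt(v: float) -> str:
    # fixed 4-decimal formatting; avoids "-0.0000"
    s = f"{float(v):.4f}"
    return "0.0000" if s == "-0.0000" else s


class SvgCanvas:
    """A y-up drawing surface mapped onto SVG's y-down pixel space."""

    def __init__(self, lo, hi, scale: float = 20.0, background: str | None = None):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.scale = float(scale)
        size = (self.hi - self.lo) * self.scale
        self.width = max(size[0], 1.0)
        self.height = max(size[1], 1.0)
        self.elements: list[str] = []
        if background:
            self.elements.append(
                f'<rect width="{_fmt(self.width)}" height="{_fmt(self.height)}" '
                f'fill="{background}" />'
            )

    def _pix(self, x: float, y: float) -> tuple[float, float]:
        return (
            (x - self.lo[0]) * self.scale,
            (self.hi[1] - y) * self.scale,
        )

    def circle(self, x: float, y: float, r: float, fill: str = "#000000") -> None:
        cx, cy = self._pix(x, y)
        self.elements.append(
            f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r * self.scale)}" '
            f'fill="{fill}" />'
        )

    def ellipse(
        self, x: float, y: float, rx: float, ry: float, fill: str = "#000000"
    ) -> None:
        cx, cy = self._pix(x, y)
        self.elements.append(
            f'<ellipse cx="{_fmt(cx)}" cy="{_fmt(cy)}" rx="{_fmt(rx * self.scale)}" '
            f'ry="{_fmt(ry * self.scale)}" fill="{fill}" />'
        )

    def polygon(
        self, vertices, fill: str = "none", stroke: str = "#000000"
    ) -> None:
        pts = " ".join(
            f"{_fmt(px)},{_fmt(py)}" for px, py in (self._pix(x, y) for x, y in vertices)
        )
        self.elements.append(
            f'<polygon points="{pts}" fill="{fill}" stroke="{stroke}" />'
        )

    def tostring(self) -> str:
        header = (
            '<?xml version="1.0" encoding="utf-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'width="{_fmt(self.width)}" height="{_fmt(self.height)}" '
            f'viewBox="0 0 {_fmt(self.width)} {_fmt(self.height)}">\n'
        )
        return header + "\n".join(self.elements) + "\n</svg>\n"

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.tostring())
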