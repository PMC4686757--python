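"""Riverlake logos: dinucleotide-aware sequence visualization.

A riverlake renders a first-order Markov motif model as columns of four
circles (one per base, radius proportional to the mononucleotide
frequency) connected by lines whose width is proportional to the joint
frequency of the corresponding adjacent dinucleotide.  Lines whose
dinucleotide is more frequent than predicted from the mononucleotide
frequencies are drawn in dark blue; lines less frequent than predicted
are drawn as yellow dotted lines.  The mononucleotide frequency at each
position is derived from the dinucleotide model itself: first-base
marginals of each pair, and second-base marginals for the final
position.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._alphabet import BASES
from .motif import DinucModel


def mono_from_dinuc(model: DinucModel) -> np.ndarray:
    """(L, 4) mononucleotide frequencies marginalized from pair rows.

    m_i(b) = sum_b2 p_i(b, b2) for i < L-1; the last position uses the
    second-base marginal of the final pair.
    """
    pairs = model.pair_probs.reshape(-1, 4, 4)
    mono = np.empty((len(model), 4))
    mono[:-1] = pairs.sum(axis=2)
    mono[-1] = pairs[-1].sum(axis=0)
    return mono


def excess_matrix(model: DinucModel, mono: Optional[np.ndarray] = None) -> np.ndarray:
    """Signed departure from positional independence, (L-1, 16).

    e_i(b1, b2) = p_i(b1, b2) - m_i(b1) * m_{i+1}(b2); each row sums to 0.
    """
    if mono is None:
        mono = mono_from_dinuc(model)
    expected = mono[:-1][:, :, None] * mono[1:][:, None, :]
    return model.pair_probs - expected.reshape(-1, 16)


# -------------------------------------------------------------------- layout

@dataclass(frozen=True)
class RiverlakeStyle:
    """Geometry and colour constants for riverlake rendering (pixels)."""

    radius_scale: float = 40.0
    width_scale: float = 40.0
    column_spacing: float = 110.0
    row_spacing: float = 95.0
    margin: float = 60.0
    excess_threshold: float = 0.01
    min_radius: float = 0.5           # anchors for circles with m < 0.005
    base_colors: Tuple[str, str, str, str] = ("#109648", "#255C99", "#F7B32B", "#D62839")
    neutral_color: str = "#B8B8B8"
    excess_color: str = "#00338D"     # dark blue
    deficit_color: str = "#FFD700"    # yellow
    deficit_dash: str = "4 3"
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 18.0

    def __post_init__(self):
        if self.radius_scale <= 0 or self.width_scale <= 0:
            raise ValueError("scales must be strictly positive")
        if not (0 <= self.excess_threshold < 1):
            raise ValueError("excess_threshold must be in [0, 1)")


@dataclass(frozen=True)
class Circle:
    position: int
    base: str
    x: float
    y: float
    radius: float
    frequency: float


@dataclass(frozen=True)
class Edge:
    position: int          # left column index i of the pair (i, i+1)
    base_from: str
    base_to: str
    x1: float
    y1: float
    x2: float
    y2: float
    width: float           # width_scale * p_i(b1, b2)
    frequency: float
    excess: float          # e_i(b1, b2)
    klass: str             # 'neutral' | 'excess' | 'deficit'


@dataclass
class RiverlakeLayout:
    """Geometric scene derived from a DinucModel, ready for SVG export."""

    circles: List[Circle]
    edges: List[Edge]
    style: RiverlakeStyle
    mono: np.ndarray
    excess: np.ndarray
    width: float = 0.0
    height: float = 0.0

    def circle(self, position: int, base: str) -> Circle:
        idx = position * 4 + BASES.index(base)
        return self.circles[idx]


def build_layout(model: DinucModel, style: Optional[RiverlakeStyle] = None) -> RiverlakeLayout:
    """Lay out circles and edges for a dinucleotide model.

    Edge widths encode the full dinucleotide frequency (width_scale * p);
    excess or deficit relative to positional independence is encoded by
    class (colour/dash), not by width.  Outgoing edge widths of a circle
    therefore sum exactly to (width_scale / radius_scale) x its radius.
    """
    style = style or RiverlakeStyle()
    L = len(model)
    mono = mono_from_dinuc(model)
    excess = excess_matrix(model, mono)

    circles: List[Circle] = []
    for i in range(L):
        for bi, b in enumerate(BASES):
            circles.append(Circle(
                position=i, base=b,
                x=style.margin + i * style.column_spacing,
                y=style.margin + bi * style.row_spacing,
                radius=max(style.radius_scale * mono[i, bi],
                           style.min_radius if mono[i, bi] < 0.005 else 0.0),
                frequency=float(mono[i, bi]),
            ))

    edges: List[Edge] = []
    for i in range(L - 1):
        for b1i, b1 in enumerate(BASES):
            for b2i, b2 in enumerate(BASES):
                p = float(model.pair_probs[i, b1i * 4 + b2i])
                e = float(excess[i, b1i * 4 + b2i])
                if e > style.excess_threshold:
                    klass = "excess"
                elif e < -style.excess_threshold:
                    klass = "deficit"
                else:
                    klass = "neutral"
                c1 = circles[i * 4 + b1i]
                c2 = circles[(i + 1) * 4 + b2i]
                edges.append(Edge(i, b1, b2, c1.x, c1.y, c2.x, c2.y,
                                  width=style.width_scale * p,
                                  frequency=p, excess=e, klass=klass))

    return RiverlakeLayout(
        circles=circles, edges=edges, style=style, mono=mono, excess=excess,
        width=2 * style.margin + (L - 1) * style.column_spacing,
        height=2 * style.margin + 3 * style.row_spacing,
    )


# ----------------------------------------------------------------- rendering

def _fmt(x: float) -> str:
    return f"{x:.3f}".rstrip("0").rstrip(".")


def render_riverlake(model: DinucModel, style: Optional[RiverlakeStyle] = None) -> str:
    """Render a dinucleotide model as a standalone SVG 1.1 document.

    Output bytes are a pure function of (model, style): element order,
    float formatting and attribute order are all fixed.
    """
    if len(model) < 2:
        raise ValueError("model must cover at least two positions")
    style = style or RiverlakeStyle()
    layout = build_layout(model, style)

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(layout.width)}" height="{_fmt(layout.height)}" '
        f'viewBox="0 0 {_fmt(layout.width)} {_fmt(layout.height)}">\n',
    ]

    # Edges beneath circles. Observed-frequency lines carry width
    # width_scale*p (neutral grey, or dark blue when in excess of the
    # independence prediction). A deficit -- predicted frequency exceeding
    # the observed one -- is indicated by a yellow dotted overlay whose
    # width encodes the missing amount width_scale*|e|, since the observed
    # line itself can have zero width.
    def line(e: Edge, klass: str, width: float, stroke: str, extra: str = ""):
        parts.append(
            f'<line class="edge {klass}" x1="{_fmt(e.x1)}" y1="{_fmt(e.y1)}" '
            f'x2="{_fmt(e.x2)}" y2="{_fmt(e.y2)}" stroke="{stroke}" '
            f'stroke-width="{_fmt(width)}"{extra}/>\n')

    for e in layout.edges:
        if e.klass != "neutral" or e.width <= 0:
            continue
        line(e, "neutral", e.width, style.neutral_color)
    for e in layout.edges:
        if e.klass == "deficit" and e.width > 0:
            line(e, "neutral", e.width, style.neutral_color)
    for e in layout.edges:
        if e.klass != "excess" or e.width <= 0:
            continue
        line(e, "excess", e.width, style.excess_color)
    for e in layout.edges:
        if e.klass != "deficit":
            continue
        line(e, "deficit", style.width_scale * abs(e.excess),
             style.deficit_color,
             f' stroke-dasharray="{style.deficit_dash}"')

    for c in layout.circles:
        if c.radius <= 0:
            continue
        fill = style.base_colors[BASES.index(c.base)]
        parts.append(
            f'<circle class="base base-{c.base}" cx="{_fmt(c.x)}" cy="{_fmt(c.y)}" '
            f'r="{_fmt(c.radius)}" fill="{fill}"/>\n')

    # row labels
    for bi, b in enumerate(BASES):
        parts.append(
            f'<text x="{_fmt(style.margin / 3)}" '
            f'y="{_fmt(style.margin + bi * style.row_spacing + style.font_size / 3)}" '
            f'font-family="{style.font_family}" font-size="{_fmt(style.font_size)}" '
            f'fill="#333333">{b}</text>\n')

    parts.append("</svg>\n")
    return "".join(parts)


def svg_sha256(svg: str) -> str:
    return hashlib.sha256(svg.encode("utf-8")).hexdigest()
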