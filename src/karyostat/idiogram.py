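"""Idiogram construction and SVG rendering.

An idiogram shows one glyph per chromosome pair, ordered 1..n left to
right, glyph height proportional to the pair's relative length (RL, % of
the haploid complement), short arm drawn above the centromeric
constriction, satellites as a distal block separated by a gap (the
secondary constriction), and marker tracks (fluorochrome bands, rDNA
sites) as rectangles at their fractional extents.  The ordinate axis is
in RL percent.

Geometry and styling are separated: :func:`build_idiogram` produces an
abstract, unit-true specification (RL-percent coordinates) that is easy
to test; :func:`render_svg` maps it to a deterministic SVG byte stream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .config import DEFAULT_CONFIG, AnalysisConfig
from .io import LinkageError, MarkerSite, PairSummary


@dataclass(frozen=True)
class MarkerBox:
    arm: str                      # short | long | centromere-spanning
    start_frac: float
    end_frac: float
    marker_type: str


@dataclass(frozen=True)
class ChromosomeGlyph:
    """One pair's glyph in RL-percent units (height == RL)."""

    pair_id: int
    height: float                 # == RL (percent of haploid complement)
    short_height: float           # b/(b+B) · height (satellite included)
    long_height: float
    sat_height: float = 0.0       # satellite block, distal part of its arm
    sat_arm: str = "none"
    markers: tuple[MarkerBox, ...] = ()


@dataclass(frozen=True)
class IdiogramSpec:
    species: str
    glyphs: tuple[ChromosomeGlyph, ...]
    axis_max: float               # ordinate range top (RL percent)


def build_idiogram(pairs: Sequence[PairSummary],
                   sites: Sequence[MarkerSite] = (),
                   species: str = "",
                   satellite_frac: float = 0.15,
                   config: AnalysisConfig = DEFAULT_CONFIG) -> IdiogramSpec:
    """Abstract idiogram geometry from pair summaries and marker sites.

    Glyphs are emitted in pair order (decreasing RL by construction of the
    summaries).  ``satellite_frac`` is the drawn fraction of the satellited
    arm occupied by the satellite block when the measurement tables do not
    resolve it further.  Markers referencing an unknown pair raise
    :class:`LinkageError`.
    """
    known = {p.orig_pair_id for p in pairs}
    for s in sites:
        if s.pair_id not in known:
            raise LinkageError(f"marker references unknown pair {s.pair_id}")
    by_pair: dict[int, list[MarkerBox]] = {p.orig_pair_id: [] for p in pairs}
    for s in sites:
        by_pair[s.pair_id].append(
            MarkerBox(arm=s.arm, start_frac=s.start_frac, end_frac=s.end_frac,
                      marker_type=s.marker_type))

    glyphs = []
    for p in sorted(pairs, key=lambda q: q.pair_id):
        h = p.RL
        short_h = h * p.b / (p.b + p.B)
        long_h = h - short_h
        sat_h, sat_arm = 0.0, "none"
        if p.has_satellite:
            sat_arm = "short"   # drawn on the short arm (distal) by convention
            sat_h = satellite_frac * short_h
        glyphs.append(ChromosomeGlyph(
            pair_id=p.pair_id, height=h, short_height=short_h,
            long_height=long_h, sat_height=sat_h, sat_arm=sat_arm,
            markers=tuple(by_pair[p.orig_pair_id])))
    axis_max = max((g.height for g in glyphs), default=10.0)
    return IdiogramSpec(species=species, glyphs=tuple(glyphs), axis_max=axis_max)


# ---------------------------------------------------------------------------
# SVG rendering


@dataclass(frozen=True)
class IdiogramStyle:
    """Rendering style; colors follow the CPD/DAPI/FISH palette convention
    (CPD red, DAPI blue, 5S magenta, 45S green)."""

    px_per_rl: float = 28.0       # vertical scale: pixels per RL percent
    glyph_width: float = 26.0
    glyph_gap: float = 18.0
    margin: float = 46.0
    constriction_gap: float = 3.0  # visual gap at centromere / satellite neck
    chromosome_fill: str = "#e8e8e8"
    chromosome_stroke: str = "#444444"
    axis_tick_step: float = 2.0   # RL percent between axis ticks
    colors: tuple[tuple[str, str], ...] = (
        ("CPD", "#d62728"), ("DAPI", "#1f77b4"),
        ("5S", "#c843c8"), ("45S", "#2ca02c"))

    def color(self, marker_type: str) -> str:
        return dict(self.colors).get(marker_type, "#888888")


def _f(x: float) -> str:
    """Stable coordinate formatting for byte-deterministic output."""
    return f"{x:.3f}"


def _rect(x: float, y: float, w: float, h: float, fill: str,
          stroke: str | None = None, rx: float = 0.0) -> str:
    s = (f'<rect x="{_f(x)}" y="{_f(y)}" width="{_f(w)}" height="{_f(h)}" '
         f'fill="{fill}"')
    if rx:
        s += f' rx="{_f(rx)}"'
    if stroke:
        s += f' stroke="{stroke}" stroke-width="1"'
    return s + "/>"


def render_svg(spec: IdiogramSpec, path: str | Path | None = None,
               style: IdiogramStyle = IdiogramStyle()) -> str:
    """Render an idiogram specification to SVG 1.1 markup.

    Output is byte-deterministic for a fixed (spec, style); if *path* is
    given the markup is also written there.
    """
    st = style
    n = len(spec.glyphs)
    height = st.margin * 2 + spec.axis_max * st.px_per_rl
    width = st.margin * 1.5 + n * (st.glyph_width + st.glyph_gap) + st.margin
    top = st.margin
    baseline = top + spec.axis_max * st.px_per_rl   # y of RL 0

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(width)}" height="{_f(height)}" '
        f'viewBox="0 0 {_f(width)} {_f(height)}">',
        f'<title>Idiogram {spec.species}</title>' if spec.species
        else "<title>Idiogram</title>",
    ]

    # ordinate axis (RL percent), ticks from 0 upward
    ax = st.margin * 0.9
    parts.append(f'<g id="axis" stroke="#000000" stroke-width="1">')
    parts.append(f'<line x1="{_f(ax)}" y1="{_f(top)}" x2="{_f(ax)}" '
                 f'y2="{_f(baseline)}"/>')
    tick = 0.0
    while tick <= spec.axis_max + 1e-9:
        y = baseline - tick * st.px_per_rl
        parts.append(f'<line x1="{_f(ax - 4)}" y1="{_f(y)}" x2="{_f(ax)}" '
                     f'y2="{_f(y)}"/>')
        parts.append(f'<text x="{_f(ax - 7)}" y="{_f(y + 3)}" font-size="9" '
                     f'text-anchor="end" stroke="none" '
                     f'fill="#000000">{tick:g}</text>')
        tick += st.axis_tick_step
    parts.append("</g>")

    for i, g in enumerate(spec.glyphs):
        x = st.margin * 1.5 + i * (st.glyph_width + st.glyph_gap)
        w = st.glyph_width
        glyph_top = baseline - g.height * st.px_per_rl
        short_px = g.short_height * st.px_per_rl
        long_px = g.long_height * st.px_per_rl
        sat_px = g.sat_height * st.px_per_rl
        cen_y = glyph_top + short_px          # centromere line
        gap = st.constriction_gap

        parts.append(f'<g id="pair-{g.pair_id}">')
        parts.append(f'<text x="{_f(x + w / 2)}" y="{_f(top - 8)}" '
                     f'font-size="11" text-anchor="middle" '
                     f'fill="#000000">{g.pair_id}</text>')

        # chromosome body: satellite block / short arm / long arm,
        # separated by constriction gaps (drawn inside the arm extents).
        if sat_px > 0 and g.sat_arm == "short":
            parts.append(_rect(x, glyph_top, w, max(sat_px - gap / 2, 0.5),
                               st.chromosome_fill, st.chromosome_stroke, rx=3))
            arm_y = glyph_top + sat_px + gap / 2
            arm_h = max(short_px - sat_px - gap, 0.5)
        else:
            arm_y = glyph_top
            arm_h = max(short_px - gap / 2, 0.5)
        parts.append(_rect(x, arm_y, w, arm_h,
                           st.chromosome_fill, st.chromosome_stroke, rx=3))
        parts.append(_rect(x, cen_y + gap / 2, w, max(long_px - gap / 2, 0.5),
                           st.chromosome_fill, st.chromosome_stroke, rx=3))

        # marker tracks at exact fractional extents
        for m in sorted(g.markers, key=lambda m: (m.arm, m.start_frac,
                                                  m.end_frac, m.marker_type)):
            color = st.color(m.marker_type)
            if m.arm == "short":
                y1 = cen_y - m.end_frac * short_px
                h = (m.end_frac - m.start_frac) * short_px
            elif m.arm == "long":
                y1 = cen_y + m.start_frac * long_px
                h = (m.end_frac - m.start_frac) * long_px
            else:  # centromere-spanning: symmetric about the centromere
                y1 = cen_y - m.end_frac * short_px
                h = m.end_frac * (short_px + long_px)
            parts.append(_rect(x + 1, y1, w - 2, h, color) +
                         f'<!--{m.marker_type}-->')
        parts.append("</g>")

    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    if path is not None:
        Path(path).write_text(svg, encoding="utf-8")
    return svg
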