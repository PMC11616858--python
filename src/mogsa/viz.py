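"""Deterministic SVG rendering of the MoGSA star and comparison bars.

The star is a fixed circle of twelve 30-degree sectors, P1 at the top
and subsequent principles clockwise.  Sector color encodes the points:

    3 points  -> green sector
    2 points  -> half sector (inner green, outer red, split at 50% radius)
    1 point   -> red sector
    N/A       -> yellow sector

The overall score sits in the centre above a band-colored bar.  Output
is plain SVG built from fixed-precision strings: rendering the same
result twice yields byte-identical files (no timestamps, stable element
order), so images can be snapshot-tested and diffed.
"""

from __future__ import annotations

import math
from pathlib import Path
from xml.sax.saxutils import escape
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, field_validator

from .scoring import BAND_COLORS, FILL_BY_POINTS, MoGSAResult

__all__ = ["StarSpec", "build_star_spec", "render_svg", "render_comparison_svg", "star_svg"]

FillName = Literal["green", "half-green-half-red", "red", "yellow"]

#: Pinned palette so snapshots are reproducible; override via StarSpec.palette.
DEFAULT_PALETTE: dict[str, str] = {
    "green": "#1a9850",
    "red": "#d73027",
    "yellow": "#fee08b",
}


class StarSpec(BaseModel):
    """Render-ready description of one MoGSA star."""

    model_config = {"frozen": True}

    sectors: tuple[tuple[str, FillName], ...]
    center_label: str
    bar_color: Literal["red", "yellow", "green"]
    title: str = ""
    palette: dict[str, str] = DEFAULT_PALETTE

    @field_validator("sectors")
    @classmethod
    def _twelve(cls, v):
        if len(v) != 12:
            raise ValueError(f"a star has exactly 12 sectors, got {len(v)}")
        return v


def build_star_spec(r: MoGSAResult) -> StarSpec:
    """Derive the star's colors purely from a scored result."""
    fills = r.sector_fills
    return StarSpec(
        sectors=tuple((res.principle, fills[res.principle]) for res in r.results),
        center_label=f"{r.score:.2f}",
        bar_color=BAND_COLORS[r.band],
        title=r.title,
    )


def _pt(cx: float, cy: float, radius: float, theta_deg: float) -> tuple[float, float]:
    # theta measured clockwise from 12 o'clock, SVG y grows downward
    t = math.radians(theta_deg)
    return cx + radius * math.sin(t), cy - radius * math.cos(t)


def _wedge(cx: float, cy: float, r0: float, r1: float, a0: float, a1: float) -> str:
    """SVG path for an annular wedge between radii r0<r1 and clock angles a0<a1."""
    x0o, y0o = _pt(cx, cy, r1, a0)
    x1o, y1o = _pt(cx, cy, r1, a1)
    f = "{:.3f}".format
    if r0 <= 0:
        return (
            f"M {f(cx)} {f(cy)} L {f(x0o)} {f(y0o)} "
            f"A {f(r1)} {f(r1)} 0 0 1 {f(x1o)} {f(y1o)} Z"
        )
    x0i, y0i = _pt(cx, cy, r0, a0)
    x1i, y1i = _pt(cx, cy, r0, a1)
    return (
        f"M {f(x0i)} {f(y0i)} L {f(x0o)} {f(y0o)} "
        f"A {f(r1)} {f(r1)} 0 0 1 {f(x1o)} {f(y1o)} "
        f"L {f(x1i)} {f(y1i)} A {f(r0)} {f(r0)} 0 0 0 {f(x0i)} {f(y0i)} Z"
    )


def star_svg(spec: StarSpec, *, size: int = 360) -> str:
    """Render a StarSpec to an SVG document string (pure function)."""
    cx = cy = size / 2.0
    radius = size * 0.36
    pal = spec.palette
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size + 40}" '
        f'viewBox="0 0 {size} {size + 40}">',
        f'<title>{escape(spec.title or "MoGSA star")}</title>',
        f'<rect width="{size}" height="{size + 40}" fill="#ffffff"/>',
    ]
    for i, (pid, fill) in enumerate(spec.sectors):
        a0, a1 = 30.0 * i - 15.0, 30.0 * i + 15.0
        if fill == "half-green-half-red":
            parts.append(
                f'<path class="sector" data-principle="{pid}" data-fill="{fill}" '
                f'd="{_wedge(cx, cy, 0, radius, a0, a1)}" fill="{pal["red"]}" '
                'stroke="#ffffff" stroke-width="1.5"/>'
            )
            parts.append(
                f'<path class="sector-inner" data-principle="{pid}" '
                f'd="{_wedge(cx, cy, 0, radius / 2.0, a0, a1)}" fill="{pal["green"]}" '
                'stroke="#ffffff" stroke-width="1.5"/>'
            )
        else:
            parts.append(
                f'<path class="sector" data-principle="{pid}" data-fill="{fill}" '
                f'd="{_wedge(cx, cy, 0, radius, a0, a1)}" fill="{pal[fill]}" '
                'stroke="#ffffff" stroke-width="1.5"/>'
            )
        lx, ly = _pt(cx, cy, radius + 16.0, 30.0 * i)
        parts.append(
            f'<text class="sector-label" x="{lx:.3f}" y="{ly + 4.0:.3f}" '
            'text-anchor="middle" font-family="sans-serif" font-size="13">'
            f"{pid}</text>"
        )
    inner = radius * 0.34
    parts.append(
        f'<circle cx="{cx:.3f}" cy="{cy:.3f}" r="{inner:.3f}" fill="#ffffff" '
        'stroke="#555555" stroke-width="1"/>'
    )
    parts.append(
        f'<text class="score" x="{cx:.3f}" y="{cy + 5.0:.3f}" text-anchor="middle" '
        f'font-family="sans-serif" font-size="20" font-weight="bold">{spec.center_label}</text>'
    )
    bar_w, bar_h = size * 0.6, 14.0
    parts.append(
        f'<rect class="band-bar" x="{(size - bar_w) / 2.0:.3f}" y="{size + 12.0:.3f}" '
        f'width="{bar_w:.3f}" height="{bar_h:.3f}" fill="{pal[spec.bar_color]}" '
        'stroke="#555555" stroke-width="1"/>'
    )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_svg(spec: StarSpec, path: str | Path, *, size: int = 360) -> None:
    """Write the star SVG; byte-identical across runs for identical input."""
    Path(path).write_text(star_svg(spec, size=size), encoding="utf-8")


def comparison_svg(results: Sequence[MoGSAResult], *, width_per_bar: int = 110) -> str:
    """Score bar chart across assessments, bars colored by band."""
    pal = DEFAULT_PALETTE
    n = len(results)
    w, h = width_per_bar * n + 40, 300
    base, top = h - 60.0, 30.0
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
        "<title>MoGSA comparison</title>",
        f'<rect width="{w}" height="{h}" fill="#ffffff"/>',
        f'<line x1="20" y1="{base:.3f}" x2="{w - 20}" y2="{base:.3f}" '
        'stroke="#555555" stroke-width="1"/>',
    ]
    for i, r in enumerate(results):
        x = 40.0 + width_per_bar * i
        bh = (base - top) * r.score / 100.0
        parts.append(
            f'<rect class="score-bar" data-band="{r.band}" x="{x:.3f}" '
            f'y="{base - bh:.3f}" width="{width_per_bar - 50:.3f}" height="{bh:.3f}" '
            f'fill="{pal[BAND_COLORS[r.band]]}" stroke="#555555" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{x + (width_per_bar - 50) / 2.0:.3f}" y="{base - bh - 6.0:.3f}" '
            'text-anchor="middle" font-family="sans-serif" font-size="13">'
            f"{r.score:.2f}</text>"
        )
        label = escape((r.title or f"method {i + 1}")[:14])
        parts.append(
            f'<text x="{x + (width_per_bar - 50) / 2.0:.3f}" y="{base + 18.0:.3f}" '
            'text-anchor="middle" font-family="sans-serif" font-size="11">'
            f"{label}</text>"
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_comparison_svg(results: Sequence[MoGSAResult], path: str | Path) -> None:
    Path(path).write_text(comparison_svg(results), encoding="utf-8")
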