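"""SVG track rendering of promoter annotations and consensus rows.

Mirrors the classic promoter-annotation figure style: one horizontal
track per member with a glyph at the start position of each motif,
plus a consensus track with the conserved (and optionally majority)
motifs and shaded module spans.  Pure-text SVG output, no plotting
dependency, deterministic for identical inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .consensus import CCRM, ConsensusAnnotation
from .scan import AnnotatedPromoter

__all__ = ["render_tracks"]

_FAMILY_COLORS = {
    "DOF": "#1f77b4",
    "bZIP": "#d62728",
    "RY": "#9467bd",
    "AACA-MYB": "#2ca02c",
    "GATA-MYB": "#ff7f0e",
    "OTHER": "#7f7f7f",
}


def _color_for(motif_id: str, family_of: dict[str, str]) -> str:
    return _FAMILY_COLORS.get(family_of.get(motif_id, "OTHER"), "#7f7f7f")


def render_tracks(
    annotated_set: Sequence[AnnotatedPromoter],
    consensus: ConsensusAnnotation | None = None,
    ccrms: Sequence[CCRM] = (),
    family_of: dict[str, str] | None = None,
    path: str | Path | None = None,
    width: int = 900,
) -> str:
    """Render member tracks plus an optional consensus track to SVG."""
    family_of = family_of or {}
    extent = max(
        [len(a.promoter) for a in annotated_set]
        + [-m.ref_coordinate for c in ([consensus] if consensus else []) for m in c.conserved]
        + [1]
    )
    row_h = 28
    margin = 120
    n_rows = len(annotated_set) + (1 if consensus is not None else 0)
    height = 40 + n_rows * row_h

    def x_of(coord: int) -> float:
        # coord is negative ATG-relative; −extent maps to the left edge.
        return margin + (coord + extent) / extent * (width - margin - 20)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="monospace" font-size="10">'
    ]
    # Scale bar with ticks every 100 bp.
    y0 = 20
    parts.append(
        f'<line x1="{x_of(-extent):.1f}" y1="{y0}" x2="{x_of(-1):.1f}" '
        f'y2="{y0}" stroke="#000"/>'
    )
    tick = -((extent // 100) * 100)
    while tick <= -1:
        if tick >= -extent:
            parts.append(
                f'<line x1="{x_of(tick):.1f}" y1="{y0 - 3}" x2="{x_of(tick):.1f}" '
                f'y2="{y0 + 3}" stroke="#000"/>'
                f'<text x="{x_of(tick):.1f}" y="{y0 - 6}" text-anchor="middle">{tick}</text>'
            )
        tick += 100

    rows: list[tuple[str, list[tuple[int, str, str]]]] = []
    for ann in annotated_set:
        rows.append(
            (
                ann.promoter.seq_id,
                [(h.start, h.motif_id, h.strand) for h in ann.hits],
            )
        )
    if consensus is not None:
        rows.append(
            (
                f"consensus ({consensus.set_id})",
                [(m.ref_coordinate, m.motif_id, m.strand) for m in consensus.conserved],
            )
        )

    for r, (label, glyphs) in enumerate(rows):
        y = 40 + r * row_h + row_h // 2
        parts.append(f'<text x="4" y="{y + 3}">{label}</text>')
        parts.append(
            f'<line x1="{x_of(-extent):.1f}" y1="{y}" x2="{x_of(-1):.1f}" '
            f'y2="{y}" stroke="#999"/>'
        )
        is_consensus = consensus is not None and r == len(rows) - 1
        if is_consensus:
            for c in ccrms:
                x1, x2 = x_of(c.span[0]), x_of(c.span[1])
                parts.append(
                    f'<rect x="{x1:.1f}" y="{y - 10}" width="{max(x2 - x1, 2):.1f}" '
                    f'height="20" fill="#ffe28a" opacity="0.6"/>'
                    f'<text x="{x1:.1f}" y="{y - 12}">CCRM{c.index}</text>'
                )
        for start, motif_id, strand in sorted(glyphs):
            x = x_of(start)
            color = _color_for(motif_id, family_of)
            marker = "▲" if strand == "+" else "▼"
            parts.append(
                f'<text x="{x:.1f}" y="{y + 4}" text-anchor="middle" '
                f'fill="{color}">{marker}</text>'
            )
    parts.append("</svg>")
    svg = "\n".join(parts)
    if path is not None:
        Path(path).write_text(svg)
    return svg
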