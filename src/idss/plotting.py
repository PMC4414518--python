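"""Battleship (stacked centered-bar) rendering of seriation orders.

The traditional visual check for frequency seriation: one row per
assemblage in solution order, one horizontally centered bar per type whose
width is proportional to the type's share of the assemblage, with the
bootstrap confidence interval drawn as a whisker. A valid order shows each
type swelling to a single widest point and tapering away — the lens
("battleship") shape.

The writer emits plain SVG text directly: output is byte-identical for
identical input, which keeps rendered atlases diffable and reproducible.
"""

from __future__ import annotations

from pathlib import Path
from xml.sax.saxutils import escape

from .bootstrap import ConfidenceBands
from .types import FrequencyMatrix

# layout constants (user units = px)
ROW_H = 22
COL_W = 90
LABEL_W = 120
HEADER_H = 70
BAR_H = 12
PAD = 10


def render_battleship(
    order: tuple[str, ...],
    freqs: FrequencyMatrix,
    bands: ConfidenceBands | None = None,
    title: str | None = None,
) -> str:
    """Return an SVG document for one solution.

    Bars are centered within per-type columns and scaled so that a
    proportion of 1 fills the column. A zero proportion draws no bar; its
    whisker appears only if the band is nonzero (a [0, 0] band draws
    nothing). Layout is deterministic.
    """
    types = freqs.type_names
    width = LABEL_W + COL_W * len(types) + 2 * PAD
    height = HEADER_H + ROW_H * len(order) + 2 * PAD
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        '<style>text{font-family:sans-serif;font-size:10px;}'
        '.t{font-size:9px;}.title{font-size:12px;font-weight:bold;}</style>',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    if title:
        out.append(f'<text class="title" x="{PAD}" y="{PAD + 12}">'
                   f"{escape(title)}</text>")
    for j, t in enumerate(types):
        cx = LABEL_W + COL_W * j + COL_W / 2 + PAD
        out.append(
            f'<text class="t" x="{cx:.1f}" y="{HEADER_H - 8}" '
            f'text-anchor="middle" transform="rotate(-30 {cx:.1f} '
            f'{HEADER_H - 8})">{escape(t)}</text>'
        )
    for i, aid in enumerate(order):
        y = HEADER_H + ROW_H * i + PAD
        cy = y + ROW_H / 2
        out.append(
            f'<text x="{LABEL_W - 6 + PAD}" y="{cy + 3:.1f}" '
            f'text-anchor="end">{escape(aid)}</text>'
        )
        row = freqs.row(aid)
        bi = bands.index_of(aid) if bands is not None else None
        for j in range(len(types)):
            cx = LABEL_W + COL_W * j + COL_W / 2 + PAD
            w = row[j] * (COL_W - 8)
            if w > 0:
                out.append(
                    f'<rect x="{cx - w / 2:.2f}" y="{cy - BAR_H / 2:.1f}" '
                    f'width="{w:.2f}" height="{BAR_H}" fill="none" '
                    f'stroke="black" stroke-width="0.8"/>'
                )
            if bands is not None:
                lo = bands.lower[bi, j] * (COL_W - 8)
                hi = bands.upper[bi, j] * (COL_W - 8)
                if hi > 0:
                    # whisker: thin line spanning the upper CI width, thick
                    # line spanning the lower bound
                    out.append(
                        f'<line x1="{cx - hi / 2:.2f}" y1="{cy + BAR_H / 2 + 2:.1f}" '
                        f'x2="{cx + hi / 2:.2f}" y2="{cy + BAR_H / 2 + 2:.1f}" '
                        f'stroke="black" stroke-width="1"/>'
                    )
                    if lo > 0:
                        out.append(
                            f'<line x1="{cx - lo / 2:.2f}" '
                            f'y1="{cy + BAR_H / 2 + 2:.1f}" '
                            f'x2="{cx + lo / 2:.2f}" '
                            f'y2="{cy + BAR_H / 2 + 2:.1f}" '
                            f'stroke="black" stroke-width="3"/>'
                        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def write_battleship(
    order: tuple[str, ...],
    freqs: FrequencyMatrix,
    path: str | Path,
    bands: ConfidenceBands | None = None,
    title: str | None = None,
) -> None:
    Path(path).write_text(render_battleship(order, freqs, bands, title))
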