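"""Optional vector rendering of sequence logos.

The normative logo artifacts are the numeric height tables
(:func:`qpisa.rearrange.linear_logo`, :func:`qpisa.rearrange.triplet_logo_frame`);
this module draws them with matplotlib. Letters are scaled glyph outlines
stacked by height: cleavage-promoting residues above the axis, impairing
ones below, largest magnitudes closest to the axis. Entries without
training support are greyed out rather than omitted.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .rearrange import RearrangedParams, triplet_logo_frame

_FONT = FontProperties(family="DejaVu Sans", weight="bold")

_COLORS = {
    **{aa: "#2ca02c" for aa in "STNQ"},     # polar
    **{aa: "#1f77b4" for aa in "AVLIMFWY"}, # hydrophobic/aromatic
    **{aa: "#d62728" for aa in "DE"},       # acidic
    **{aa: "#9467bd" for aa in "KRH"},      # basic
    "P": "#ff7f0e", "G": "#8c564b", "C": "#e377c2",
}
_GREY = "#bbbbbb"


def _draw_letter(ax, letter: str, x: float, y: float, height: float,
                 color: str, width: float = 0.9) -> None:
    if height == 0:
        return
    path = TextPath((0, 0), letter, size=1.0, prop=_FONT)
    bbox = path.get_extents()
    sx = width / bbox.width
    sy = abs(height) / bbox.height
    transform = (Affine2D()
                 .translate(-bbox.x0, -bbox.y0)
                 .scale(sx, sy)
                 .translate(x - width / 2, min(y, y + height)))
    ax.add_patch(PathPatch(transform.transform_path(path),
                           facecolor=color, edgecolor="none"))


def _stack(ax, x: float, heights: pd.Series, supported: pd.Series) -> None:
    """Stack letters at one x position: positives up, negatives down,
    large magnitudes nearest the axis."""
    pos = heights[heights > 0].sort_values(ascending=False)
    neg = heights[heights < 0].sort_values()
    y = 0.0
    for aa, h in pos.items():
        color = _COLORS.get(aa, "#333333") if supported.get(aa, True) else _GREY
        _draw_letter(ax, aa, x, y, h, color)
        y += h
    y = 0.0
    for aa, h in neg.items():
        color = _COLORS.get(aa, "#333333") if supported.get(aa, True) else _GREY
        _draw_letter(ax, aa, x, y, h, color)
        y += h


def plot_linear_logo(heights: pd.DataFrame, path=None, ax=None):
    """Render a six-position logo from a positions x residues frame."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    full = pd.Series(True, index=heights.columns)
    for i, pos in enumerate(heights.index):
        _stack(ax, i, heights.loc[pos], full)
    ax.set_xticks(range(len(heights.index)), heights.index)
    ax.set_xlim(-0.6, len(heights.index) - 0.4)
    lim = float(heights.abs().to_numpy().sum(axis=1).max()) or 1.0
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("contribution to cleavage (log2)")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_triplet_logos(params: RearrangedParams, path=None,
                       panels: list[str] | None = None):
    """Render per-P1 triplet panels (P2 stack | P1 letter | P1' stack).

    ``panels`` restricts to chosen P1 residues; default is the four
    largest term1 values, the motif's most informative rows.
    """
    frame = triplet_logo_frame(params)
    if panels is None:
        panels = list(params.term1.sort_values(ascending=False).index[:4])
    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3),
                             squeeze=False)
    for ax, p1 in zip(axes[0], panels):
        sub = frame.loc[frame["panel_p1"] == p1]
        for x, position in ((0, "P2"), (2, "P1'")):
            block = sub.loc[sub["position"] == position]
            _stack(ax, x,
                   block.set_index("residue")["height"],
                   block.set_index("residue")["supported"])
        row = sub.loc[sub["position"] == "P1"].iloc[0]
        _draw_letter(ax, p1, 1, 0, float(row["height"]),
                     _COLORS.get(p1, "#333333") if row["supported"] else _GREY)
        ax.set_xticks([0, 1, 2], ["P2", "P1", "P1'"])
        ax.set_xlim(-0.6, 2.6)
        lim = max(float(sub.groupby("position")["height"]
                        .apply(lambda s: s.abs().sum()).max()), 0.1)
        ax.set_ylim(-lim, lim)
        ax.axhline(0, color="black", lw=0.8)
        ax.set_title(f"P1 = {p1}")
    axes[0][0].set_ylabel("contribution to cleavage (log2)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
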