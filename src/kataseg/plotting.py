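"""Rainfall plots: IMD against genomically ordered variant index.

Each variant is a point at its ordinal position (per-chromosome genomic
order), with the intermutation distance on a log10 y-axis and the color
giving the substitution class.  Called kataegis loci are shaded rectangles
with their member variants emphasized; the segmentation overlay adds
vertical changepoint lines and per-segment mean-IMD bars.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

import matplotlib

if not os.environ.get("DISPLAY"):  # headless by default
    matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .calling import DetectionResult
from .io import classify_substitution

__all__ = ["rainfall_plot"]

_CLASS_COLORS = {
    "C>A": "#2EBAED",
    "C>G": "#000000",
    "C>T": "#DE1C14",
    "T>A": "#ADCC54",
    "T>C": "#D4D2D2",
    "T>G": "#F0D0CE",
    "MNV": "#8c564b",
    "indel": "#9467bd",
    "other": "#7f7f7f",
}

LOCUS_GID = "kataegis-locus"
SEGMENT_MEAN_GID = "segment-mean"
CHANGEPOINT_GID = "changepoint"


def rainfall_plot(
    result: DetectionResult,
    show_sequence: str | Sequence[str] = "all",
    show_segmentation: bool = False,
    out: str | os.PathLike | None = None,
    ax: plt.Axes | None = None,
    figsize: tuple[float, float] = (12, 4),
    dpi: int = 150,
):
    """Render the rainfall plot of a detection result.

    Parameters
    ----------
    result
        A nonempty detection result.
    show_sequence
        "all" or a chromosome name / list of names to display.
    show_segmentation
        Overlay changepoint verticals and per-segment mean-IMD bars.
    out
        Optional image path (PNG/SVG/PDF by extension); the figure is
        returned either way.

    Returns
    -------
    matplotlib.figure.Figure
    """
    available = result.variants.chromosomes
    if not available:
        raise ValueError("empty detection result: nothing to plot")
    if show_sequence == "all":
        chroms = available
    else:
        wanted = [show_sequence] if isinstance(show_sequence, str) else list(show_sequence)
        missing = [c for c in wanted if c not in available]
        if missing:
            raise ValueError(
                f"chromosome(s) {missing} not in result; available: {available}"
            )
        chroms = wanted

    if ax is None:
        fig, ax = plt.subplots(figsize=figsize)
    else:
        fig = ax.figure

    df = result.variants.df
    offset = 0
    boundaries = []
    offsets: dict[str, int] = {}
    xs_all, ys_all, colors_all = [], [], []
    for chrom in chroms:
        sub = df[df["chromosome"] == chrom].sort_values("start")
        imdseq = result.imd_by_chromosome.get(chrom)
        if imdseq is None:
            continue
        offsets[chrom] = offset
        xs = offset + np.arange(1, imdseq.n_variants + 1)
        ys = np.maximum(imdseq.imds, 1)  # IMD floor of 1 keeps the log axis finite
        classes = [
            classify_substitution(r, a) if r and a else "other"
            for r, a in zip(sub["ref"], sub["alt"])
        ]
        xs_all.append(xs)
        ys_all.append(ys)
        colors_all.extend(_CLASS_COLORS.get(c, _CLASS_COLORS["other"]) for c in classes)
        offset += imdseq.n_variants
        boundaries.append(offset)

    xs_cat = np.concatenate(xs_all)
    ys_cat = np.concatenate(ys_all)
    in_locus = np.zeros(xs_cat.size, dtype=bool)

    # shaded rectangles for the called loci, spanning member ordinal ranges
    for locus in result.loci:
        if locus.chromosome not in offsets:
            continue
        imdseq = result.imd_by_chromosome[locus.chromosome]
        member = np.flatnonzero(
            (imdseq.positions >= locus.genomic_start)
            & (imdseq.positions <= locus.genomic_end)
        )
        if member.size == 0:
            continue
        x0 = offsets[locus.chromosome] + member[0] + 1
        x1 = offsets[locus.chromosome] + member[-1] + 1
        span = ax.axvspan(x0 - 0.5, x1 + 0.5, color="#ADD8E6", alpha=0.5, zorder=0)
        span.set_gid(LOCUS_GID)
        lo = np.searchsorted(xs_cat, x0)
        hi = np.searchsorted(xs_cat, x1, side="right")
        in_locus[lo:hi] = True

    sizes = np.where(in_locus, 22.0, 6.0)
    ax.scatter(xs_cat, ys_cat, c=colors_all, s=sizes, linewidths=0, zorder=2)

    if show_segmentation:
        for chrom in chroms:
            base = offsets.get(chrom)
            if base is None:
                continue
            imdseq = result.imd_by_chromosome[chrom]
            n_var = imdseq.n_variants
            for seg in (s for s in result.segments if s.chromosome == chrom):
                if not seg.has_variants:
                    continue
                (line,) = ax.plot(
                    [base + seg.first_variant_index, base + seg.last_variant_index],
                    [max(seg.mean_imd, 1)] * 2,
                    color="black",
                    lw=1.5,
                    zorder=3,
                )
                line.set_gid(SEGMENT_MEAN_GID)
                if seg.last_variant_index < n_var:
                    vline = ax.axvline(
                        base + seg.last_variant_index + 0.5,
                        color="0.4",
                        lw=0.8,
                        ls="--",
                        zorder=1,
                    )
                    vline.set_gid(CHANGEPOINT_GID)

    for b in boundaries[:-1]:
        ax.axvline(b + 0.5, color="0.8", lw=0.6, zorder=0)

    ax.set_yscale("log")
    ax.set_xlabel("variant ID (ordered by genomic location)")
    ax.set_ylabel("intermutation distance (bp)")
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=c, label=name)
        for name, c in _CLASS_COLORS.items()
        if name != "other"
    ]
    ax.legend(handles=handles, loc="upper right", ncol=4, fontsize=7, frameon=False)

    if out is not None:
        fig.savefig(out, dpi=dpi, bbox_inches="tight")
    return fig
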