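"""Per-variant classification metrics and locus-level concordance.

Kataegis detection is scored as a binary classification of variants
(inside/outside a kataegis locus).  Because in-locus variants are a tiny
minority, the normalized Matthews correlation coefficient
``nMCC = (MCC + 1) / 2`` is the headline metric; accuracy, F1, TPR and TNR
are reported alongside.  Locus-level agreement between two call sets uses
the 1-bp-overlap rule: two loci are concordant iff their genomic intervals
share at least one base on the same chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .calling import DetectionResult, KataegisLocus
from .simulate import LabeledSample

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "confusion",
    "metrics",
    "evaluate_sample",
    "evaluate_by_tmb",
    "locus_concordance",
    "ConcordanceResult",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Variant-level confusion counts (positive = in a kataegis locus)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    mcc: float
    nmcc: float
    f1: float
    tpr: float
    tnr: float


def confusion(
    truth: Sequence[bool] | np.ndarray, predicted: Sequence[bool] | np.ndarray
) -> ConfusionMatrix:
    """Tally the confusion matrix of aligned truth/prediction vectors."""
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("truth and prediction must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, MCC, nMCC, F1, TPR and TNR from a confusion matrix.

    When any factor of the MCC denominator is zero (e.g. a sample with no
    positive truth and no positive calls) the MCC is defined as 0, hence
    nMCC 0.5.  Rates with empty denominators are reported as NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = (float(x) for x in (cm.tp, cm.fp, cm.tn, cm.fn))
    accuracy = (tp + tn) / cm.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    f1 = tp / (tp + 0.5 * (fp + fn)) if (tp + fp + fn) > 0 else math.nan
    tpr = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    tnr = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    return MetricSet(
        accuracy=accuracy, mcc=mcc, nmcc=(mcc + 1.0) / 2.0, f1=f1, tpr=tpr, tnr=tnr
    )


def evaluate_sample(
    truth_sample: LabeledSample, result: DetectionResult
) -> ConfusionMatrix:
    """Confusion matrix of a detection run against a labeled sample.

    Variants are matched positionally by (chromosome, position); a variant
    is predicted positive iff the detector flagged it as in-kataegis.
    Order-insensitive on both sides.
    """
    truth_df = truth_sample.variants.df[["chromosome", "start", "truth_label"]]
    pred_df = result.variants.df[["chromosome", "start", "in_kataegis"]]
    merged = truth_df.merge(pred_df, on=["chromosome", "start"], how="left")
    predicted = merged["in_kataegis"].fillna(False).to_numpy(dtype=bool)
    return confusion(merged["truth_label"].to_numpy(dtype=bool), predicted)


def evaluate_by_tmb(
    per_sample: Iterable[tuple[float, ConfusionMatrix]],
) -> pd.DataFrame:
    """Pool per-sample confusion matrices within TMB class.

    Returns one row per TMB class plus an ``overall`` row, each carrying the
    pooled counts and the metric set computed from them.
    """
    pools: dict[object, ConfusionMatrix] = {}
    for tmb, cm in per_sample:
        pools[tmb] = pools.get(tmb, ConfusionMatrix()) + cm
    if not pools:
        raise ValueError("no samples to evaluate")
    pools["overall"] = sum(
        (cm for k, cm in pools.items() if k != "overall"), ConfusionMatrix()
    )
    rows = []
    for key in sorted((k for k in pools if k != "overall")) + ["overall"]:
        cm = pools[key]
        m = metrics(cm)
        rows.append(
            {
                "tmb_class": key,
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "accuracy": m.accuracy,
                "mcc": m.mcc,
                "nmcc": m.nmcc,
                "f1": m.f1,
                "tpr": m.tpr,
                "tnr": m.tnr,
            }
        )
    return pd.DataFrame(rows).set_index("tmb_class")


@dataclass(frozen=True)
class ConcordanceResult:
    """Partition of one locus list by >=1 bp overlap with another."""

    matched: tuple[KataegisLocus, ...]
    unmatched: tuple[KataegisLocus, ...]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def locus_concordance(
    loci_a: Sequence[KataegisLocus], loci_b: Sequence[KataegisLocus]
) -> ConcordanceResult:
    """Partition ``loci_a`` into loci overlapping some locus of ``loci_b``.

    Two loci agree iff they share at least 1 bp on the same chromosome;
    intervals that merely abut (end of one = start of the other - 1) do not
    overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for locus in loci_b:
        # IntervalTree is half-open; +1 makes the inclusive end queryable
        trees.setdefault(locus.chromosome, IntervalTree()).addi(
            locus.genomic_start, locus.genomic_end + 1
        )
    matched, unmatched = [], []
    for locus in loci_a:
        tree = trees.get(locus.chromosome)
        if tree is not None and tree.overlap(locus.genomic_start, locus.genomic_end + 1):
            matched.append(locus)
        else:
            unmatched.append(locus)
    return ConcordanceResult(matched=tuple(matched), unmatched=tuple(unmatched))
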