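"""Scikit-learn style estimator wrapping the kataegis detection workflow."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .calling import DetectionParams, detect
from .changepoint import ChangepointParams
from .io import VariantCollection, read_chromosome_lengths

__all__ = ["KataegisDetector"]


class KataegisDetector(BaseEstimator):
    """Detect kataegis loci in a sample's somatic variant calls.

    Transductive estimator in the scikit-learn idiom (compare
    ``sklearn.cluster``): :meth:`fit` runs intermutation-distance
    segmentation and locus calling on the given sample and exposes the
    outcome through fitted attributes; :meth:`fit_predict` returns the
    per-variant in-kataegis labels.

    Parameters
    ----------
    imd_cutoff : float, "pcawg", or callable, default 1000
        Maximum mean IMD (bp) of a kataegis segment.  ``"pcawg"`` selects
        the sample-adaptive PCAWG cutoff; a callable receives
        ``(segment, summary)`` and returns the cutoff per segment.
    min_size_kataegis : int, default 6
        Minimum number of variants in a kataegis locus.
    search : {"pelt", "binseg", "segneigh", "amoc"}, default "pelt"
        Changepoint search algorithm.
    min_seg_len : int, default 2
        Minimum observations per segment.
    penalty : "bic" or float, default "bic"
        Per-changepoint penalty; "bic" resolves to ``2 ln n``.
    max_segments : int, optional
        Segment budget for binseg/segneigh.
    genome : mapping, path, or None
        Chromosome-length table used when the input does not carry one.

    Attributes
    ----------
    result_ : DetectionResult
        Full detection output (loci, segments, flagged variants, summary).
    loci_ : list of KataegisLocus
    segments_ : list of Segment
    labels_ : ndarray of bool
        Per-variant in-kataegis flags, aligned with the preprocessed input.
    n_loci_ : int

    Examples
    --------
    >>> det = KataegisDetector()
    >>> labels = det.fit_predict(variant_collection)   # doctest: +SKIP
    >>> det.n_loci_                                    # doctest: +SKIP
    """

    def __init__(
        self,
        imd_cutoff=1000.0,
        min_size_kataegis: int = 6,
        search: str = "pelt",
        min_seg_len: int = 2,
        penalty="bic",
        max_segments: int | None = None,
        genome=None,
    ):
        self.imd_cutoff = imd_cutoff
        self.min_size_kataegis = min_size_kataegis
        self.search = search
        self.min_seg_len = min_seg_len
        self.penalty = penalty
        self.max_segments = max_segments
        self.genome = genome

    def _detection_params(self) -> DetectionParams:
        if self.penalty == "bic":
            penalty_value = None
        else:
            penalty_value = float(self.penalty)
        return DetectionParams(
            imd_cutoff=self.imd_cutoff,
            min_size_kataegis=self.min_size_kataegis,
            changepoint=ChangepointParams(
                search=self.search,
                penalty_value=penalty_value,
                min_seg_len=self.min_seg_len,
                max_segments=self.max_segments,
            ),
        )

    def _as_collection(self, X) -> VariantCollection:
        if isinstance(X, VariantCollection):
            if X.chromosome_lengths or self.genome is None:
                return X
            return VariantCollection(X.df, self._genome_lengths())
        if isinstance(X, pd.DataFrame):
            df = X.copy()
            if "end" not in df.columns:
                df["end"] = df["start"]
            return VariantCollection(df, self._genome_lengths())
        raise TypeError(
            "X must be a VariantCollection or a DataFrame with "
            "chromosome/start[/end/ref/alt] columns"
        )

    def _genome_lengths(self) -> Mapping[str, int]:
        if self.genome is None:
            raise ValueError(
                "a chromosome-length table is required: pass genome= or a "
                "VariantCollection that carries one"
            )
        if isinstance(self.genome, (str, bytes)):
            return read_chromosome_lengths(self.genome)
        return dict(self.genome)

    def fit(self, X, y=None) -> "KataegisDetector":
        """Run kataegis detection on sample ``X``.

        ``y`` is ignored (present for pipeline compatibility).
        """
        result = detect(self._as_collection(X), self._detection_params())
        self.result_ = result
        self.loci_ = result.loci
        self.segments_ = result.segments
        self.summary_ = result.summary
        self.labels_ = result.labels
        self.n_loci_ = result.n_loci
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Detect and return the per-variant boolean in-kataegis labels."""
        return self.fit(X, y).labels_

    def predict(self, X) -> np.ndarray:
        """Alias for :meth:`fit_predict`: detection is per-sample, so
        prediction always re-runs the workflow on the given sample."""
        return self.fit_predict(X)
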