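"""Segment annotation, mutation rates, and kataegis locus calling.

After changepoint segmentation of a chromosome's IMD sequence, each segment
is annotated with its genomic bounds, variant count, mean IMD and mutation
rate.  A segment is a putative kataegis locus when its mean IMD is at most
the IMD cutoff (static value, the PCAWG adaptive rule, or any user
function) and it holds at least ``min_size_kataegis`` variants; maximal
runs of adjacent qualifying segments are merged into single loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .changepoint import (
    ChangepointParams,
    ChangepointResult,
    ImdSequence,
    compute_imd,
    segment_observations,
)
from .io import VariantCollection, preprocess

__all__ = [
    "Segment",
    "SampleSummary",
    "DetectionParams",
    "KataegisLocus",
    "DetectionResult",
    "annotate_segments",
    "sample_rate",
    "pcawg_imd_cutoff",
    "call_kataegis",
    "detect",
]

logger = logging.getLogger(__name__)

#: default maximum mean IMD (bp) for a kataegis segment
DEFAULT_IMD_CUTOFF = 1000.0
#: default minimum number of variants in a kataegis locus
DEFAULT_MIN_SIZE = 6


@dataclass(frozen=True)
class Segment:
    """A changepoint-delimited run of variants on one chromosome.

    ``genomic_start``/``genomic_end`` tile the chromosome: a segment spans
    from just after the previous segment's last variant to its own last
    variant (the final segment ends at the chromosome end, absorbing the
    pseudo-IMD).  ``variant_count`` and ``mean_imd`` cover member variants
    only — the pseudo-IMD observation is never counted as a variant.

    ``anchor_pos`` is the position of the *anchor*: the previous segment's
    last variant, sitting 1 bp before this segment's start.  A run of m
    clustered IMDs involves m+1 variants, the anchor included — its gap to
    the segment's first member IS the segment's first IMD — so kataegis
    size counting and locus bounds use the anchor, while the partition
    fields keep exclusive semantics (segments tile, counts sum to the
    chromosome total).
    """

    chromosome: str
    first_variant_index: int  # 1-based index into the chromosome's variants
    last_variant_index: int
    genomic_start: int
    genomic_end: int
    variant_count: int
    length_bp: int
    mean_imd: float
    rate: float  # variants per bp
    first_variant_pos: int
    last_variant_pos: int
    anchor_pos: int | None = None

    @property
    def has_variants(self) -> bool:
        return self.variant_count > 0

    @property
    def kataegis_variant_count(self) -> int:
        """Variants witnessed by this segment's IMDs: members plus anchor."""
        return self.variant_count + (1 if self.anchor_pos is not None else 0)


@dataclass(frozen=True)
class SampleSummary:
    """Sample-level mutation rate summary.

    ``sample_rate`` is both the direct ratio (total variants over genome
    length) and the length-weighted mean of the segment rates; the two
    coincide by construction and are asserted equal at build time.
    ``lambda_med`` is the exponential rate implied by the median IMD
    (``ln 2 / median``), used by the PCAWG adaptive cutoff.
    """

    total_variants: int
    genome_length: int
    sample_rate: float
    segment_count: int
    median_imd: float
    lambda_med: float


@dataclass(frozen=True)
class DetectionParams:
    """User-facing kataegis detection parameters.

    ``imd_cutoff`` may be a static value in bp (default 1000), the string
    ``"pcawg"`` selecting :func:`pcawg_imd_cutoff`, or a callable
    ``f(segment, summary) -> float`` evaluated per segment before merging.
    """

    imd_cutoff: float | str | Callable[[Segment, SampleSummary], float] = (
        DEFAULT_IMD_CUTOFF
    )
    min_size_kataegis: int = DEFAULT_MIN_SIZE
    changepoint: ChangepointParams = field(default_factory=ChangepointParams)

    def __post_init__(self) -> None:
        if self.min_size_kataegis < 1:
            raise ValueError("min_size_kataegis must be >= 1")
        if isinstance(self.imd_cutoff, str) and self.imd_cutoff != "pcawg":
            raise ValueError(f"unknown imd_cutoff rule {self.imd_cutoff!r}")
        if isinstance(self.imd_cutoff, (int, float)) and self.imd_cutoff <= 0:
            raise ValueError("imd_cutoff must be positive")

    def cutoff_for(self, segment: Segment, summary: SampleSummary) -> float:
        if callable(self.imd_cutoff):
            return float(self.imd_cutoff(segment, summary))
        if self.imd_cutoff == "pcawg":
            return pcawg_imd_cutoff(segment, summary)
        return float(self.imd_cutoff)


@dataclass(frozen=True)
class KataegisLocus:
    """A merged run of qualifying segments, bounded by its member variants."""

    chromosome: str
    genomic_start: int
    genomic_end: int
    variant_count: int
    mean_imd: float


@dataclass
class DetectionResult:
    """Everything a detection run produced.

    ``variants`` carries a boolean ``in_kataegis`` column aligned with the
    (preprocessed) input records; ``segments`` tile every analysed
    chromosome; ``loci`` are the called kataegis loci.
    """

    loci: list[KataegisLocus]
    segments: list[Segment]
    variants: VariantCollection
    params: DetectionParams
    summary: SampleSummary | None
    imd_by_chromosome: dict[str, ImdSequence] = field(default_factory=dict)
    changepoints_by_chromosome: dict[str, ChangepointResult] = field(
        default_factory=dict
    )

    @property
    def labels(self) -> np.ndarray:
        return self.variants.df["in_kataegis"].to_numpy(dtype=bool)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chromosome": l.chromosome,
                    "start": l.genomic_start,
                    "end": l.genomic_end,
                    "variant_count": l.variant_count,
                    "mean_imd": l.mean_imd,
                }
                for l in self.loci
            ],
            columns=["chromosome", "start", "end", "variant_count", "mean_imd"],
        )

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chromosome": s.chromosome,
                    "start": s.genomic_start,
                    "end": s.genomic_end,
                    "variant_count": s.variant_count,
                    "length_bp": s.length_bp,
                    "mean_imd": s.mean_imd,
                    "rate": s.rate,
                }
                for s in self.segments
            ]
        )


def annotate_segments(cpts: ChangepointResult, imd: ImdSequence) -> list[Segment]:
    """Annotate changepoint-delimited segments of one chromosome.

    The observation sequence is the chromosome's IMDs plus the closing
    pseudo-IMD; segment bounds therefore tile the chromosome exactly
    (``sum(length_bp) == chromosome_length``).  Mean IMD and variant count
    include member variants only.
    """
    k = imd.n_variants
    n_obs = k + 1
    if cpts.changepoints and cpts.changepoints[-1] != n_obs:
        raise ValueError("changepoints do not cover the observation sequence")
    imds = imd.imds
    positions = imd.positions
    imd_cumsum = np.concatenate(([0], np.cumsum(imds)))
    segments: list[Segment] = []
    prev = 0
    for b in cpts.changepoints:
        a = prev + 1
        last_var = min(b, k)
        count = max(0, last_var - a + 1)
        genomic_start = 1 if a == 1 else int(positions[a - 2]) + 1
        genomic_end = int(positions[b - 1]) if b <= k else imd.chromosome_length
        if count > 0:
            imd_sum = int(imd_cumsum[last_var] - imd_cumsum[a - 1])
            mean_imd = imd_sum / count
            first_pos = int(positions[a - 1])
            last_pos = int(positions[last_var - 1])
        else:  # pseudo-IMD-only segment (possible only with min_seg_len=1)
            mean_imd = math.inf
            first_pos = genomic_start
            last_pos = genomic_end
        length_bp = genomic_end - genomic_start + 1
        segments.append(
            Segment(
                chromosome=imd.chromosome,
                first_variant_index=a if count else 0,
                last_variant_index=last_var if count else 0,
                genomic_start=genomic_start,
                genomic_end=genomic_end,
                variant_count=count,
                length_bp=length_bp,
                mean_imd=mean_imd,
                rate=count / length_bp,
                first_variant_pos=first_pos,
                last_variant_pos=last_pos,
                anchor_pos=int(positions[a - 2]) if a > 1 else None,
            )
        )
        prev = b
    return segments


def sample_rate(
    segments: Sequence[Segment],
    genome_length: int,
    all_imds: np.ndarray | None = None,
) -> SampleSummary:
    """Sample-level mutation rate as the length-weighted mean of segment rates.

    The direct form (total variants / genome length over the analysed
    chromosomes) and the weighted form must agree; a relative discrepancy
    beyond 1e-9 indicates segments that do not tile the genome.
    ``all_imds`` (the pooled member-variant IMDs) supplies the median IMD
    for the PCAWG adaptive cutoff.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    k_t = sum(s.variant_count for s in segments)
    analysed_length = sum(s.length_bp for s in segments)
    direct = k_t / analysed_length if analysed_length else 0.0
    weighted = (
        sum(s.rate * s.length_bp for s in segments) / analysed_length
        if analysed_length
        else 0.0
    )
    if k_t and not math.isclose(direct, weighted, rel_tol=1e-9):
        raise AssertionError(
            f"rate identity violated: direct {direct} vs weighted {weighted}"
        )
    if all_imds is not None and len(all_imds):
        median_imd = float(np.median(all_imds))
    else:
        median_imd = math.nan
    lambda_med = math.log(2) / median_imd if median_imd and median_imd > 0 else math.nan
    return SampleSummary(
        total_variants=k_t,
        genome_length=int(genome_length),
        sample_rate=k_t / genome_length,
        segment_count=len(segments),
        median_imd=median_imd,
        lambda_med=lambda_med,
    )


def pcawg_imd_cutoff(segment: Segment, summary: SampleSummary) -> float:
    """Sample-adaptive IMD cutoff used by the PCAWG consortium.

    The sample's IMDs are modelled as exponential with rate
    ``lambda_med = ln 2 / median(IMD)``; the cutoff for a segment with
    ``k`` mutations over ``L`` bp is
    ``-ln(1 - (0.01 / L)**(1 / (k - 1))) / lambda_med``, capped at 1000 bp.
    Segments with fewer than 2 mutations get cutoff 0 (cannot be kataegis).
    """
    k = segment.variant_count
    if k < 2:
        return 0.0
    if not (summary.median_imd > 0):
        raise ValueError("PCAWG cutoff requires a positive sample median IMD")
    raw = -math.log(1.0 - (0.01 / segment.length_bp) ** (1.0 / (k - 1)))
    return min(1000.0, raw / summary.lambda_med)


def call_kataegis(
    segments: Sequence[Segment],
    summary: SampleSummary,
    params: DetectionParams,
) -> list[KataegisLocus]:
    """Call kataegis loci from annotated segments.

    A segment qualifies iff ``mean_imd <= cutoff`` and its witnessed
    variant count (members plus the upstream anchor — v clustered variants
    have v-1 IMDs) is at least ``min_size_kataegis``; cutoffs are evaluated
    per segment *before* merging.  Maximal runs of adjacent qualifying
    segments on the same chromosome are merged into one locus spanning from
    the first segment's anchor (or first member, at a chromosome start) to
    the last member variant; the pooled mean IMD averages the member IMD
    sums.
    """
    loci: list[KataegisLocus] = []
    run: list[Segment] = []

    def flush() -> None:
        if not run:
            return
        head = run[0]
        count = sum(s.variant_count for s in run)
        imd_sum = sum(s.mean_imd * s.variant_count for s in run)
        mean_imd = imd_sum / count
        start = head.first_variant_pos
        if head.anchor_pos is not None:
            start = head.anchor_pos
            count += 1
        loci.append(
            KataegisLocus(
                chromosome=head.chromosome,
                genomic_start=start,
                genomic_end=run[-1].last_variant_pos,
                variant_count=count,
                mean_imd=mean_imd,
            )
        )
        run.clear()

    prev: Segment | None = None
    for seg in segments:
        adjacent = prev is not None and prev.chromosome == seg.chromosome
        if not adjacent:
            flush()
        qualifies = (
            seg.kataegis_variant_count >= params.min_size_kataegis
            and seg.has_variants
            and seg.mean_imd <= params.cutoff_for(seg, summary)
        )
        if qualifies:
            run.append(seg)
        else:
            flush()
        prev = seg
    flush()
    return loci


def detect(
    variants: VariantCollection,
    params: DetectionParams | None = None,
) -> DetectionResult:
    """Run the full kataegis detection workflow on one sample.

    Per chromosome: compute IMDs (with the closing pseudo-IMD), run the
    configured changepoint search, annotate segments; then call and merge
    kataegis loci sample-wide and flag each variant as in/outside a locus.
    Deterministic for fixed input and parameters.  Input is preprocessed
    (sorted, overlapping records merged) if it is not already.
    """
    params = params or DetectionParams()
    collection = preprocess(variants)
    df = collection.df
    if df.empty:
        logger.warning("empty sample: no variants to analyse")
        empty = df.assign(in_kataegis=pd.Series(dtype=bool))
        return DetectionResult(
            loci=[],
            segments=[],
            variants=VariantCollection(empty, collection.chromosome_lengths),
            params=params,
            summary=None,
        )
    collection.validate()

    segments: list[Segment] = []
    imd_by_chrom: dict[str, ImdSequence] = {}
    cpts_by_chrom: dict[str, ChangepointResult] = {}
    imd_parts: list[np.ndarray] = []
    minseg = params.changepoint.min_seg_len
    for chrom in collection.chromosomes:
        positions = df.loc[df["chromosome"] == chrom, "start"].to_numpy()
        imd = compute_imd(positions, collection.chromosome_lengths[chrom], chrom)
        obs = imd.observations()
        if obs.size < 2 * minseg:
            cpts = ChangepointResult(changepoints=(obs.size,), total_objective=0.0)
        else:
            cpts = segment_observations(obs, params.changepoint)
        imd_by_chrom[chrom] = imd
        cpts_by_chrom[chrom] = cpts
        segments.extend(annotate_segments(cpts, imd))
        imd_parts.append(imd.imds)

    genome_length = sum(
        collection.chromosome_lengths[c] for c in collection.chromosomes
    )
    summary = sample_rate(segments, genome_length, np.concatenate(imd_parts))
    loci = call_kataegis(segments, summary, params)

    flags = np.zeros(len(df), dtype=bool)
    for locus in loci:
        flags |= (
            (df["chromosome"] == locus.chromosome)
            & (df["start"] >= locus.genomic_start)
            & (df["start"] <= locus.genomic_end)
        ).to_numpy()
    flagged = VariantCollection(
        df.assign(in_kataegis=flags), collection.chromosome_lengths
    )
    flagged.df["in_kataegis"] = flags
    return DetectionResult(
        loci=loci,
        segments=segments,
        variants=flagged,
        params=params,
        summary=summary,
        imd_by_chromosome=imd_by_chrom,
        changepoints_by_chromosome=cpts_by_chrom,
    )
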