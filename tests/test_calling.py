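"""Segment annotation, rate identities, cutoffs, and locus calling."""

import math

import numpy as np
import pytest

from kataseg import (
    DetectionParams,
    KataegisDetector,
    SyntheticSampleSpec,
    annotate_segments,
    call_kataegis,
    compute_imd,
    detect,
    generate_sample,
    pcawg_imd_cutoff,
    sample_rate,
)
from kataseg.calling import SampleSummary, Segment
from kataseg.changepoint import ChangepointResult, pelt

from conftest import make_collection


def make_segment(
    count,
    mean_imd,
    length=None,
    chromosome="chr1",
    start=1,
    anchor=None,
):
    length = length or max(int(count * mean_imd), 1)
    end = start + length - 1
    return Segment(
        chromosome=chromosome,
        first_variant_index=1,
        last_variant_index=count,
        genomic_start=start,
        genomic_end=end,
        variant_count=count,
        length_bp=length,
        mean_imd=mean_imd,
        rate=count / length,
        first_variant_pos=start,
        last_variant_pos=end,
        anchor_pos=anchor,
    )


SUMMARY = SampleSummary(
    total_variants=100,
    genome_length=10**6,
    sample_rate=1e-4,
    segment_count=1,
    median_imd=1e4,
    lambda_med=math.log(2) / 1e4,
)


# ---------------------------------------------------------- annotate_segments
def test_single_segment_annotation():
    imd = compute_imd([100, 200, 400], 1000, "chr1")
    segs = annotate_segments(
        ChangepointResult(changepoints=(4,), total_objective=0.0), imd
    )
    assert len(segs) == 1
    (seg,) = segs
    assert seg.variant_count == 3  # pseudo-IMD not counted
    assert (seg.genomic_start, seg.genomic_end) == (1, 1000)
    assert seg.rate == pytest.approx(3 / 1000)
    assert seg.anchor_pos is None


def test_two_segment_fixture_annotation(two_segment_collection):
    res = detect(two_segment_collection)
    segs = res.segments
    assert [s.variant_count for s in segs] == [10, 10]
    assert [s.mean_imd for s in segs] == [1000.0, 10.0]
    assert segs[1].anchor_pos == segs[0].last_variant_pos
    assert sum(s.length_bp for s in segs) == 10100  # tiles the chromosome


def test_segment_tiling_on_random_fixtures():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(1, 60))
        positions = np.sort(rng.choice(np.arange(1, 10**6), size=n, replace=False))
        length = int(positions[-1] + rng.integers(0, 10**5))
        imd = compute_imd(positions, length, "chr1")
        obs = imd.observations()
        cpts = (
            pelt(obs)
            if obs.size >= 4
            else ChangepointResult(changepoints=(obs.size,), total_objective=0.0)
        )
        segs = annotate_segments(cpts, imd)
        assert sum(s.length_bp for s in segs) == length
        assert sum(s.variant_count for s in segs) == n


# ---------------------------------------------------------------- sample_rate
def test_sample_rate_single_segment():
    seg = make_segment(10, 100.0, length=1000)
    summary = sample_rate([seg], 1000)
    assert summary.sample_rate == pytest.approx(seg.rate)


def test_sample_rate_three_segment_toy():
    segs = [
        make_segment(2, 50.0, length=100),
        make_segment(3, 33.0, length=100, start=101),
        make_segment(5, 160.0, length=800, start=201),
    ]
    summary = sample_rate(segs, 1000)
    assert summary.sample_rate == pytest.approx(10 / 1000)
    assert summary.total_variants == 10


def test_sample_rate_weighted_form_equals_direct_on_random_fixtures():
    rng = np.random.default_rng(23)
    for _ in range(50):
        pos = 1
        segs = []
        for _ in range(int(rng.integers(1, 8))):
            length = int(rng.integers(10, 10**5))
            count = int(rng.integers(0, 50))
            segs.append(
                make_segment(count, 10.0, length=length, start=pos)
            )
            pos += length
        genome = pos - 1
        summary = sample_rate(segs, genome)  # raises if the identity breaks
        k_t = sum(s.variant_count for s in segs)
        weighted = sum(s.rate * s.length_bp for s in segs) / genome
        assert weighted == pytest.approx(k_t / genome, rel=1e-9)


# ---------------------------------------------------------------- PCAWG rule
def test_pcawg_cutoff_cap_case():
    import dataclasses

    seg = make_segment(10, 900.0, length=10_000)
    summary = dataclasses.replace(
        SUMMARY, median_imd=1e5, lambda_med=math.log(2) / 1e5
    )
    raw = -math.log(1 - (0.01 / 1e4) ** (1 / 9)) / (math.log(2) / 1e5)
    assert raw == pytest.approx(3.50e4, rel=5e-3)
    assert pcawg_imd_cutoff(seg, summary) == 1000.0


def test_pcawg_cutoff_uncapped_values():
    # hand evaluation: k=5, L=1e6, median 2000 -> 29.00; k=2, L=1e3,
    # median 500 -> 7.2135e-3
    summary_2000 = SampleSummary(100, 10**6, 1e-4, 1, 2000.0, math.log(2) / 2000)
    assert pcawg_imd_cutoff(
        make_segment(5, 500.0, length=10**6), summary_2000
    ) == pytest.approx(29.0006, rel=1e-4)
    summary_500 = SampleSummary(100, 10**6, 1e-4, 1, 500.0, math.log(2) / 500)
    assert pcawg_imd_cutoff(
        make_segment(2, 400.0, length=1000), summary_500
    ) == pytest.approx(7.2135e-3, rel=1e-4)


def test_pcawg_cutoff_limits():
    assert pcawg_imd_cutoff(make_segment(1, 10.0), SUMMARY) == 0.0
    # longer segment at fixed k -> smaller cutoff
    cut = [
        pcawg_imd_cutoff(make_segment(5, 10.0, length=L), SUMMARY)
        for L in (10**4, 10**6, 10**8)
    ]
    assert cut[0] > cut[1] > cut[2]
    # halving the median IMD doubles lambda_med and halves the uncapped cutoff
    s_full = SampleSummary(100, 10**6, 1e-4, 1, 2000.0, math.log(2) / 2000)
    s_half = SampleSummary(100, 10**6, 1e-4, 1, 1000.0, math.log(2) / 1000)
    seg = make_segment(5, 100.0, length=10**6)
    assert pcawg_imd_cutoff(seg, s_half) == pytest.approx(
        pcawg_imd_cutoff(seg, s_full) / 2
    )


# -------------------------------------------------------------- call_kataegis
def test_call_boundary_mean_imd_is_inclusive():
    params = DetectionParams()
    assert len(call_kataegis([make_segment(6, 1000.0)], SUMMARY, params)) == 1
    assert len(call_kataegis([make_segment(6, 1000.5)], SUMMARY, params)) == 0
    assert len(call_kataegis([make_segment(5, 100.0)], SUMMARY, params)) == 0


def test_adjacent_qualifying_segments_merge():
    a = make_segment(6, 500.0, length=3000, start=1)
    b = make_segment(7, 400.0, length=2800, start=3001)
    loci = call_kataegis([a, b], SUMMARY, DetectionParams())
    assert len(loci) == 1
    assert loci[0].variant_count == 13
    pooled = (6 * 500.0 + 7 * 400.0) / 13
    assert loci[0].mean_imd == pytest.approx(pooled)
    assert (loci[0].genomic_start, loci[0].genomic_end) == (1, 5800)


def test_anchor_variant_counts_toward_minimum_size():
    """Six clustered variants show five clustered IMDs; the upstream anchor
    completes the count, so a planted 6-variant cluster is callable."""
    seg_with_anchor = make_segment(5, 100.0, start=1000, anchor=900)
    assert len(call_kataegis([seg_with_anchor], SUMMARY, DetectionParams())) == 1
    seg_chrom_start = make_segment(5, 100.0, start=1000, anchor=None)
    assert len(call_kataegis([seg_chrom_start], SUMMARY, DetectionParams())) == 0


def test_callable_cutoff_is_used_per_segment():
    params = DetectionParams(imd_cutoff=lambda seg, summ: 50.0)
    assert len(call_kataegis([make_segment(6, 100.0)], SUMMARY, params)) == 0
    assert len(call_kataegis([make_segment(6, 49.0)], SUMMARY, params)) == 1


# --------------------------------------------------------------------- detect
def test_detect_six_variant_cluster_end_to_end(clustered_collection):
    res = detect(clustered_collection)
    assert len(res.loci) == 1
    locus = res.loci[0]
    assert locus.variant_count == 6
    assert locus.genomic_start == 2_000_000  # includes the cluster's first variant
    assert locus.genomic_end == 2_000_500
    assert res.labels.sum() == 6


def test_detect_synthetic_high_burden_sample():
    """A TMB-500 sample with one planted 50-variant locus at expected IMD 100
    is recovered with default parameters."""
    spec = SyntheticSampleSpec(
        tmb=500, n_loci=1, variants_per_locus=50, expected_imd=100, seed=7
    )
    sample = generate_sample(spec)
    res = detect(sample.variants)
    assert len(res.loci) >= 1
    planted = sample.planted_loci[0]
    hits = [
        l
        for l in res.loci
        if l.genomic_start <= planted.end and l.genomic_end >= planted.start
    ]
    assert hits and hits[0].variant_count >= 50


def test_detect_small_cluster_never_called():
    cluster = 2_000_000 + np.arange(5) * 100  # 5 variants < minSizeKataegis
    coll = make_collection(
        np.concatenate(([1000], cluster, [3_900_000])), 4_000_000
    )
    assert detect(coll).loci == []


def test_null_samples_rarely_produce_loci():
    """False-positive sample rate under the uniform null at TMB 0.1."""
    false_positives = 0
    for seed in range(20):
        sample = generate_sample(SyntheticSampleSpec(tmb=0.1, seed=seed))
        if detect(sample.variants).loci:
            false_positives += 1
    assert false_positives / 20 <= 0.05


def test_flags_are_consistent_with_loci(two_segment_collection):
    res = detect(two_segment_collection)
    df = res.variants.df
    for _, row in df.iterrows():
        inside = [
            l
            for l in res.loci
            if l.chromosome == row["chromosome"]
            and l.genomic_start <= row["start"] <= l.genomic_end
        ]
        assert row["in_kataegis"] == (len(inside) == 1)
        assert len(inside) <= 1
    for locus in res.loci:
        length = res.variants.chromosome_lengths[locus.chromosome]
        assert 1 <= locus.genomic_start <= locus.genomic_end <= length


def test_flag_monotonicity_in_parameters():
    rng = np.random.default_rng(31)
    bg = np.sort(rng.choice(np.arange(1, 10**6), size=60, replace=False))
    cluster = 500_000 + np.cumsum(rng.integers(50, 300, size=8))
    coll = make_collection(np.unique(np.concatenate([bg, cluster])), 2 * 10**6)
    flagged = []
    for cutoff, min_size in [(200.0, 8), (1000.0, 6), (5000.0, 4)]:
        params = DetectionParams(imd_cutoff=cutoff, min_size_kataegis=min_size)
        flagged.append(detect(coll, params).labels.sum())
    assert flagged == sorted(flagged)


def test_detect_empty_sample_returns_empty_result():
    coll = make_collection([], 1000)
    res = detect(coll)
    assert res.loci == [] and res.segments == [] and len(res.variants) == 0


def test_detect_is_deterministic(clustered_collection):
    a = detect(clustered_collection)
    b = detect(clustered_collection)
    assert a.loci == b.loci
    assert (a.labels == b.labels).all()


# --------------------------------------------------------- sklearn estimator
def test_detector_sklearn_api(clustered_collection):
    from sklearn.base import clone

    det = KataegisDetector(min_size_kataegis=6)
    cloned = clone(det)
    assert cloned.get_params() == det.get_params()
    labels = det.fit_predict(clustered_collection)
    assert labels.sum() == 6
    assert det.n_loci_ == 1
    assert len(det.segments_) == len(det.result_.segments)
    det.set_params(min_size_kataegis=7)
    assert det.fit_predict(clustered_collection).sum() == 0


def test_detector_accepts_dataframe_with_genome():
    cluster = 2_000_000 + np.arange(6) * 100
    df = make_collection(
        np.concatenate(([1_000, 900_000], cluster, [3_500_000])), 4_000_000
    ).df[["chromosome", "start", "ref", "alt"]]
    det = KataegisDetector(genome={"chr1": 4_000_000})
    det.fit(df)
    assert det.n_loci_ == 1


def test_detector_requires_genome_for_bare_dataframe():
    df = make_collection([100, 200], 1000).df[["chromosome", "start"]]
    with pytest.raises(ValueError, match="chromosome-length"):
        KataegisDetector().fit(df)
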