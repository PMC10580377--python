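"""Synthetic mutation samples with planted kataegis loci.

Background mutations follow a Bernoulli process along the chromosome: each
base mutates with the same probability, so inter-mutation distances are
geometric.  A sample's background count is fixed by its tumor mutational
burden (TMB, mutations per Mbp); conditioned on that count, the process is
equivalent to sampling positions uniformly without replacement, which is
how positions are drawn here.  Each planted kataegis locus receives ``k``
variants placed uniformly in a window sized so that the expected
intra-locus IMD equals the requested value:
``end = start + E(T) * (k + 1) - 1``.

The benchmark design crosses 8 TMB classes (0.1–500) with a grid of locus
count {1,2,3,5} x variants-per-locus {6,10,25,50} x expected IMD
{100,250,500,750}, plus 64 locus-free samples per class: 1,024 samples on
a chromosome of 249,250,621 bp (hg19 chr1), 176 planted loci and 4,004
planted in-locus variants per class.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io import VariantCollection

__all__ = [
    "SyntheticSampleSpec",
    "PlannedLocus",
    "LabeledSample",
    "n_background",
    "generate_sample",
    "assign_alleles",
    "dataset_specs",
    "iter_dataset",
    "generate_dataset",
    "CHR1_LENGTH",
    "TMB_CLASSES",
    "N_LOCI_GRID",
    "K_GRID",
    "EXPECTED_IMD_GRID",
]

#: hg19 chromosome 1 length in bp, the default simulation chromosome
CHR1_LENGTH = 249_250_621

TMB_CLASSES = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0)
N_LOCI_GRID = (1, 2, 3, 5)
K_GRID = (6, 10, 25, 50)
EXPECTED_IMD_GRID = (100, 250, 500, 750)
N_NULL_PER_CLASS = 64

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SyntheticSampleSpec:
    """Design of one synthetic sample."""

    tmb: float
    n_loci: int = 0
    variants_per_locus: int = 0
    expected_imd: int = 0
    chromosome_length: int = CHR1_LENGTH
    chromosome: str = "chr1"
    seed: int = 0
    replicate: int | None = None  # distinguishes otherwise-identical samples

    def __post_init__(self) -> None:
        if self.tmb < 0:
            raise ValueError("tmb must be nonnegative")
        if self.n_loci > 0 and (self.variants_per_locus < 1 or self.expected_imd < 1):
            raise ValueError(
                "kataegis samples need variants_per_locus >= 1 and expected_imd >= 1"
            )

    @property
    def n_background(self) -> int:
        return n_background(self.tmb, self.chromosome_length)

    @property
    def name(self) -> str:
        base = (
            f"{self.n_background}_{self.n_loci}_"
            f"{self.variants_per_locus}_{self.expected_imd}"
        )
        return base if self.replicate is None else f"{base}_{self.replicate}"


@dataclass(frozen=True)
class PlannedLocus:
    """A planted kataegis locus: ``end - start + 1 = expected_imd * (k + 1)``."""

    start: int
    end: int
    k: int


@dataclass
class LabeledSample:
    """A generated sample with per-variant ground truth."""

    variants: VariantCollection
    planted_loci: list[PlannedLocus]
    name: str
    spec: SyntheticSampleSpec

    @property
    def truth(self) -> np.ndarray:
        return self.variants.df["truth_label"].to_numpy(dtype=bool)

    @property
    def n_in_locus(self) -> int:
        return int(self.truth.sum())


def n_background(tmb: float, chromosome_length: int) -> int:
    """Background mutation count for a TMB (mutations/Mbp) and chromosome.

    Inverts TMB = count / length * 1e6, rounding half away from zero
    (e.g. TMB 10 on 249,250,621 bp gives 2492.506... -> 2493).
    """
    if tmb < 0:
        raise ValueError("tmb must be nonnegative")
    return int(np.floor(tmb * chromosome_length / 1e6 + 0.5))


def _sample_unique(
    rng: np.random.Generator, n: int, low: int, high: int, exclude: np.ndarray
) -> np.ndarray:
    """Draw n distinct integers uniformly from [low, high], avoiding `exclude`.

    Rejection with top-up: repeatedly draws, deduplicates, and refills; the
    accepted set is a uniform sample without replacement.
    """
    span = high - low + 1
    if n > span - len(exclude):
        raise ValueError("cannot place that many distinct positions")
    taken = np.sort(exclude) if len(exclude) else np.empty(0, dtype=np.int64)
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        need = n - out.size
        draw = rng.integers(low, high + 1, size=max(int(need * 1.1) + 16, need))
        draw = np.unique(draw)
        if taken.size:
            draw = draw[~np.isin(draw, taken)]
        if out.size:
            draw = draw[~np.isin(draw, out)]
        rng.shuffle(draw)
        out = np.concatenate([out, draw[:need]])
    return np.sort(out)


def _place_loci(
    rng: np.random.Generator, spec: SyntheticSampleSpec
) -> list[PlannedLocus]:
    k = spec.variants_per_locus
    locus_len = spec.expected_imd * (k + 1)
    if spec.n_loci * locus_len > spec.chromosome_length:
        raise ValueError("planted loci cannot fit on the chromosome")
    placed: list[PlannedLocus] = []
    for _ in range(spec.n_loci):
        for _attempt in range(10_000):
            start = int(rng.integers(1, spec.chromosome_length - locus_len + 2))
            end = start + locus_len - 1
            if all(end < p.start or start > p.end for p in placed):
                placed.append(PlannedLocus(start=start, end=end, k=k))
                break
        else:  # pragma: no cover - astronomically unlikely at benchmark scale
            raise RuntimeError("failed to place disjoint kataegis loci")
    return sorted(placed, key=lambda p: p.start)


def generate_sample(
    spec: SyntheticSampleSpec, with_alleles: bool = True
) -> LabeledSample:
    """Generate one labeled synthetic sample, deterministically from its seed.

    Locus positions are drawn first (k distinct positions uniform within
    each planted window), then background positions uniform over the whole
    chromosome avoiding collisions, so all positions are unique.  A variant
    is labeled in-kataegis iff it falls inside a planted window — including
    background variants that land there by chance.
    """
    rng = np.random.default_rng(spec.seed)
    loci = _place_loci(rng, spec) if spec.n_loci else []
    locus_positions = [
        np.sort(rng.choice(np.arange(l.start, l.end + 1), size=l.k, replace=False))
        for l in loci
    ]
    in_locus = (
        np.concatenate(locus_positions)
        if locus_positions
        else np.empty(0, dtype=np.int64)
    )
    n_bg = spec.n_background
    background = _sample_unique(rng, n_bg, 1, spec.chromosome_length, in_locus)
    positions = np.sort(np.concatenate([in_locus, background]))
    labels = np.zeros(positions.size, dtype=bool)
    for l in loci:
        labels |= (positions >= l.start) & (positions <= l.end)
    df = pd.DataFrame(
        {
            "chromosome": spec.chromosome,
            "start": positions,
            "end": positions,
            "ref": "N",
            "alt": "N",
            "sample_id": spec.name,
            "truth_label": labels,
        }
    )
    sample = LabeledSample(
        variants=VariantCollection(df, {spec.chromosome: spec.chromosome_length}),
        planted_loci=loci,
        name=spec.name,
        spec=spec,
    )
    if with_alleles:
        sample = assign_alleles(sample, int(rng.integers(0, 2**31)))
    return sample


def assign_alleles(sample: LabeledSample, seed: int) -> LabeledSample:
    """Assign SNV alleles: ref uniform over ACGT, alt uniform over the rest."""
    rng = np.random.default_rng(seed)
    n = len(sample.variants)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    df = sample.variants.df.copy()
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[alt_idx]
    return LabeledSample(
        variants=VariantCollection(df, dict(sample.variants.chromosome_lengths)),
        planted_loci=sample.planted_loci,
        name=sample.name,
        spec=sample.spec,
    )


def _derive_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % 2**31)


def dataset_specs(
    chromosome_length: int = CHR1_LENGTH,
    seed: int = 0,
    tmb_classes: Sequence[float] = TMB_CLASSES,
    n_loci_grid: Sequence[int] = N_LOCI_GRID,
    k_grid: Sequence[int] = K_GRID,
    imd_grid: Sequence[int] = EXPECTED_IMD_GRID,
    n_null: int = N_NULL_PER_CLASS,
) -> list[SyntheticSampleSpec]:
    """The full benchmark design: per TMB class, one sample per grid
    combination plus ``n_null`` locus-free samples.

    Every sample's seed is derived from the master seed and its position in
    the design, so any single sample can be regenerated in isolation.
    """
    specs: list[SyntheticSampleSpec] = []
    for ci, tmb in enumerate(tmb_classes):
        si = 0
        for n_loci in n_loci_grid:
            for k in k_grid:
                for imd in imd_grid:
                    specs.append(
                        SyntheticSampleSpec(
                            tmb=tmb,
                            n_loci=n_loci,
                            variants_per_locus=k,
                            expected_imd=imd,
                            chromosome_length=chromosome_length,
                            seed=_derive_seed(seed, ci, si),
                        )
                    )
                    si += 1
        for r in range(n_null):
            specs.append(
                SyntheticSampleSpec(
                    tmb=tmb,
                    chromosome_length=chromosome_length,
                    seed=_derive_seed(seed, ci, si),
                    replicate=r,
                )
            )
            si += 1
    return specs


def iter_dataset(
    specs: Sequence[SyntheticSampleSpec], with_alleles: bool = True
) -> Iterator[LabeledSample]:
    """Generate samples one at a time (the full benchmark holds ~21M variants)."""
    for spec in specs:
        yield generate_sample(spec, with_alleles=with_alleles)


def _write_vcf(sample: LabeledSample, path: str | os.PathLike) -> None:
    df = sample.variants.df
    chrom = sample.spec.chromosome
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={sample.spec.chromosome_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n"
            )


def generate_dataset(
    chromosome_length: int = CHR1_LENGTH,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
    **design_kwargs,
) -> dict:
    """Generate the benchmark dataset and return its manifest.

    With ``out_dir`` set, writes per sample: a VCF, a truth TSV
    (chromosome, position, label) and a BED of planted loci, plus a JSON
    manifest keyed by sample name.  Without it, only the manifest is built
    (samples are generated and discarded after counting).
    """
    specs = dataset_specs(chromosome_length=chromosome_length, seed=seed, **design_kwargs)
    manifest: dict = {
        "chromosome_length": chromosome_length,
        "seed": seed,
        "samples": {},
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    for sample in iter_dataset(specs):
        spec = sample.spec
        entry = {
            "tmb": spec.tmb,
            "n_loci": spec.n_loci,
            "variants_per_locus": spec.variants_per_locus,
            "expected_imd": spec.expected_imd,
            "seed": spec.seed,
            "n_variants": len(sample.variants),
            "n_background": spec.n_background,
            "n_in_locus": sample.n_in_locus,
            "planted_loci": [
                dataclasses.asdict(l) for l in sample.planted_loci
            ],
        }
        manifest["samples"][sample.name] = entry
        if out_dir is not None:
            _write_vcf(sample, os.path.join(out_dir, f"{sample.name}.vcf"))
            truth = sample.variants.df[["chromosome", "start", "truth_label"]]
            truth = truth.rename(columns={"start": "position", "truth_label": "label"})
            truth.to_csv(
                os.path.join(out_dir, f"{sample.name}.truth.tsv"), sep="\t", index=False
            )
            with open(os.path.join(out_dir, f"{sample.name}.loci.bed"), "w") as fh:
                for l in sample.planted_loci:
                    fh.write(f"{spec.chromosome}\t{l.start - 1}\t{l.end}\n")
    if out_dir is not None:
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest
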