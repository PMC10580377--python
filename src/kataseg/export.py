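"""Writers for detection results (BED, TSV, flagged VCF).

Coordinates are 1-based inclusive everywhere inside the package; BED output
converts to 0-based half-open at this boundary only.
"""

from __future__ import annotations

import os
from typing import Sequence

from .calling import DetectionResult, KataegisLocus

__all__ = [
    "write_loci_bed",
    "write_loci_tsv",
    "write_segments_tsv",
    "write_flagged_tsv",
    "write_flagged_vcf",
    "read_loci_bed",
]


def write_loci_bed(loci: Sequence[KataegisLocus], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.chromosome}\t{l.genomic_start - 1}\t{l.genomic_end}\t"
                f"kataegis\t{l.variant_count}\n"
            )


def read_loci_bed(path: str | os.PathLike) -> list[KataegisLocus]:
    """Read loci from BED (any tool's calls); counts default to 0 if absent."""
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            count = int(parts[4]) if len(parts) > 4 and parts[4].isdigit() else 0
            loci.append(
                KataegisLocus(
                    chromosome=parts[0],
                    genomic_start=int(parts[1]) + 1,
                    genomic_end=int(parts[2]),
                    variant_count=count,
                    mean_imd=float("nan"),
                )
            )
    return loci


def write_loci_tsv(result: DetectionResult, path: str | os.PathLike) -> None:
    result.loci_frame().to_csv(path, sep="\t", index=False)


def write_segments_tsv(result: DetectionResult, path: str | os.PathLike) -> None:
    result.segments_frame().to_csv(path, sep="\t", index=False)


def write_flagged_tsv(result: DetectionResult, path: str | os.PathLike) -> None:
    """Variant table with the per-variant in_kataegis flag."""
    df = result.variants.df.rename(columns={"sample_id": "sample"})
    if "truth_label" in df.columns and df["truth_label"].isna().all():
        df = df.drop(columns=["truth_label"])
    df.to_csv(path, sep="\t", index=False)


def write_flagged_vcf(result: DetectionResult, path: str | os.PathLike) -> None:
    """Minimal VCF of the analysed variants; in-kataegis rows get INFO KATAEGIS=1."""
    df = result.variants.df
    lengths = result.variants.chromosome_lengths
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=KATAEGIS,Number=0,Type=Flag,'
            'Description="Variant lies within a called kataegis locus">\n'
        )
        for chrom in result.variants.chromosomes:
            if chrom in lengths:
                fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in df.itertuples(index=False):
            info = "KATAEGIS" if row.in_kataegis else "."
            ref = row.ref if row.ref and row.ref != "-" else "N"
            alt = row.alt if row.alt and row.alt != "-" else "N"
            fh.write(
                f"{row.chromosome}\t{row.start}\t.\t{ref}\t{alt}\t.\t.\t{info}\n"
            )
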