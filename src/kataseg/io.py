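"""Reading, validating and preprocessing somatic variant calls.

Variants enter from VCF (via :mod:`cyvcf2`), MAF (GDC-style tab-delimited)
or a generic TSV table and are held in a :class:`VariantCollection`: a
pandas DataFrame of 1-based inclusive coordinates plus a chromosome-length
table.  Preprocessing sorts each chromosome and merges overlapping records
so that downstream intermutation distances are strictly positive; phasing
and clonality are deliberately ignored.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "VariantCollection",
    "read_variants",
    "read_chromosome_lengths",
    "preprocess",
    "classify_substitution",
    "write_variants_tsv",
    "SUBSTITUTION_CLASSES",
]

_NUCLEOTIDES = frozenset("ACGTN")

#: pyrimidine-normalized single-base substitution classes plus catch-alls
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G", "MNV", "indel", "other")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_MAF_REQUIRED = [
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
]

_COLUMNS = ["chromosome", "start", "end", "ref", "alt", "sample_id", "truth_label"]


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One somatic variant with 1-based inclusive coordinates."""

    chromosome: str
    start: int
    end: int
    ref: str
    alt: str
    sample_id: str = ""
    truth_label: bool | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1 (coordinates are 1-based)")
        if self.end < self.start:
            raise ValueError("end must be >= start")


class VariantCollection:
    """Ordered variant records of one or more samples plus chromosome lengths.

    Parameters
    ----------
    records
        DataFrame with columns chromosome/start/end/ref/alt/sample_id
        (truth_label optional), or an iterable of :class:`VariantRecord`.
    chromosome_lengths
        Mapping from chromosome name to its length in base pairs.
    """

    def __init__(
        self,
        records: pd.DataFrame | Iterable[VariantRecord],
        chromosome_lengths: Mapping[str, int] | None = None,
    ) -> None:
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        if df.empty:
            df = pd.DataFrame(columns=_COLUMNS)
        for col, default in (("sample_id", ""), ("truth_label", None)):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"variant table lacks required columns: {missing}")
        df = df[_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chromosome"] = df["chromosome"].astype(str)
        self.df = df
        self.chromosome_lengths: dict[str, int] = dict(chromosome_lengths or {})

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[VariantRecord]:
        for row in self.df.itertuples(index=False):
            yield VariantRecord(
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                ref=row.ref,
                alt=row.alt,
                sample_id=row.sample_id,
                truth_label=None if pd.isna(row.truth_label) else bool(row.truth_label),
            )

    @property
    def records(self) -> list[VariantRecord]:
        return list(self)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.df["chromosome"].unique(), key=_chromosome_sort_key)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def for_sample(self, sample_id: str) -> "VariantCollection":
        return VariantCollection(
            self.df[self.df["sample_id"] == sample_id], self.chromosome_lengths
        )

    def validate(self) -> None:
        """Check coordinate invariants against the chromosome-length table."""
        df = self.df
        if (df["start"] < 1).any():
            raise ValueError("variant with start < 1 (coordinates are 1-based)")
        if (df["end"] < df["start"]).any():
            raise ValueError("variant with end < start")
        if not self.chromosome_lengths:
            raise ValueError("chromosome_lengths table is empty")
        for chrom, sub in df.groupby("chromosome", sort=False):
            if chrom not in self.chromosome_lengths:
                raise ValueError(f"chromosome {chrom!r} absent from length table")
            length = self.chromosome_lengths[chrom]
            if (sub["end"] > length).any():
                raise ValueError(
                    f"variant beyond end of chromosome {chrom} (length {length})"
                )


def _chromosome_sort_key(name: str):
    core = name[3:] if name.lower().startswith("chr") else name
    if core.isdigit():
        return (0, int(core), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (0, order[core], "") if core in order else (1, 0, core)


def _normalize_chromosome_names(df: pd.DataFrame, lengths: Mapping[str, int]) -> None:
    """Rewrite 'chr1' <-> '1' in place to match the length table's dialect."""
    if not lengths:
        return
    table_prefixed = all(str(k).lower().startswith("chr") for k in lengths)
    chroms = df["chromosome"].astype(str)
    if table_prefixed:
        mask = ~chroms.str.lower().str.startswith("chr")
        df.loc[mask, "chromosome"] = "chr" + chroms[mask]
    else:
        mask = chroms.str.lower().str.startswith("chr")
        df.loc[mask, "chromosome"] = chroms[mask].str[3:]


def read_chromosome_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column chromosome-length table (name, length in bp).

    Accepts the samtools ``.fai`` layout as well (extra columns ignored).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    return {str(row[0]): int(row[1]) for row in df.itertuples(index=False)}


def _infer_format(path: str) -> str:
    lowered = str(path).lower()
    for suffix in (".gz", ".bgz"):
        if lowered.endswith(suffix):
            lowered = lowered[: -len(suffix)]
    if lowered.endswith(".vcf"):
        return "vcf"
    if lowered.endswith(".maf"):
        return "maf"
    if lowered.endswith((".tsv", ".txt")):
        return "tsv"
    raise ValueError(f"cannot infer variant format from file name {path!r}")


def _read_vcf(path: str, sample_id: str | None, keep_filtered: bool) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    name = sample_id or os.path.basename(str(path)).split(".")[0]
    rows = []
    for v in vcf:
        if not keep_filtered and v.FILTER is not None:
            continue
        ref = v.REF
        alts = v.ALT if v.ALT else ["."]
        for alt in alts:  # multi-allelic rows become one record per alt
            rows.append((v.CHROM, v.POS, v.POS + len(ref) - 1, ref, alt, name))
    lengths = {}
    try:
        lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header without contig lengths
        pass
    vcf.close()
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "ref", "alt", "sample_id"])
    df.attrs["header_lengths"] = {str(k): int(v) for k, v in lengths.items()}
    return df


def _read_maf(path: str, sample_id: str | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: MAF file lacks required columns {missing}")
    sample_col = "Tumor_Sample_Barcode"
    samples = df[sample_col] if sample_col in df.columns else ""
    out = pd.DataFrame(
        {
            "chromosome": df["Chromosome"],
            "start": df["Start_Position"].astype(np.int64),
            "end": df["End_Position"].astype(np.int64),
            "ref": df["Reference_Allele"].fillna("-"),
            "alt": df["Tumor_Seq_Allele2"].fillna("-"),
            "sample_id": samples,
        }
    )
    if sample_id is not None:
        out = out[out["sample_id"] == sample_id]
    return out


def _read_tsv(path: str, sample_id: str | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chromosome", "start", "end", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variant TSV lacks required columns {missing}")
    out = df.rename(columns={"sample": "sample_id"})
    if "sample_id" not in out.columns:
        out["sample_id"] = ""
    if "truth_label" in out.columns:
        out["truth_label"] = out["truth_label"].astype(bool)
    if sample_id is not None:
        out = out[out["sample_id"] == sample_id]
    return out


def read_variants(
    path: str | os.PathLike,
    format: str | None = None,
    sample_id: str | None = None,
    chromosome_lengths: Mapping[str, int] | str | os.PathLike | None = None,
    keep_filtered: bool = True,
) -> VariantCollection:
    """Read variant calls into a :class:`VariantCollection`.

    Parameters
    ----------
    path
        Input file (VCF v4.x, MAF, or generic TSV with a
        chromosome/start/end/ref/alt[/sample] header).
    format
        One of ``vcf``/``maf``/``tsv``; inferred from the extension if None.
    sample_id
        For multi-sample MAF/TSV inputs, keep only this sample's rows; for
        VCF it names the sample (default: the file stem).
    chromosome_lengths
        Mapping or two-column TSV path.  Chromosome names are normalized to
        the dialect of this table ("chr1" vs "1"); for VCF, contig lengths
        from the header are used when no table is given.
    keep_filtered
        Keep VCF rows whose FILTER is not PASS (default True: every row in
        the file is imported, including indels and structural variants).
    """
    fmt = format or _infer_format(str(path))
    if fmt == "vcf":
        df = _read_vcf(str(path), sample_id, keep_filtered)
    elif fmt == "maf":
        df = _read_maf(str(path), sample_id)
    elif fmt == "tsv":
        df = _read_tsv(str(path), sample_id)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")
    if chromosome_lengths is None:
        lengths = df.attrs.get("header_lengths", {})
    elif isinstance(chromosome_lengths, (str, os.PathLike)):
        lengths = read_chromosome_lengths(chromosome_lengths)
    else:
        lengths = dict(chromosome_lengths)
    _normalize_chromosome_names(df, lengths)
    return VariantCollection(df, lengths)


def preprocess(collection: VariantCollection) -> VariantCollection:
    """Sort per chromosome and merge overlapping records.

    Within each chromosome, records are sorted by start; any run of records
    whose [start, end] intervals overlap is replaced by one record spanning
    their union, keeping the alleles of the earliest record.  The output has
    strictly increasing starts per chromosome, so every intermutation
    distance is at least 1.  Idempotent.

    Raises
    ------
    ValueError
        If a record exceeds its chromosome's length or the length table is
        missing a chromosome.
    """
    df = collection.df
    if df.empty:
        return VariantCollection(df, collection.chromosome_lengths)
    out = df.sort_values(["chromosome", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    # group ids: a new group starts where the interval does not overlap the
    # running union of the previous group on the same chromosome
    new_chrom = out["chromosome"].ne(out["chromosome"].shift())
    running_end = (
        out.groupby("chromosome", sort=False)["end"].cummax().shift().fillna(-1)
    )
    overlap = (out["start"] <= running_end) & ~new_chrom
    group = (~overlap).cumsum()
    merged = out.groupby(group, sort=False).agg(
        chromosome=("chromosome", "first"),
        start=("start", "first"),
        end=("end", "max"),
        ref=("ref", "first"),
        alt=("alt", "first"),
        sample_id=("sample_id", "first"),
        truth_label=("truth_label", "first"),
    )
    result = VariantCollection(merged.reset_index(drop=True), collection.chromosome_lengths)
    if result.chromosome_lengths:
        result.validate()
    return result


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a ref/alt pair into the six pyrimidine-normalized SNV classes,
    MNV, indel, or other.

    Single-base substitutions with a purine reference are reverse-complement
    normalized (e.g. G>T is reported as C>A); equal-length multi-base changes
    are MNV; length-changing ones are indels.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be nonempty")
    ref = ref.upper()
    alt = alt.upper()
    if ref == "-" or alt == "-":  # MAF-style indel markers
        return "indel"
    if not (set(ref) <= _NUCLEOTIDES and set(alt) <= _NUCLEOTIDES):
        return "other"
    if len(ref) != len(alt):
        return "indel"
    if len(ref) > 1:
        return "MNV"
    if ref == alt or "N" in (ref, alt):
        return "other"
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def write_variants_tsv(collection: VariantCollection, path: str | os.PathLike) -> None:
    """Write the canonical tab-separated variant table.

    Columns: chromosome, start, end, ref, alt, sample, and truth_label when
    any record carries one.  Reading the file back with
    :func:`read_variants` restores (chromosome, start, end, ref, alt).
    """
    df = collection.df.rename(columns={"sample_id": "sample"})
    if df["truth_label"].isna().all():
        df = df.drop(columns=["truth_label"])
    df.to_csv(path, sep="\t", index=False)
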