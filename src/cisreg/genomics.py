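"""Genomic coordinate conventions, variants, interval arithmetic and descriptive stats.

Two coordinate dialects coexist in regulatory genomics: the 1-based fully
inclusive convention used for "g." positions and PCR amplicons, and the
0-based half-open convention of BED/BEDPE.  Everything in this package keeps
the convention explicit on the interval object and converts losslessly
between the two, so that region arithmetic (critical-region intersection,
variant spans) can never silently mix dialects.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Convention",
    "GenomicInterval",
    "Variant",
    "VariantTable",
    "BoxplotStats",
    "CoordinateError",
    "ParseError",
    "interval_length",
    "position_distance",
    "minimal_overlap",
    "variant_span",
    "recurrence_summary",
    "percentage",
    "boxplot_stats",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "read_vcf",
    "write_vcf",
    "read_variant_table",
    "write_variant_table",
]


class CoordinateError(ValueError):
    """Invalid genomic coordinates (bad ordering, mixed chromosomes...)."""


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class Convention(enum.Enum):
    ONE_BASED_INCLUSIVE = "one_based_inclusive"
    ZERO_BASED_HALF_OPEN = "zero_based_half_open"


@dataclass(frozen=True)
class GenomicInterval:
    """A contiguous genomic region under an explicit coordinate convention."""

    chrom: str
    start: int
    end: int
    convention: Convention = Convention.ONE_BASED_INCLUSIVE

    def __post_init__(self):
        if self.convention is Convention.ONE_BASED_INCLUSIVE:
            if self.end < self.start or self.start < 1:
                raise CoordinateError(
                    f"invalid one-based inclusive interval {self.chrom}:{self.start}-{self.end}"
                )
        else:
            if self.end <= self.start or self.start < 0:
                raise CoordinateError(
                    f"invalid zero-based half-open interval {self.chrom}:{self.start}-{self.end}"
                )

    def to_one_based(self) -> "GenomicInterval":
        if self.convention is Convention.ONE_BASED_INCLUSIVE:
            return self
        return GenomicInterval(
            self.chrom, self.start + 1, self.end, Convention.ONE_BASED_INCLUSIVE
        )

    def to_half_open(self) -> "GenomicInterval":
        if self.convention is Convention.ZERO_BASED_HALF_OPEN:
            return self
        return GenomicInterval(
            self.chrom, self.start - 1, self.end, Convention.ZERO_BASED_HALF_OPEN
        )

    @property
    def length(self) -> int:
        return interval_length(self)


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp; 397 for chr10:71,108,536-71,108,932 one-based inclusive."""
    if iv.convention is Convention.ONE_BASED_INCLUSIVE:
        return iv.end - iv.start + 1
    return iv.end - iv.start


def position_distance(p1: int, p2: int, chrom1: Optional[str] = None,
                      chrom2: Optional[str] = None) -> int:
    """Absolute distance in bp between two positions on the same chromosome."""
    if chrom1 is not None and chrom2 is not None and chrom1 != chrom2:
        raise CoordinateError(
            f"positions on different chromosomes ({chrom1} vs {chrom2})"
        )
    return abs(p2 - p1)


def minimal_overlap(intervals: Sequence[GenomicInterval]) -> Optional[GenomicInterval]:
    """Intersection of all intervals (the shared critical region).

    Returns ``None`` when the intersection is empty, so pipelines can report
    "no shared region" rather than crash.  All intervals must lie on one
    chromosome and share a convention.
    """
    if len(intervals) < 2:
        raise CoordinateError("minimal_overlap needs at least two intervals")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise CoordinateError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    conv = intervals[0].convention
    ones = [iv.to_one_based() for iv in intervals]
    start = max(iv.start for iv in ones)
    end = min(iv.end for iv in ones)
    if end < start:
        return None
    out = GenomicInterval(intervals[0].chrom, start, end, Convention.ONE_BASED_INCLUSIVE)
    return out if conv is Convention.ONE_BASED_INCLUSIVE else out.to_half_open()


_BASES = set("ACGT")


@dataclass(frozen=True)
class Variant:
    """A substitution or indel in VCF-style representation (1-based pos).

    ``ref``/``alt`` may carry the shared VCF padding base for indels; the
    ``affected_range`` property reports the first and last reference base the
    allele change actually touches (the padding base is excluded for pure
    indels, matching how "g." deletion coordinates are printed).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: Optional[str] = None
    inheritance: Optional[str] = None  # de_novo | inherited | unknown

    def __post_init__(self):
        if self.pos < 1:
            raise CoordinateError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if allele and not set(allele.upper()) <= _BASES:
                raise ValueError(
                    f"{name} allele {allele!r} at {self.chrom}:{self.pos} "
                    "contains non-ACGT characters"
                )
        if not self.ref and not self.alt:
            raise ValueError("both alleles empty")

    @property
    def kind(self) -> str:
        r, a = len(self.ref), len(self.alt)
        if r == a == 1:
            return "SNV"
        if r == a:
            return "indel"  # multi-nucleotide substitution
        pos, ref, alt = self.normalized()
        if not alt:
            return "deletion"
        if not ref:
            return "insertion"
        return "indel"

    def normalized(self) -> tuple[int, str, str]:
        """Strip the shared leading VCF padding base; returns (pos, ref, alt).

        A pure deletion comes back with an empty alt (pos = first deleted
        base), a pure insertion with an empty ref (pos = base after which the
        sequence is inserted, by the padding-base convention the insertion
        point follows the returned pos - 1 ... pos junction).
        """
        pos, ref, alt = self.pos, self.ref.upper(), self.alt.upper()
        while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
            pos += 1
            ref, alt = ref[1:], alt[1:]
        return pos, ref, alt

    @property
    def affected_range(self) -> tuple[int, int]:
        """(first, last) 1-based reference base affected by the change."""
        pos, ref, alt = self.normalized()
        if ref:
            return pos, pos + len(ref) - 1
        # pure insertion: the junction sits after pos-1; report the base
        # immediately left of the inserted sequence
        return pos - 1, pos - 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref.upper(), self.alt.upper())


class VariantTable:
    """Ordered, de-duplicated collection of :class:`Variant`.

    Duplicate (chrom, pos, ref, alt, sample_id) records are collapsed on
    entry so recurrence counts never double-count multi-file input.
    """

    def __init__(self, variants: Iterable[Variant] = ()):
        self._variants: list[Variant] = []
        self._seen: set = set()
        for v in variants:
            self.add(v)

    def add(self, v: Variant) -> None:
        k = v.key + (v.sample_id,)
        if k in self._seen:
            return
        self._seen.add(k)
        self._variants.append(v)

    def __len__(self) -> int:
        return len(self._variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._variants)

    def __getitem__(self, i) -> Variant:
        return self._variants[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "sample_id": v.sample_id,
                    "inheritance": v.inheritance,
                }
                for v in self._variants
            ],
            columns=["chrom", "pos", "ref", "alt", "sample_id", "inheritance"],
        )


def variant_span(vt: VariantTable) -> GenomicInterval:
    """Smallest 1-based inclusive interval covering every affected base.

    This is the "critical region by point variants" operation: the 14
    probands' substitutions in the study this package generalises all fell
    within a 42 bp span computed exactly this way.
    """
    if len(vt) == 0:
        raise CoordinateError("variant_span of an empty table")
    chroms = {v.chrom for v in vt}
    if len(chroms) > 1:
        raise CoordinateError(f"variants span multiple chromosomes: {sorted(chroms)}")
    firsts, lasts = zip(*(v.affected_range for v in vt))
    return GenomicInterval(vt[0].chrom, min(firsts), max(lasts),
                           Convention.ONE_BASED_INCLUSIVE)


@dataclass
class RecurrenceSummary:
    n_distinct_variants: int
    n_probands: int
    probands_per_variant: dict
    per_position: pd.DataFrame  # columns: chrom, pos, n_substitutions, n_carriers


def recurrence_summary(vt: VariantTable) -> RecurrenceSummary:
    """Distinct-variant and carrier counts, overall and per position.

    Distinctness is on (chrom, pos, ref, alt); carriers are counted once per
    sample per key.  The per-position table answers questions like "this
    position is hit by 3 different substitutions in 6 individuals".
    """
    if len(vt) == 0:
        return RecurrenceSummary(0, 0, {}, pd.DataFrame(
            columns=["chrom", "pos", "n_substitutions", "n_carriers"]))
    df = vt.to_frame()
    df["vkey"] = list(zip(df.chrom, df.pos, df.ref.str.upper(), df.alt.str.upper()))
    per_variant = df.groupby("vkey")["sample_id"].nunique()
    per_pos = (
        df.groupby(["chrom", "pos"])
        .agg(n_substitutions=("vkey", "nunique"), n_carriers=("sample_id", "nunique"))
        .reset_index()
    )
    return RecurrenceSummary(
        n_distinct_variants=int(per_variant.size),
        n_probands=int(df["sample_id"].nunique()),
        probands_per_variant={k: int(n) for k, n in per_variant.items()},
        per_position=per_pos,
    )


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100*n/d rounded half-away-from-zero to ``decimals`` places.

    Printed prevalences round this way: 374/46,885 cells -> 0.8%.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey boxplot summary: whiskers reach the furthest point within 1.5*IQR."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Quartiles by linear interpolation; Tukey whiskers and outliers."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot_stats of empty input")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = tuple(sorted(arr[(arr < lo_fence) | (arr > hi_fence)].tolist()))
    return BoxplotStats(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Sequences keyed by record id, upper-cased."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ParseError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """BED3+ records as zero-based half-open intervals."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"BED record has {len(parts)} fields, need >=3", line=i)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ParseError(f"non-integer BED coordinates: {e}", line=i) from None
            try:
                out.append(GenomicInterval(parts[0], start, end,
                                           Convention.ZERO_BASED_HALF_OPEN))
            except CoordinateError as e:
                raise ParseError(str(e), line=i) from None
    return out


def read_vcf(path: Union[str, Path]) -> VariantTable:
    """SNVs and indels from a VCF 4.x file; symbolic/breakend alts rejected.

    Multi-allelic records are split into one Variant per alt.  The first
    sample column, when present, provides ``sample_id`` for carriers
    (genotypes containing the alt allele); otherwise records are unassigned.
    """
    import pysam

    vt = VariantTable()
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for ai, alt in enumerate(rec.alts or (), start=1):
                if alt is None or alt.startswith("<") or any(c in alt for c in "[]."):
                    raise ParseError(
                        f"symbolic/breakend alt {alt!r} at {rec.chrom}:{rec.pos} "
                        "is not supported (SNVs and explicit indels only)"
                    )
                carriers = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt and ai in [g for g in gt if g is not None]:
                        carriers.append(s)
                if not carriers:
                    carriers = [rec.info.get("SAMPLE")]
                inh = rec.info.get("INH")
                for sample in carriers:
                    vt.add(Variant(rec.chrom, rec.pos, rec.ref, alt,
                                   sample_id=sample, inheritance=inh))
    return vt


def write_vcf(vt: VariantTable, path: Union[str, Path]) -> None:
    """Minimal sites-only VCF; sample and inheritance go in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample id">\n')
        fh.write('##INFO=<ID=INH,Number=1,Type=String,Description="Inheritance">\n')
        for chrom in dict.fromkeys(v.chrom for v in vt):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in vt:
            info = []
            if v.sample_id:
                info.append(f"SAMPLE={v.sample_id}")
            if v.inheritance:
                info.append(f"INH={v.inheritance}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"{';'.join(info) or '.'}\n"
            )


_TABLE_COLS = ["chrom", "pos", "ref", "alt", "sample_id", "inheritance"]


def read_variant_table(path: Union[str, Path]) -> VariantTable:
    """Tab-separated variant table: chrom, pos, ref, alt[, sample_id, inheritance]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise ParseError(f"variant table missing columns: {sorted(missing)}")
    vt = VariantTable()
    for row in df.itertuples(index=False):
        vt.add(Variant(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
            sample_id=(None if not hasattr(row, "sample_id") or pd.isna(row.sample_id)
                       else str(row.sample_id)),
            inheritance=(None if not hasattr(row, "inheritance") or pd.isna(row.inheritance)
                         else str(row.inheritance)),
        ))
    return vt


def write_variant_table(vt: VariantTable, path: Union[str, Path]) -> None:
    vt.to_frame().to_csv(path, sep="\t", index=False)
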