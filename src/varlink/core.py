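"""Core genomic coordinate types and readers/writers for standard text formats.

Every coordinate inside the package is 0-based, half-open ``[start, end)``
(the BED convention).  Formats that are 1-based on disk (VCF ``POS``, GWAS
tables, the mutation/CNV input TSVs) are shifted on read, so downstream code
never sees a 1-based coordinate.  Chromosome names are normalized to the
``chr``-prefixed form on read.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "MutationRecord",
    "CnvRecord",
    "GwasSnp",
    "BedRecord",
    "VcfRecord",
    "ChromSizes",
    "ParseError",
    "normalize_chrom",
    "chrom_sort_key",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "intersect",
    "load_gwas_snps",
    "read_vcf_minimal",
    "read_gmt",
    "write_gmt",
]

DIRECTIONS = frozenset({"deletion", "duplication"})
COHORTS = frozenset({"case", "control"})

#: chromosome name -> length in bp
ChromSizes = Dict[str, int]


class ParseError(ValueError):
    """A malformed line in an input file; carries the file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def normalize_chrom(name: str) -> str:
    """Return the ``chr``-prefixed form of a chromosome name."""
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


_CHROM_NUM = re.compile(r"^chr(\d+)$")


def chrom_sort_key(chrom: str) -> Tuple[int, int, str]:
    """Sort key giving the natural chr1 < chr2 < ... < chr10 < chrX order."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic point mutation observed in one sample."""

    sample_id: str
    position: GenomicInterval

    def __post_init__(self):
        if self.position.width != 1:
            raise ValueError("a point mutation must span exactly 1 bp")


@dataclass(frozen=True)
class CnvRecord:
    """One copy-number variant call (deletion or duplication) in one sample."""

    sample_id: str
    span: GenomicInterval
    direction: str
    cohort: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {sorted(COHORTS)}")


@dataclass(frozen=True)
class GwasSnp:
    """A GWAS variant with its association p-value."""

    rsid: str
    position: GenomicInterval
    p_value: float

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.position.width != 1:
            raise ValueError("a SNP must span exactly 1 bp")


@dataclass
class BedRecord:
    """One BED line: an interval plus the optional name/score/strand columns."""

    interval: GenomicInterval
    name: Optional[str] = None
    score: Optional[str] = None
    strand: Optional[str] = None


@dataclass(frozen=True)
class VcfRecord:
    """A minimal, per-ALT-allele view of a VCF record.

    ``dp`` is None when neither INFO nor the first sample's FORMAT carries a
    DP field; such records are kept but flagged by the missing value.
    """

    position: GenomicInterval
    ref: str
    alt: str
    qual: Optional[float]
    dp: Optional[int]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> ChromSizes:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: ChromSizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError(path, lineno, "expected chrom and length")
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer length {fields[1]!r}")
            if length <= 0:
                raise ParseError(path, lineno, f"length must be > 0, got {length}")
            sizes[normalize_chrom(fields[0])] = length
    return sizes


_BED_SKIP = ("#", "track", "browser")


def read_bed(path) -> List[BedRecord]:
    """Read BED3/BED6 records; track/browser/comment lines are skipped.

    Raises :class:`ParseError` (naming the line) on non-integer coordinates or
    zero/negative-width intervals.
    """
    records: List[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or any(line.startswith(p) for p in _BED_SKIP):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError(path, lineno, "fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            if end <= start or start < 0:
                raise ParseError(
                    path, lineno, f"invalid interval [{fields[1]}, {fields[2]})"
                )
            records.append(
                BedRecord(
                    interval=GenomicInterval(normalize_chrom(fields[0]), start, end),
                    name=fields[3] if len(fields) > 3 else None,
                    score=fields[4] if len(fields) > 4 else None,
                    strand=fields[5] if len(fields) > 5 else None,
                )
            )
    return records


def write_bed(records: Iterable[Union[BedRecord, GenomicInterval]], path) -> None:
    """Write BED records; only columns present on the record are emitted."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                rec = BedRecord(interval=rec)
            iv = rec.interval
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            for extra in (rec.name, rec.score, rec.strand):
                if extra is None:
                    break
                fields.append(str(extra))
            fh.write("\t".join(fields) + "\n")


def _build_trees(intervals: Sequence[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
    min_overlap_frac_of_a: float = 0.0,
) -> List[Tuple[int, int, int]]:
    """All same-chromosome overlapping pairs between two interval lists.

    Returns ``(a_index, b_index, overlap_bp)`` tuples for every pair with
    overlap >= ``min_overlap_bp`` and overlap >= ``min_overlap_frac_of_a`` x
    width(a).  The fraction is always computed on the first argument.
    """
    if not (0.0 <= min_overlap_frac_of_a <= 1.0):
        raise ValueError("min_overlap_frac_of_a must be in [0, 1]")
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees = _build_trees(b)
    out: List[Tuple[int, int, int]] = []
    for ai, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if ov >= min_overlap_bp and ov >= min_overlap_frac_of_a * iv.width:
                out.append((ai, hit.data, ov))
    out.sort()
    return out


def load_gwas_snps(path, p_threshold: float = 5e-8) -> List[GwasSnp]:
    """Load a GWAS table (rsid/chrom/pos/pvalue TSV, 1-based positions).

    Only SNPs with ``p_value < p_threshold`` (strict) are retained; the
    default is the conventional genome-wide significance level 5e-8.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    required = {"rsid", "chrom", "pos", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
    try:
        pvals = df["pvalue"].astype(float)
        positions = df["pos"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ParseError(path, 0, f"non-numeric pos/pvalue column: {exc}")
    snps: List[GwasSnp] = []
    for rsid, chrom, pos, p in zip(df["rsid"], df["chrom"], positions, pvals):
        if p < p_threshold:
            snps.append(
                GwasSnp(
                    rsid=str(rsid),
                    position=GenomicInterval(normalize_chrom(chrom), pos - 1, pos),
                    p_value=float(p),
                )
            )
    return snps


def read_vcf_minimal(path) -> List[VcfRecord]:
    """Read a VCF 4.x file into minimal per-ALT records via pysam.

    DP is taken from INFO when present, otherwise from the first sample's
    FORMAT field; missing DP is recorded as None.  Multiallelic records are
    expanded to one record per ALT allele.
    """
    import pysam

    records: List[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            dp = rec.info.get("DP")
            if dp is None and rec.samples:
                first = rec.samples[next(iter(rec.samples))]
                dp = first.get("DP")
            if isinstance(dp, tuple):
                dp = dp[0]
            pos = GenomicInterval(normalize_chrom(rec.chrom), rec.start, rec.start + 1)
            for alt in rec.alts or ():
                records.append(
                    VcfRecord(
                        position=pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=None if rec.qual is None else float(rec.qual),
                        dp=None if dp is None else int(dp),
                    )
                )
    return records


def read_gmt(path) -> List[Tuple[str, str, List[str]]]:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>gene...`` lines.

    Gene symbols are upper-cased and de-duplicated within a set (first
    occurrence order preserved).
    """
    sets: List[Tuple[str, str, List[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT line needs >= 3 fields")
            seen = dict.fromkeys(g.strip().upper() for g in fields[2:] if g.strip())
            sets.append((fields[0], fields[1], list(seen)))
    return sets


def write_gmt(sets: Iterable[Tuple[str, str, Iterable[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")
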