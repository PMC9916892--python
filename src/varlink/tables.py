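"""Readers/writers for the pipeline's TSV dialects.

On-disk positions are 1-based (the common TSV/VCF habit) and are shifted to
the internal 0-based half-open convention on read; BED-family files stay
0-based.  Writers format numbers deterministically so fixed-seed fixture
files are byte-identical.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import (
    ChromSizes,
    CnvRecord,
    GenomicInterval,
    MutationRecord,
    ParseError,
    VcfRecord,
    normalize_chrom,
)
from .epi import Interaction
from .genes import Variant

__all__ = [
    "read_mutations_tsv",
    "write_mutations_tsv",
    "read_cnvs_tsv",
    "write_cnvs_tsv",
    "read_interactions_tsv",
    "write_interactions_tsv",
    "read_variants_tsv",
    "write_variants_tsv",
    "write_vcf_minimal",
    "read_cnv_segments_bed",
    "write_cnv_segments_bed",
]


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_mutations_tsv(path) -> List[MutationRecord]:
    """Read ``sample_id  chrom  pos_1based`` (header optional)."""
    records: List[MutationRecord] = []
    for lineno, fields in _data_lines(path):
        if fields[0] == "sample_id":
            continue
        if len(fields) < 3:
            raise ParseError(path, lineno, "expected sample_id, chrom, pos")
        try:
            pos = int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer position {fields[2]!r}")
        records.append(
            MutationRecord(
                sample_id=fields[0],
                position=GenomicInterval(normalize_chrom(fields[1]), pos - 1, pos),
            )
        )
    return records


def write_mutations_tsv(mutations: Sequence[MutationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\n")
        for m in mutations:
            fh.write(f"{m.sample_id}\t{m.position.chrom}\t{m.position.start + 1}\n")


def read_cnvs_tsv(path) -> List[CnvRecord]:
    """Read ``sample_id chrom start_1based end direction cohort``."""
    records: List[CnvRecord] = []
    for lineno, fields in _data_lines(path):
        if fields[0] == "sample_id":
            continue
        if len(fields) < 6:
            raise ParseError(path, lineno, "expected 6 CNV columns")
        try:
            start, end = int(fields[2]), int(fields[3])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates")
        records.append(
            CnvRecord(
                sample_id=fields[0],
                span=GenomicInterval(normalize_chrom(fields[1]), start - 1, end),
                direction=fields[4],
                cohort=fields[5],
            )
        )
    return records


def write_cnvs_tsv(cnvs: Sequence[CnvRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tdirection\tcohort\n")
        for c in cnvs:
            fh.write(
                f"{c.sample_id}\t{c.span.chrom}\t{c.span.start + 1}\t{c.span.end}"
                f"\t{c.direction}\t{c.cohort}\n"
            )


def read_interactions_tsv(path, cell_line: str = "") -> List[Interaction]:
    """Read BEDPE-like ``chrom1 start1 end1 chrom2 start2 end2 reads p``."""
    out: List[Interaction] = []
    for lineno, fields in _data_lines(path):
        if fields[0] in ("chrom1", "chr1") and not fields[1].isdigit():
            continue
        if len(fields) < 8:
            raise ParseError(path, lineno, "expected 8 interaction columns")
        try:
            s1, e1 = int(fields[1]), int(fields[2])
            s2, e2 = int(fields[4]), int(fields[5])
            reads = int(fields[6])
            p = float(fields[7])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
        out.append(
            Interaction(
                anchor1=GenomicInterval(normalize_chrom(fields[0]), s1, e1),
                anchor2=GenomicInterval(normalize_chrom(fields[3]), s2, e2),
                read_count=reads,
                p_value=p,
                cell_line=fields[8] if len(fields) > 8 else cell_line,
            )
        )
    return out


def write_interactions_tsv(interactions: Sequence[Interaction], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tread_count\tp_value\n")
        for it in interactions:
            a1, a2 = it.anchor1, it.anchor2
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t{a2.chrom}\t{a2.start}\t{a2.end}"
                f"\t{it.read_count}\t{it.p_value:.6g}\n"
            )


def read_variants_tsv(path) -> List[Variant]:
    """Read ``class chrom start_0based end name`` variant lists (BED-style)."""
    out: List[Variant] = []
    for lineno, fields in _data_lines(path):
        if fields[0] == "class":
            continue
        if len(fields) < 4:
            raise ParseError(path, lineno, "expected class, chrom, start, end")
        try:
            span = GenomicInterval(
                normalize_chrom(fields[1]), int(fields[2]), int(fields[3])
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
        out.append(
            Variant(span=span, vclass=fields[0], name=fields[4] if len(fields) > 4 else "")
        )
    return out


def write_variants_tsv(variants: Sequence[Variant], path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tchrom\tstart\tend\tname\n")
        for v in variants:
            fh.write(
                f"{v.vclass}\t{v.span.chrom}\t{v.span.start}\t{v.span.end}\t{v.name}\n"
            )


def write_vcf_minimal(
    records: Sequence[VcfRecord],
    path,
    chrom_sizes: Optional[ChromSizes] = None,
    sample: str = "SAMPLE",
) -> None:
    """Write the minimal VCF 4.2 dialect the package reads back.

    DP goes into INFO; records with absent DP omit it.  Contig header lines
    are emitted when chromosome sizes are supplied (pysam appreciates them).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        for r in records:
            qual = "." if r.qual is None else f"{r.qual:g}"
            info = "." if r.dp is None else f"DP={r.dp}"
            fh.write(
                f"{r.position.chrom}\t{r.position.start + 1}\t.\t{r.ref}\t{r.alt}"
                f"\t{qual}\t.\t{info}\n"
            )


def read_cnv_segments_bed(path) -> List[Tuple[GenomicInterval, str]]:
    """Read WGS copy-number segments: ``chrom start end direction`` (0-based)."""
    out: List[Tuple[GenomicInterval, str]] = []
    for lineno, fields in _data_lines(path):
        if fields[0] == "chrom":
            continue
        if len(fields) < 4:
            raise ParseError(path, lineno, "expected chrom, start, end, direction")
        try:
            span = GenomicInterval(
                normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
        out.append((span, fields[3]))
    return out


def write_cnv_segments_bed(
    segments: Sequence[Tuple[GenomicInterval, str]], path
) -> None:
    with open(path, "w") as fh:
        for span, direction in segments:
            fh.write(f"{span.chrom}\t{span.start}\t{span.end}\t{direction}\n")
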