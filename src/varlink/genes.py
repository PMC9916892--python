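"""Merged reference gene list and variant-to-gene annotation.

The reference list takes one annotation source as its backbone and fills in
genes absent from it (by case-insensitive symbol) from two further sources in
order of precedence: FANTOM5, then Ensembl, then GENCODE.  Variants are
linked to genes by >= 1 bp overlap with the full annotated gene body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import GenomicInterval, ParseError, intersect, normalize_chrom

__all__ = [
    "GeneRecord",
    "Variant",
    "VariantAnnotation",
    "BIOTYPES",
    "NONCODING_BIOTYPES",
    "build_reference_genes",
    "read_gene_table",
    "write_gene_table",
    "annotate_variants",
    "summarize_annotation",
]

BIOTYPES = frozenset(
    {"protein_coding", "lncRNA", "miRNA", "snoRNA", "pseudogene", "other_ncRNA"}
)
NONCODING_BIOTYPES = BIOTYPES - {"protein_coding"}
SOURCES = ("fantom5", "ensembl", "gencode")


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    span: GenomicInterval
    strand: str
    biotype: str
    source: str
    tss: int = -1  # filled from strand when negative

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.tss < 0:
            object.__setattr__(
                self,
                "tss",
                self.span.start if self.strand == "+" else self.span.end - 1,
            )
        if not (self.span.start <= self.tss < self.span.end):
            raise ValueError("tss must lie inside the gene span")


@dataclass(frozen=True)
class Variant:
    """A variant of any class entering annotation/integration.

    ``vclass`` is one of gwas_snp, hotspot, cnvr_dup, cnvr_del.
    """

    span: GenomicInterval
    vclass: str
    name: str = ""


@dataclass
class VariantAnnotation:
    variant: Variant
    hits: List[GeneRecord]

    @property
    def annotated(self) -> bool:
        return bool(self.hits)


def build_reference_genes(
    fantom: Sequence[GeneRecord],
    ensembl: Sequence[GeneRecord],
    gencode: Sequence[GeneRecord],
) -> List[GeneRecord]:
    """Merge annotation sources with FANTOM5 > Ensembl > GENCODE precedence.

    A gene from a lower-precedence source is added only when its symbol
    (case-insensitive) has not been seen yet; the ``source`` field records
    where each record came from.
    """
    merged: List[GeneRecord] = []
    seen: set = set()
    for source_name, records in zip(SOURCES, (fantom, ensembl, gencode)):
        for gene in records:
            key = gene.symbol.upper()
            if key in seen:
                continue
            seen.add(key)
            if gene.source != source_name:
                gene = GeneRecord(
                    symbol=gene.symbol,
                    span=gene.span,
                    strand=gene.strand,
                    biotype=gene.biotype,
                    source=source_name,
                    tss=gene.tss,
                )
            merged.append(gene)
    return merged


def read_gene_table(path, source: str = "fantom5") -> List[GeneRecord]:
    """Read the BED6+biotype gene TSV: chrom start end symbol biotype strand."""
    genes: List[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno, "gene table needs 6 columns")
            chrom, start, end, symbol, biotype, strand = fields[:6]
            try:
                span = GenomicInterval(normalize_chrom(chrom), int(start), int(end))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
            genes.append(
                GeneRecord(
                    symbol=symbol,
                    span=span,
                    strand=strand,
                    biotype=biotype,
                    source=source,
                )
            )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.span.chrom,
                        str(g.span.start),
                        str(g.span.end),
                        g.symbol,
                        g.biotype,
                        g.strand,
                    ]
                )
                + "\n"
            )


def annotate_variants(
    variants: Sequence[Variant], genes: Sequence[GeneRecord]
) -> List[VariantAnnotation]:
    """Link every variant to the genes it overlaps by >= 1 bp.

    A variant may hit several genes; zero hits marks it non-annotated.
    """
    gene_spans = [g.span for g in genes]
    pairs = intersect([v.span for v in variants], gene_spans)
    hits: Dict[int, List[GeneRecord]] = {}
    for vi, gi, _ov in pairs:
        hits.setdefault(vi, []).append(genes[gi])
    return [
        VariantAnnotation(variant=v, hits=hits.get(i, []))
        for i, v in enumerate(variants)
    ]


def summarize_annotation(annotations: Sequence[VariantAnnotation]) -> Dict[str, Dict]:
    """Per-variant-class summary: annotated fraction, coding vs non-coding,
    and a biotype histogram over distinct hit genes.

    A variant counts as protein-coding-associated if ANY hit gene is protein
    coding (coding wins on mixed hits); the histogram counts each distinct
    gene once per class.
    """
    by_class: Dict[str, List[VariantAnnotation]] = {}
    for ann in annotations:
        by_class.setdefault(ann.variant.vclass, []).append(ann)
    summary: Dict[str, Dict] = {}
    for vclass, anns in by_class.items():
        n = len(anns)
        annotated = [a for a in anns if a.annotated]
        coding = [
            a for a in annotated if any(g.biotype == "protein_coding" for g in a.hits)
        ]
        distinct: Dict[str, GeneRecord] = {}
        for a in annotated:
            for g in a.hits:
                distinct[g.symbol.upper()] = g
        hist: Dict[str, int] = {}
        for g in distinct.values():
            hist[g.biotype] = hist.get(g.biotype, 0) + 1
        summary[vclass] = {
            "n_variants": n,
            "annotated_fraction": len(annotated) / n if n else 0.0,
            "coding_fraction": len(coding) / len(annotated) if annotated else 0.0,
            "noncoding_fraction": (
                (len(annotated) - len(coding)) / len(annotated) if annotated else 0.0
            ),
            "biotype_hist": dict(sorted(hist.items())),
        }
    return summary
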