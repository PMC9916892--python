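"""Cross-referencing variants with condition-specific EPIs.

A variant becomes a regulatory candidate only when it overlaps the ENHANCER
anchor of at least one EPI; promoter-side overlaps never qualify.  Candidates
inherit the union of target genes across their supporting EPIs and can be
flagged as replicated in whole-genome sequencing of a cell line: SNPs by
exact position identity, hotspot windows by containing any WGS SNV, CNV
regions by >= 1 bp overlap with a same-direction copy-number segment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .core import GenomicInterval, VcfRecord, chrom_sort_key
from .epi import Epi
from .genes import GeneRecord, Variant

__all__ = [
    "RegulatoryCandidate",
    "VARIANT_CLASSES",
    "overlap_variants_with_enhancers",
    "vcf_quality_filter",
    "replicate_candidates",
    "report_candidates",
]

VARIANT_CLASSES = ("gwas_snp", "hotspot", "cnvr_dup", "cnvr_del")
_CNV_DIRECTION = {"cnvr_dup": "duplication", "cnvr_del": "deletion"}


@dataclass
class RegulatoryCandidate:
    variant: Variant
    epis: List[Epi]
    target_genes: Set[str]
    host_gene: Optional[str] = None
    replicated_in: Set[str] = field(default_factory=set)


def overlap_variants_with_enhancers(
    variants: Sequence[Variant],
    epis: Sequence[Epi],
    host_genes: Optional[Sequence[GeneRecord]] = None,
) -> List[RegulatoryCandidate]:
    """Candidates = variants overlapping >= 1 EPI enhancer anchor by >= 1 bp.

    Target genes are the union over supporting EPIs.  When ``host_genes`` is
    given, the first gene body containing the variant (e.g. a lncRNA) is
    recorded as the host gene.
    """
    candidates: List[RegulatoryCandidate] = []
    for var in variants:
        support = [e for e in epis if e.enhancer_anchor.overlap_bp(var.span) >= 1]
        if not support:
            continue
        targets: Set[str] = set()
        for e in support:
            targets |= e.target_genes
        host = None
        if host_genes is not None:
            for gene in host_genes:
                if gene.span.overlap_bp(var.span) >= 1:
                    host = gene.symbol
                    break
        candidates.append(
            RegulatoryCandidate(
                variant=var, epis=support, target_genes=targets, host_gene=host
            )
        )
    return candidates


def vcf_quality_filter(
    records: Sequence[VcfRecord], min_qual: float = 30.0, min_dp: int = 10
) -> List[VcfRecord]:
    """Keep records with QUAL > min_qual AND DP > min_dp (both strict).

    Records with absent DP or QUAL are dropped: the removal set is everything
    that cannot demonstrate sufficient confidence and depth.
    """
    return [
        r
        for r in records
        if r.qual is not None
        and r.dp is not None
        and r.qual > min_qual
        and r.dp > min_dp
    ]


def replicate_candidates(
    candidates: Sequence[RegulatoryCandidate],
    wgs_snvs: Sequence[VcfRecord],
    wgs_cnv_segments: Sequence[Tuple[GenomicInterval, str]],
    cell_line: str,
    min_reciprocal_overlap: float = 0.0,
) -> None:
    """Flag candidates replicated by quality-filtered WGS calls of one cell line.

    gwas_snp: a WGS SNV at the identical position (allele-agnostic);
    hotspot: >= 1 WGS SNV inside the window; cnvr_dup/cnvr_del: a
    same-direction segment overlapping by >= 1 bp and, when
    ``min_reciprocal_overlap`` > 0, by that fraction of both spans.
    """
    snv_positions = {(r.position.chrom, r.position.start) for r in wgs_snvs}
    for cand in candidates:
        span = cand.variant.span
        vclass = cand.variant.vclass
        hit = False
        if vclass == "gwas_snp":
            hit = (span.chrom, span.start) in snv_positions
        elif vclass == "hotspot":
            hit = any(
                r.position.chrom == span.chrom
                and span.start <= r.position.start < span.end
                for r in wgs_snvs
            )
        elif vclass in _CNV_DIRECTION:
            want = _CNV_DIRECTION[vclass]
            for seg, direction in wgs_cnv_segments:
                if direction != want:
                    continue
                ov = seg.overlap_bp(span)
                if ov >= 1 and (
                    min_reciprocal_overlap <= 0.0
                    or (
                        ov >= min_reciprocal_overlap * span.width
                        and ov >= min_reciprocal_overlap * seg.width
                    )
                ):
                    hit = True
                    break
        else:
            raise ValueError(f"unknown variant class {vclass!r}")
        if hit:
            cand.replicated_in.add(cell_line)


def report_candidates(
    candidates: Sequence[RegulatoryCandidate],
) -> Tuple[str, str, Dict]:
    """Deterministic candidate report.

    Returns (report_tsv, gene_index_tsv, summary).  Rows are ordered by
    variant class, chromosome, start -- byte-identical regardless of input
    order.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (
            c.variant.vclass,
            chrom_sort_key(c.variant.span.chrom),
            c.variant.span.start,
            c.variant.span.end,
            c.variant.name,
        ),
    )
    report = io.StringIO()
    report.write(
        "class\tchrom\tstart\tend\tname\tn_epis\ttarget_genes\thost_gene\treplicated_in\n"
    )
    gene_index: Dict[str, List[str]] = {}
    per_class: Dict[str, int] = {}
    per_cell_line: Dict[str, int] = {}
    for cand in ordered:
        v = cand.variant
        per_class[v.vclass] = per_class.get(v.vclass, 0) + 1
        for cl in cand.replicated_in:
            per_cell_line[cl] = per_cell_line.get(cl, 0) + 1
        label = v.name or str(v.span)
        report.write(
            "\t".join(
                [
                    v.vclass,
                    v.span.chrom,
                    str(v.span.start),
                    str(v.span.end),
                    label,
                    str(len(cand.epis)),
                    ";".join(sorted(cand.target_genes)),
                    cand.host_gene or ".",
                    ";".join(sorted(cand.replicated_in)) or ".",
                ]
            )
            + "\n"
        )
        for gene in cand.target_genes:
            gene_index.setdefault(gene, []).append(label)
    index = io.StringIO()
    index.write("gene\tn_candidates\tcandidates\n")
    for gene in sorted(gene_index):
        entries = sorted(gene_index[gene])
        index.write(f"{gene}\t{len(entries)}\t{';'.join(entries)}\n")
    summary = {
        "n_candidates": len(ordered),
        "per_class": dict(sorted(per_class.items())),
        "per_cell_line": dict(sorted(per_cell_line.items())),
        "n_target_genes": len(gene_index),
    }
    return report.getvalue(), index.getvalue(), summary
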