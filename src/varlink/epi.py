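"""Enhancer-promoter interaction (EPI) calling from significant Hi-C pairs.

Significant cis interactions (fixed bin size, default 5 kb) are filtered on
p-value, read support, and anchor distance; replicates are merged by bin
pair.  An interaction becomes an EPI when one anchor overlaps an H3K27ac
peak (the enhancer side) and the other anchor overlaps the promoter of a
protein-coding gene (the promoter side); both orientations may qualify
independently.  Condition-specific EPIs are those whose bin pair is absent
from the comparison condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .core import ChromSizes, GenomicInterval, chrom_sort_key
from .genes import GeneRecord

__all__ = [
    "Interaction",
    "Epi",
    "PromoterRegion",
    "filter_interactions",
    "merge_replicates",
    "annotate_anchor_genes",
    "promoter_regions",
    "call_epis",
    "condition_specific_epis",
]


def _anchor_key(iv: GenomicInterval) -> Tuple:
    return (chrom_sort_key(iv.chrom), iv.start)


@dataclass(frozen=True)
class Interaction:
    """A Hi-C bin pair; anchors are stored sorted (chrom, then start)."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    read_count: int
    p_value: float
    cell_line: str = ""
    replicate_merged: bool = False

    def __post_init__(self):
        if self.anchor1.width != self.anchor2.width:
            raise ValueError("both anchors must share one bin width")
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if _anchor_key(self.anchor1) > _anchor_key(self.anchor2):
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)

    @property
    def bin_width(self) -> int:
        return self.anchor1.width

    @property
    def is_cis(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def distance(self) -> Optional[int]:
        """Anchor start-coordinate separation; None for trans pairs."""
        if not self.is_cis:
            return None
        return abs(self.anchor2.start - self.anchor1.start)

    def bin_pair(self) -> Tuple[str, int, int, str, int, int]:
        a1, a2 = self.anchor1, self.anchor2
        return (a1.chrom, a1.start, a1.end, a2.chrom, a2.start, a2.end)


@dataclass(frozen=True)
class PromoterRegion:
    span: GenomicInterval
    symbol: str


@dataclass(frozen=True)
class Epi:
    """An interaction with enhancer/promoter roles assigned to its anchors."""

    interaction: Interaction
    enhancer_side: int  # 1 or 2
    promoter_side: int
    target_genes: FrozenSet[str]
    enhancer_peaks: Tuple[GenomicInterval, ...]

    def __post_init__(self):
        if {self.enhancer_side, self.promoter_side} != {1, 2}:
            raise ValueError("enhancer and promoter must be opposite anchors")
        if not self.target_genes:
            raise ValueError("an EPI must have at least one target gene")

    @property
    def enhancer_anchor(self) -> GenomicInterval:
        return (
            self.interaction.anchor1
            if self.enhancer_side == 1
            else self.interaction.anchor2
        )

    @property
    def promoter_anchor(self) -> GenomicInterval:
        return (
            self.interaction.anchor1
            if self.promoter_side == 1
            else self.interaction.anchor2
        )


def filter_interactions(
    interactions: Sequence[Interaction],
    p_max: float = 0.01,
    min_reads: int = 10,
    min_dist: int = 5_000,
    max_dist: int = 10_000_000,
) -> List[Interaction]:
    """Keep cis pairs with p < p_max, read_count >= min_reads, and anchor
    distance strictly between min_dist and max_dist.  Idempotent."""
    out = []
    for it in interactions:
        if not it.is_cis:
            continue
        if not (it.p_value < p_max and it.read_count >= min_reads):
            continue
        if min_dist < it.distance < max_dist:
            out.append(it)
    return out


def merge_replicates(
    rep1: Sequence[Interaction], rep2: Sequence[Interaction]
) -> List[Interaction]:
    """Union of two replicates by bin pair: read counts summed, p-value the
    minimum of those available, merged records flagged."""
    widths = {it.bin_width for it in list(rep1) + list(rep2)}
    if len(widths) > 1:
        raise ValueError(f"bin-width mismatch between replicates: {sorted(widths)}")
    merged: Dict[Tuple, Interaction] = {}
    for it in list(rep1) + list(rep2):
        key = it.bin_pair()
        prev = merged.get(key)
        if prev is None:
            merged[key] = it
        else:
            merged[key] = Interaction(
                anchor1=it.anchor1,
                anchor2=it.anchor2,
                read_count=prev.read_count + it.read_count,
                p_value=min(prev.p_value, it.p_value),
                cell_line=prev.cell_line or it.cell_line,
                replicate_merged=True,
            )
    return [merged[k] for k in sorted(merged)]


def annotate_anchor_genes(
    interactions: Sequence[Interaction],
    genes: Sequence[GeneRecord],
    min_frac: float = 0.10,
) -> Dict[Tuple[str, int, int], Set[str]]:
    """Map each distinct anchor to the genes overlapping it by >= min_frac of
    min(gene width, anchor width) -- short genes and bins are treated
    symmetrically."""
    anchors: Dict[Tuple[str, int, int], GenomicInterval] = {}
    for it in interactions:
        for anchor in (it.anchor1, it.anchor2):
            anchors[(anchor.chrom, anchor.start, anchor.end)] = anchor
    out: Dict[Tuple[str, int, int], Set[str]] = {key: set() for key in anchors}
    for key, anchor in anchors.items():
        for gene in genes:
            ov = anchor.overlap_bp(gene.span)
            if ov >= min_frac * min(gene.span.width, anchor.width):
                if ov >= 1:
                    out[key].add(gene.symbol)
    return out


def promoter_regions(
    genes: Sequence[GeneRecord],
    upstream: int = 2_000,
    downstream: int = 2_000,
    chrom_sizes: Optional[ChromSizes] = None,
) -> List[PromoterRegion]:
    """Strand-aware TSS windows for protein-coding genes, clipped to
    chromosome bounds.

    '+' strand: [tss - upstream, tss + downstream); '-' strand (tss at
    end - 1): [tss - downstream, tss + upstream + 1), i.e. the mirrored
    window around the TSS base.
    """
    promoters: List[PromoterRegion] = []
    for gene in genes:
        if gene.biotype != "protein_coding":
            continue
        if gene.strand == "+":
            start, end = gene.tss - upstream, gene.tss + downstream
        else:
            start, end = gene.tss - downstream, gene.tss + upstream + 1
        start = max(0, start)
        if chrom_sizes and gene.span.chrom in chrom_sizes:
            end = min(end, chrom_sizes[gene.span.chrom])
        if end > start:
            promoters.append(
                PromoterRegion(
                    span=GenomicInterval(gene.span.chrom, start, end),
                    symbol=gene.symbol,
                )
            )
    return promoters


def call_epis(
    interactions: Sequence[Interaction],
    peaks: Sequence[GenomicInterval],
    promoters: Sequence[PromoterRegion],
) -> List[Epi]:
    """Emit an EPI for every (interaction, orientation) where the enhancer
    anchor overlaps >= 1 peak (>= 1 bp) and the promoter anchor overlaps >= 1
    promoter.  Both orientations of one interaction may be emitted; target
    genes are collected from all overlapping promoters."""
    epis: List[Epi] = []
    for it in interactions:
        sides = {1: it.anchor1, 2: it.anchor2}
        peak_hits = {
            side: tuple(p for p in peaks if anchor.overlap_bp(p) >= 1)
            for side, anchor in sides.items()
        }
        prom_hits = {
            side: frozenset(
                pr.symbol for pr in promoters if anchor.overlap_bp(pr.span) >= 1
            )
            for side, anchor in sides.items()
        }
        for enh, prom in ((1, 2), (2, 1)):
            if peak_hits[enh] and prom_hits[prom]:
                epis.append(
                    Epi(
                        interaction=it,
                        enhancer_side=enh,
                        promoter_side=prom,
                        target_genes=prom_hits[prom],
                        enhancer_peaks=peak_hits[enh],
                    )
                )
    return epis


def condition_specific_epis(cancer: Sequence[Epi], normal: Sequence[Epi]) -> List[Epi]:
    """EPIs of the first condition whose bin pair never occurs among the
    second condition's EPIs.  Identity is the exact bin-pair coordinates;
    differing target genes on the same pair do not rescue it."""
    widths = {e.interaction.bin_width for e in list(cancer) + list(normal)}
    if len(widths) > 1:
        raise ValueError(f"bin-width mismatch between conditions: {sorted(widths)}")
    normal_pairs = {e.interaction.bin_pair() for e in normal}
    return [e for e in cancer if e.interaction.bin_pair() not in normal_pairs]
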