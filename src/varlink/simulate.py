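"""Seeded synthetic fixtures with planted ground truth.

Every input the pipeline consumes can be generated here on a toy genome
(default: two 1 Mb chromosomes, 5 kb Hi-C bins), with known signals planted
on top of uniform background so each stage has a machine-checkable truth:

* mutation cohorts with a planted recurrent window (hotspot stage),
* case/control CNV cohorts with a planted case-enriched region,
* a regulatory scenario where condition-specific enhancer-promoter
  interactions, enhancer-side variants, promoter-side distractors, and WGS
  replication status are all constructed by design.

Background mutations are placed uniformly, matching the assumption of the
Poisson-binomial hotspot null, so type-I-error checks against the generator
are well-posed.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ChromSizes,
    CnvRecord,
    GenomicInterval,
    MutationRecord,
    VcfRecord,
)
from .epi import Interaction, PromoterRegion, promoter_regions
from .genes import GeneRecord, Variant

__all__ = [
    "FixtureSpec",
    "ScenarioData",
    "simulate_mutations",
    "simulate_cnvs",
    "simulate_regulatory_scenario",
    "write_fixture_files",
]


def _default_chrom_sizes() -> ChromSizes:
    return {"chr1": 1_000_000, "chr2": 1_000_000}


def _default_hotspots() -> List[Tuple[GenomicInterval, float]]:
    # 21 bp tile-aligned window mid-chr1 (499989 = 21 * 23809), 30% carriage
    return [(GenomicInterval("chr1", 499_989, 500_010), 0.30)]


def _default_cnvrs() -> List[Tuple[GenomicInterval, str, float, float]]:
    # case-enriched duplication: 20/30 cases, 1/30 controls
    return [(GenomicInterval("chr2", 300_000, 320_000), "duplication", 20 / 30, 1 / 30)]


@dataclass
class FixtureSpec:
    """Generator settings; the defaults are the package's study conditions."""

    seed: int = 0
    chrom_sizes: ChromSizes = field(default_factory=_default_chrom_sizes)

    # mutation cohort (hotspot stage)
    n_mutation_samples: int = 100
    background_mutation_rate: float = 50.0  # expected mutations per sample
    planted_hotspots: List[Tuple[GenomicInterval, float]] = field(
        default_factory=_default_hotspots
    )

    # CNV cohorts (association stage)
    n_case_samples: int = 30
    n_control_samples: int = 30
    cnv_background_per_sample: float = 0.0  # noise-free breakpoints by default
    cnv_background_length: Tuple[int, int] = (10_000, 50_000)
    breakpoint_jitter_sd: float = 0.0
    planted_cnvrs: List[Tuple[GenomicInterval, str, float, float]] = field(
        default_factory=_default_cnvrs
    )

    # regulatory scenario
    bin_size: int = 5_000
    planted_replication: Tuple[bool, ...] = (True, False)

    def __post_init__(self):
        for _, frac in self.planted_hotspots:
            if not (0.0 <= frac <= 1.0):
                raise ValueError("carrier fractions must be in [0, 1]")
        for span, direction, f_case, f_ctrl in self.planted_cnvrs:
            if not (0.0 <= f_case <= 1.0 and 0.0 <= f_ctrl <= 1.0):
                raise ValueError("carrier fractions must be in [0, 1]")
            if span.end > self.chrom_sizes.get(span.chrom, 0):
                raise ValueError(f"planted span {span} outside chromosome bounds")
        for span, _ in self.planted_hotspots:
            if span.end > self.chrom_sizes.get(span.chrom, 0):
                raise ValueError(f"planted span {span} outside chromosome bounds")


def _uniform_positions(rng, chrom_sizes: ChromSizes, n: int) -> List[Tuple[str, int]]:
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    offsets = rng.integers(0, sizes.sum(), size=n)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    idx = np.searchsorted(bounds, offsets, side="right") - 1
    return [(chroms[i], int(offsets[j] - bounds[i])) for j, i in enumerate(idx)]


def simulate_mutations(
    spec: FixtureSpec,
) -> Tuple[List[MutationRecord], Dict]:
    """Uniform background mutations plus planted recurrent windows.

    Each sample draws Poisson(background rate) uniform positions; for every
    planted window each sample independently contributes one mutation inside
    it with the stated carrier fraction.  Truth records the planted windows
    and their carriers.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i:03d}" for i in range(spec.n_mutation_samples)]
    mutations: List[MutationRecord] = []
    for sample in samples:
        n_bg = int(rng.poisson(spec.background_mutation_rate))
        for chrom, pos in _uniform_positions(rng, spec.chrom_sizes, n_bg):
            mutations.append(
                MutationRecord(sample, GenomicInterval(chrom, pos, pos + 1))
            )
    truth_windows = []
    for span, frac in spec.planted_hotspots:
        carriers = []
        for sample in samples:
            if rng.random() < frac:
                pos = int(rng.integers(span.start, span.end))
                mutations.append(
                    MutationRecord(sample, GenomicInterval(span.chrom, pos, pos + 1))
                )
                carriers.append(sample)
        truth_windows.append(
            {"span": str(span), "carrier_fraction": frac, "carriers": carriers}
        )
    truth = {"planted_hotspots": truth_windows, "samples": samples}
    return mutations, truth


def simulate_cnvs(spec: FixtureSpec) -> Tuple[List[CnvRecord], Dict]:
    """Background CNVs in both cohorts plus planted case-enriched regions.

    Planted regions are carried by round(fraction x cohort size) samples with
    identical breakpoints, or jittered ones when ``breakpoint_jitter_sd`` > 0.
    """
    rng = np.random.default_rng(spec.seed + 1)
    cohorts = {
        "case": [f"CASE{i:03d}" for i in range(spec.n_case_samples)],
        "control": [f"CTRL{i:03d}" for i in range(spec.n_control_samples)],
    }
    records: List[CnvRecord] = []
    lo, hi = spec.cnv_background_length
    for cohort, samples in cohorts.items():
        for sample in samples:
            n_bg = int(rng.poisson(spec.cnv_background_per_sample))
            for _ in range(n_bg):
                chrom = sorted(spec.chrom_sizes)[
                    int(rng.integers(0, len(spec.chrom_sizes)))
                ]
                length = int(rng.integers(lo, hi + 1))
                size = spec.chrom_sizes[chrom]
                start = int(rng.integers(0, max(1, size - length)))
                direction = ["deletion", "duplication"][int(rng.integers(0, 2))]
                records.append(
                    CnvRecord(
                        sample,
                        GenomicInterval(chrom, start, start + length),
                        direction,
                        cohort,
                    )
                )
    truth_regions = []
    for span, direction, f_case, f_ctrl in spec.planted_cnvrs:
        carriers: Dict[str, List[str]] = {}
        for cohort, frac in (("case", f_case), ("control", f_ctrl)):
            samples = cohorts[cohort]
            n_carry = int(round(frac * len(samples)))
            chosen = sorted(
                rng.choice(len(samples), size=n_carry, replace=False).tolist()
            )
            carriers[cohort] = [samples[i] for i in chosen]
            for sample in carriers[cohort]:
                start, end = span.start, span.end
                if spec.breakpoint_jitter_sd > 0:
                    start = max(
                        0, start + int(round(rng.normal(0, spec.breakpoint_jitter_sd)))
                    )
                    end = min(
                        spec.chrom_sizes[span.chrom],
                        end + int(round(rng.normal(0, spec.breakpoint_jitter_sd))),
                    )
                records.append(
                    CnvRecord(
                        sample,
                        GenomicInterval(span.chrom, start, end),
                        direction,
                        cohort,
                    )
                )
        truth_regions.append(
            {
                "span": str(span),
                "direction": direction,
                "case_carriers": carriers["case"],
                "control_carriers": carriers["control"],
            }
        )
    truth = {
        "planted_cnvrs": truth_regions,
        "case_samples": cohorts["case"],
        "control_samples": cohorts["control"],
    }
    return records, truth


@dataclass
class ScenarioData:
    """All inputs of the regulatory-integration stage plus the planted truth."""

    genes: List[GeneRecord]
    promoters: List[PromoterRegion]
    peaks: List[GenomicInterval]
    interactions: Dict[str, List[Interaction]]  # condition -> interactions
    variants: List[Variant]
    wgs_snvs: List[VcfRecord]
    wgs_cnv_segments: List[Tuple[GenomicInterval, str]]
    cell_line: str
    truth: Dict


def simulate_regulatory_scenario(spec: FixtureSpec) -> ScenarioData:
    """A fully constructed toy regulatory landscape.

    Two enhancer-promoter interactions exist only in the cancer condition;
    one planted variant sits in each of their enhancer bins (one SNP inside a
    lncRNA body, one deleted CNV region).  Distractor variants sit in a
    promoter bin, in intergenic space, and in the enhancer bin of a shared
    (non-specific) interaction.  WGS calls replicate the planted variants
    according to ``spec.planted_replication``.
    """
    b = spec.bin_size

    def bin_at(chrom: str, start: int) -> GenomicInterval:
        return GenomicInterval(chrom, start, start + b)

    genes = [
        GeneRecord("TARGETA", GenomicInterval("chr1", 200_000, 210_000), "+", "protein_coding", "fantom5"),
        GeneRecord("TARGETB", GenomicInterval("chr1", 400_000, 412_000), "-", "protein_coding", "fantom5"),
        GeneRecord("TARGETC", GenomicInterval("chr2", 200_000, 210_000), "+", "protein_coding", "fantom5"),
        GeneRecord("FILLER1", GenomicInterval("chr2", 600_000, 610_000), "+", "protein_coding", "ensembl"),
        GeneRecord("LNC1", GenomicInterval("chr1", 100_000, 103_000), "+", "lncRNA", "fantom5"),
        GeneRecord("LNC2", GenomicInterval("chr2", 700_000, 702_000), "-", "lncRNA", "gencode"),
    ]
    promoters = promoter_regions(genes, chrom_sizes=spec.chrom_sizes)

    peaks = [
        GenomicInterval("chr1", 101_000, 102_000),
        GenomicInterval("chr1", 301_000, 301_600),
        GenomicInterval("chr2", 101_000, 101_800),
        GenomicInterval("chr1", 650_000, 650_500),  # peak with no interaction
    ]

    cancer_specific = [
        # enhancer bin over the LNC1 body / peak -> promoter bin of TARGETA
        Interaction(bin_at("chr1", 100_000), bin_at("chr1", 200_000), 25, 1e-4, "tumorA"),
        # enhancer bin with peak -> promoter bin of TARGETB (minus strand)
        Interaction(bin_at("chr1", 300_000), bin_at("chr1", 410_000), 30, 5e-4, "tumorA"),
    ]
    shared = Interaction(bin_at("chr2", 100_000), bin_at("chr2", 200_000), 40, 1e-5, "tumorA")
    rejected = [
        Interaction(bin_at("chr1", 500_000), bin_at("chr1", 505_000), 50, 1e-5, "tumorA"),  # distance = bin size
        Interaction(bin_at("chr1", 100_000), bin_at("chr1", 700_000), 5, 1e-5, "tumorA"),  # low reads
        Interaction(bin_at("chr1", 100_000), bin_at("chr2", 200_000), 50, 1e-5, "tumorA"),  # trans
        Interaction(bin_at("chr1", 100_000), bin_at("chr1", 400_000), 50, 0.5, "tumorA"),  # weak p
    ]
    interactions = {
        "cancer": cancer_specific + [shared] + rejected,
        "normal": [
            Interaction(shared.anchor1, shared.anchor2, 35, 2e-5, "normalA"),
            Interaction(bin_at("chr2", 400_000, ), bin_at("chr2", 600_000), 20, 1e-3, "normalA"),
        ],
    }

    variants = [
        Variant(GenomicInterval("chr1", 101_500, 101_501), "gwas_snp", "rs0001"),
        Variant(GenomicInterval("chr1", 299_000, 306_000), "cnvr_del", "cnvrdel1"),
        # distractors: promoter bin, intergenic, shared-interaction enhancer bin
        Variant(GenomicInterval("chr1", 201_000, 201_001), "gwas_snp", "rsdist1"),
        Variant(GenomicInterval("chr1", 700_000, 700_021), "hotspot", "hotdist1"),
        Variant(GenomicInterval("chr2", 101_500, 101_501), "gwas_snp", "rsdist2"),
    ]

    wgs_snvs: List[VcfRecord] = []
    wgs_cnv_segments: List[Tuple[GenomicInterval, str]] = []
    if spec.planted_replication[0]:
        wgs_snvs.append(
            VcfRecord(GenomicInterval("chr1", 101_500, 101_501), "A", "T", 60.0, 30)
        )
    if len(spec.planted_replication) > 1 and spec.planted_replication[1]:
        wgs_cnv_segments.append(
            (GenomicInterval("chr1", 298_000, 310_000), "deletion")
        )
    # calls that must NOT replicate anything: low quality, and a
    # direction-mismatched copy-number segment over the planted deletion
    wgs_snvs.append(
        VcfRecord(GenomicInterval("chr1", 700_010, 700_011), "G", "C", 10.0, 5)
    )
    wgs_cnv_segments.append((GenomicInterval("chr1", 298_000, 310_000), "duplication"))

    truth = {
        "cell_line": "tumorA",
        "expected_candidates": [
            {
                "name": "rs0001",
                "vclass": "gwas_snp",
                "target_genes": ["TARGETA"],
                "host_gene": "LNC1",
                "replicated": bool(spec.planted_replication[0]),
            },
            {
                "name": "cnvrdel1",
                "vclass": "cnvr_del",
                "target_genes": ["TARGETB"],
                "host_gene": None,
                "replicated": bool(
                    len(spec.planted_replication) > 1 and spec.planted_replication[1]
                ),
            },
        ],
        "distractors": ["rsdist1", "hotdist1", "rsdist2"],
    }
    return ScenarioData(
        genes=genes,
        promoters=promoters,
        peaks=peaks,
        interactions=interactions,
        variants=variants,
        wgs_snvs=wgs_snvs,
        wgs_cnv_segments=wgs_cnv_segments,
        cell_line="tumorA",
        truth=truth,
    )


def write_fixture_files(spec: FixtureSpec, outdir) -> Dict[str, str]:
    """Generate every fixture and write it in the dialects the pipeline reads.

    Returns a name -> path mapping; a ``truth.json`` manifest with all
    planted signals is written alongside.  Byte-identical under a fixed seed.
    """
    from . import tables
    from .core import write_bed, write_gmt
    from .genes import write_gene_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    mutations, mut_truth = simulate_mutations(spec)
    cnvs, cnv_truth = simulate_cnvs(spec)
    scenario = simulate_regulatory_scenario(spec)

    paths: Dict[str, str] = {}

    def _save(name: str, filename: str, writer) -> None:
        path = out / filename
        writer(path)
        paths[name] = str(path)

    _save("chrom_sizes", "chrom.sizes", lambda p: Path(p).write_text(
        "".join(f"{c}\t{s}\n" for c, s in sorted(spec.chrom_sizes.items()))
    ))
    _save("mutations", "mutations.tsv", lambda p: tables.write_mutations_tsv(mutations, p))
    _save("cnvs", "cnvs.tsv", lambda p: tables.write_cnvs_tsv(cnvs, p))
    _save("genes", "genes.tsv", lambda p: write_gene_table(scenario.genes, p))
    _save("peaks", "peaks.bed", lambda p: write_bed(scenario.peaks, p))
    _save(
        "interactions_cancer",
        "interactions_cancer.tsv",
        lambda p: tables.write_interactions_tsv(scenario.interactions["cancer"], p),
    )
    _save(
        "interactions_normal",
        "interactions_normal.tsv",
        lambda p: tables.write_interactions_tsv(scenario.interactions["normal"], p),
    )
    _save("variants", "variants.tsv", lambda p: tables.write_variants_tsv(scenario.variants, p))
    _save(
        "wgs_vcf",
        "wgs.vcf",
        lambda p: tables.write_vcf_minimal(scenario.wgs_snvs, p, spec.chrom_sizes),
    )
    _save(
        "wgs_cnv",
        "wgs_cnv_segments.bed",
        lambda p: tables.write_cnv_segments_bed(scenario.wgs_cnv_segments, p),
    )

    gwas_rows = [
        ("rs0001", "chr1", 101_501, 1e-9),
        ("rsdist1", "chr1", 201_001, 1e-9),
        ("rsdist2", "chr2", 101_501, 1e-9),
        ("rsweak", "chr1", 900_001, 1e-5),  # below genome-wide significance
    ]
    _save("gwas", "gwas.tsv", lambda p: Path(p).write_text(
        "rsid\tchrom\tpos\tpvalue\n"
        + "".join(f"{r}\t{c}\t{pos}\t{pv:.6g}\n" for r, c, pos, pv in gwas_rows)
    ))

    gene_sets = [
        ("SET_TARGETS", "planted targets", ["TARGETA", "TARGETB"]),
        ("SET_CHR2", "chr2 genes", ["TARGETC", "FILLER1"]),
        ("SET_ALLCODING", "all coding", ["TARGETA", "TARGETB", "TARGETC", "FILLER1"]),
        # widens the universe so the planted-target set can reach significance
        ("SET_BACKGROUND", "universe padding", [f"BG{i}" for i in range(1, 7)]),
    ]
    _save("gene_sets", "gene_sets.gmt", lambda p: write_gmt(gene_sets, p))

    truth = {
        "seed": spec.seed,
        "mutations": mut_truth,
        "cnvs": cnv_truth,
        "regulatory": scenario.truth,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    paths["truth"] = str(truth_path)
    return paths
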