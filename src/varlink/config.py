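"""Pipeline configuration: every tunable threshold in one place.

Defaults are the values the method is normally run with: 21 bp hotspot
windows selected at p < 0.001, per-base CNV association at p < 0.05,
Hi-C interactions at p < 0.01 with >= 10 reads and 5 kb - 10 Mb anchor
separation, 10% anchor-gene overlap, genome-wide GWAS significance 5e-8,
WGS call filter QUAL > 30 and DP > 10, and an enrichment report cutoff of
0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0

    # hotspot stage
    window_w: int = 21
    hotspot_alpha: float = 0.001
    hotspot_min_k: int = 1
    hotspot_bonferroni: bool = False
    sweep_sizes: Tuple[int, ...] = (9, 21, 50, 5000)

    # CNVR stage
    cnvr_p_threshold: float = 0.05
    dbscan_eps: float = 0.5
    dbscan_min_pts: int = 1

    # interaction / EPI stage
    interaction_p_max: float = 0.01
    interaction_min_reads: int = 10
    interaction_min_dist: int = 5_000
    interaction_max_dist: int = 10_000_000
    anchor_gene_min_frac: float = 0.10
    promoter_upstream: int = 2_000
    promoter_downstream: int = 2_000

    # GWAS / WGS
    gwas_p_threshold: float = 5e-8
    vcf_min_qual: float = 30.0
    vcf_min_dp: int = 10
    cnv_min_reciprocal_overlap: float = 0.0

    # enrichment
    enrichment_max_p: float = 0.05

    def validate(self) -> None:
        positive = {
            "window_w": self.window_w,
            "interaction_min_reads": self.interaction_min_reads,
            "dbscan_eps": self.dbscan_eps,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"config field {name} must be > 0, got {value}")
        for name in ("hotspot_alpha", "cnvr_p_threshold", "interaction_p_max",
                     "enrichment_max_p"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"config field {name} must be in (0, 1], got {value}")
        if not (0.0 <= self.anchor_gene_min_frac <= 1.0):
            raise ValueError("config field anchor_gene_min_frac must be in [0, 1]")
        if self.interaction_min_dist >= self.interaction_max_dist:
            raise ValueError(
                "config field interaction_min_dist must be < interaction_max_dist"
            )

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["sweep_sizes"] = list(self.sweep_sizes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "sweep_sizes" in data:
            data["sweep_sizes"] = tuple(data["sweep_sizes"])
        cfg = cls(**data)
        cfg.validate()
        return cfg
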