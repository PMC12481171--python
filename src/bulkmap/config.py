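"""Run-time configuration objects for the simulator and the pipeline.

The simulator defaults describe a biparental F2 seed-weight mapping design:
two inbred parents fixed for alternative alleles, an F2 of 341 selfed
progeny, extreme-phenotype bulks of 30 plants each, and pooled whole-genome
sequencing at roughly 23-29x per library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = ["SimConfig", "RoleMap", "RunConfig", "DEFAULT_ROLES", "stage_rng"]

# Stable sub-stream ids so each simulation stage draws from its own
# deterministic generator derived from the single user seed.
_STAGE_IDS = {
    "population": 1,
    "variant_map": 2,
    "pool_reads": 3,
    "expression": 4,
    "gene_models": 5,
    "promoter": 6,
    "reference": 7,
    "null_ci": 8,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one integer seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGE_IDS[stage])))


@dataclass
class SimConfig:
    """Parameters of the synthetic F2 pooled-sequencing study.

    Depth defaults follow the design the pipeline targets: large-seed pool
    29x, small-seed pool 28x, mutant parent (P2) 23x, reference parent (P1)
    28x.  Trait means are thousand-seed weights in grams (P1 large-seeded,
    P2 small-seeded); QTL effects are grams per P2 allele.
    """

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"A09": 10_000_000, "A06": 10_000_000}
    )
    n_snps: int = 2000
    n_indels: int = 800
    # (chrom, position bp, additive effect in grams per P2 allele)
    qtls: list = field(default_factory=lambda: [("A09", 5_500_000, -1.15)])
    trait_mean_P1: float = 4.9
    trait_mean_P2: float = 2.6
    env_sd: float = 0.5
    pop_size: int = 341
    bulk_size: int = 30
    depth_aa: float = 28.0  # small-seed pool
    depth_ab: float = 29.0  # large-seed pool
    depth_P1: float = 28.0
    depth_P2: float = 23.0
    cm_per_mb: float = 2.0
    seq_error: float = 0.001
    # expression simulation
    n_genes: int = 2000
    n_de_genes: int = 150
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_reps: int = 3
    # promoter simulation
    promoter_len: int = 1500
    promoter_n_snps: int = 16
    promoter_n_indels: int = 5
    promoter_n_motif_disruptions: int = 2

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if 2 * self.bulk_size > self.pop_size:
            raise ValueError("bulk_size*2 must not exceed pop_size")
        for chrom, pos, eff in self.qtls:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"QTL chromosome {chrom!r} not in chrom_lengths")
            if not (0 <= pos < self.chrom_lengths[chrom]):
                raise ValueError(f"QTL position {pos} outside chromosome {chrom}")
            if not math.isfinite(eff):
                raise ValueError("QTL effects must be finite")
        for name in ("depth_aa", "depth_ab", "depth_P1", "depth_P2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must not exceed n_genes")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "qtls" in d:
            d["qtls"] = [tuple(q) for q in d["qtls"]]
        return cls(**d)


#: Which VCF sample plays which role in the index formulas.  ``P`` and ``M``
#: are the two parents; ``aa`` is the small-seed pool and ``ab`` the
#: large-seed pool.  The index is the fraction of pool reads carrying the
#: M-parent allele, so with M = the small-seeded mutant the Δ-index peaks
#: positive at loci where small-seed alleles are enriched in the small pool.
DEFAULT_ROLES = {"P": "P1", "M": "P2", "aa": "bulk_small", "ab": "bulk_large"}


@dataclass
class RoleMap:
    P: str = "P1"
    M: str = "P2"
    aa: str = "bulk_small"
    ab: str = "bulk_large"

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**{k: str(v) for k, v in d.items()})

    def as_dict(self) -> dict:
        return {"P": self.P, "M": self.M, "aa": self.aa, "ab": self.ab}


@dataclass
class RunConfig:
    """End-to-end pipeline run description (YAML-serialisable)."""

    seed: int = 0
    out_dir: str = "bulkmap_run"
    stages: list = field(
        default_factory=lambda: [
            "simulate",
            "bsa",
            "annotate",
            "de",
            "triage",
            "promoter",
        ]
    )
    sim: dict = field(default_factory=dict)
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    min_sites: int = 10
    conf: float = 0.99
    loess_span: float = 0.1
    n_null_sims: int = 20_000
    upstream_bp: int = 2000
    fdr: float = 0.01
    lfc: float = 1.0
    write_reference: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def sim_config(self) -> SimConfig:
        d = dict(self.sim)
        d.setdefault("seed", self.seed)
        return SimConfig.from_dict(d)
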