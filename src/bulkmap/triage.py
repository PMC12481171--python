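"""Candidate-gene funnel: region genes -> region DEGs -> mutation carriers.

Stage 1 collects genes overlapping the called candidate regions; stage 2
keeps those flagged differentially expressed; stage 3 keeps those that
additionally carry at least one qualifying parent-differentiating variant
(by default frameshift, nonsynonymous or upstream).  Candidates are then
ranked: genes whose only qualifying variants are regulatory (upstream)
*and* that show a strong expression difference head the list — the
signature of a promoter-driven expression change — followed by effect on
|log2FC| (descending) and FDR (ascending).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .effects import GeneModel, genes_in_regions

__all__ = ["TriageReport", "triage", "rank_candidates", "QUALIFYING_EFFECTS"]

QUALIFYING_EFFECTS = frozenset({"frameshift", "nonsynonymous", "upstream"})


@dataclass
class TriageReport:
    region_genes: list
    region_degs: list
    candidates: pd.DataFrame  # gene_id, chrom, start, effects, log2fc, fdr
    counts: dict


def triage(
    regions: pd.DataFrame,
    genes: Sequence[GeneModel],
    de_results: pd.DataFrame,
    effects: pd.DataFrame,
    qualifying: frozenset = QUALIFYING_EFFECTS,
    max_id_mismatch: float = 0.5,
) -> TriageReport:
    """Run the three-stage candidate funnel; stage counts are monotone."""
    gene_ids = {g.gene_id for g in genes}
    if len(de_results) and gene_ids:
        known = de_results.index.isin(gene_ids).mean()
        if known < (1 - max_id_mismatch):
            raise ValueError(
                f"only {known:.0%} of expression gene ids match the gene models; "
                "likely a mismatched annotation build"
            )

    stage1 = genes_in_regions(regions, genes)
    deg_set = set(de_results.index[de_results["is_deg"].astype(bool)])
    stage2 = [g for g in stage1 if g in deg_set]

    eff = effects.dropna(subset=["gene_id"])
    eff_by_gene = {
        g: sorted(set(sub["effect"]))
        for g, sub in eff.groupby("gene_id", sort=False)
    }
    stage3 = [
        g
        for g in stage2
        if any(e in qualifying for e in eff_by_gene.get(g, []))
    ]

    pos = {g.gene_id: (g.chrom, g.start) for g in genes}
    rows = []
    for g in stage3:
        quals = [e for e in eff_by_gene.get(g, []) if e in qualifying]
        rows.append(
            {
                "gene_id": g,
                "chrom": pos[g][0],
                "start": pos[g][1],
                "effects": ",".join(quals),
                "log2fc": float(de_results.loc[g, "log2fc"]),
                "fdr": float(de_results.loc[g, "fdr"]),
            }
        )
    candidates = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "effects", "log2fc", "fdr"]
    )
    if len(candidates):
        candidates = candidates.sort_values(
            ["chrom", "start"], kind="stable"
        ).reset_index(drop=True)

    per_class = (
        eff[eff["gene_id"].isin(stage2) & eff["effect"].isin(qualifying)]
        .groupby("effect")["gene_id"]
        .nunique()
        .to_dict()
    )
    counts = {
        "n_region_genes": len(stage1),
        "n_region_degs": len(stage2),
        "n_candidates": len(stage3),
        "per_effect_class": per_class,
    }
    return TriageReport(stage1, stage2, candidates, counts)


def rank_candidates(
    report: TriageReport,
    strong_lfc: float = 2.0,
) -> pd.DataFrame:
    """Order candidates for follow-up.

    Key: (1) upstream-only qualifying variants combined with
    |log2FC| >= ``strong_lfc`` — expression change most plausibly caused by
    the promoter variant itself; (2) |log2FC| descending; (3) FDR
    ascending; ties broken by gene id.  The key is recorded in
    ``DataFrame.attrs['ranking_key']``.
    """
    df = report.candidates.copy()
    if df.empty:
        df.attrs["ranking_key"] = "upstream_regulatory > |log2fc| desc > fdr asc"
        return df
    upstream_only = df["effects"].map(
        lambda s: set(s.split(",")) == {"upstream"} if s else False
    )
    df["upstream_regulatory"] = upstream_only & (df["log2fc"].abs() >= strong_lfc)
    df = df.sort_values(
        by=["upstream_regulatory", "log2fc", "fdr", "gene_id"],
        key=lambda col: col.abs() if col.name == "log2fc" else col,
        ascending=[False, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    df.attrs["ranking_key"] = "upstream_regulatory > |log2fc| desc > fdr asc"
    return df
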