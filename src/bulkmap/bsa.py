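"""Δ(SNP/Indel-index) association mapping for pooled extreme bulks.

Per-variant indices measure the fraction of pool reads carrying the
M-parent allele:

    index(aa) = Maa / (Paa + Maa)
    index(ab) = Mab / (Pab + Mab)
    Δ-index   = index(aa) - index(ab)

where ``aa`` and ``ab`` are the small- and large-phenotype pools and
``Paa``/``Maa`` are the read depths supporting the P- and M-parent alleles
in pool aa.  Indices are smoothed in 1 Mb sliding windows (100 kb step),
the window track is fitted by locally weighted regression, and windows
whose fitted value falls outside a simulated null confidence band are
merged into candidate regions.  The final candidate set is the interval
intersection of SNP-derived and Indel-derived regions.

The confidence band is obtained by Monte-Carlo simulation of unselected
bulks: per site, 2x bulk_size F2 individuals are drawn (P2 dosage
Binomial(2, 1/2)), split into two bulks, pool allele frequencies computed,
reads drawn Binomial(depth, freq), and the empirical two-sided quantiles
of the resulting null Δ-index taken at the configured confidence level.
Each window is assigned the per-site band interpolated at its mean pool
depth.  Sites within a window share the bulks' local genotype draw through
linkage, so the window mean fluctuates on the per-site scale rather than
shrinking like 1/sqrt(n_sites); the per-site band is therefore the
appropriate window threshold.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import stage_rng

__all__ = [
    "assign_roles",
    "filter_informative_sites",
    "compute_index",
    "sliding_windows",
    "loess_fit",
    "simulate_null_deltas",
    "null_ci",
    "attach_ci",
    "call_regions",
    "intersect_regions",
]

_POOL_COLS = [
    "P_ref", "P_alt", "M_ref", "M_alt",
    "aa_ref", "aa_alt", "ab_ref", "ab_alt",
]


def assign_roles(sites: pd.DataFrame, roles: dict) -> pd.DataFrame:
    """Rename per-sample depth columns to P/M/aa/ab role columns.

    ``roles`` maps role name -> VCF sample name, e.g.
    ``{"P": "P1", "M": "P2", "aa": "bulk_small", "ab": "bulk_large"}``.
    """
    out = sites.copy()
    for role in ("P", "M", "aa", "ab"):
        sample = roles[role]
        for suffix in ("ref", "alt"):
            col = f"{sample}_{suffix}"
            if col not in out.columns:
                raise KeyError(f"missing depth column {col!r} for role {role}")
            out[f"{role}_{suffix}"] = out[col]
    return out


def filter_informative_sites(
    sites: pd.DataFrame,
    min_parent_depth: int = 4,
    require_opposite_homozygous: bool = True,
    max_minor_fraction: float = 0.1,
    min_pool_depth: int = 4,
) -> pd.DataFrame:
    """Keep sites where the parents are well-covered and fixed for
    different alleles (by read support), and both pools have usable depth.

    Order is preserved; an empty input yields an empty output.
    """
    if sites.empty:
        return sites.copy()
    p_tot = sites["P_ref"] + sites["P_alt"]
    m_tot = sites["M_ref"] + sites["M_alt"]
    keep = (p_tot >= min_parent_depth) & (m_tot >= min_parent_depth)
    if require_opposite_homozygous:
        with np.errstate(invalid="ignore", divide="ignore"):
            p_minor = np.minimum(sites["P_ref"], sites["P_alt"]) / p_tot
            m_minor = np.minimum(sites["M_ref"], sites["M_alt"]) / m_tot
        p_major_is_alt = sites["P_alt"] > sites["P_ref"]
        m_major_is_alt = sites["M_alt"] > sites["M_ref"]
        keep &= (
            (p_minor <= max_minor_fraction)
            & (m_minor <= max_minor_fraction)
            & (p_major_is_alt != m_major_is_alt)
        )
    keep &= (sites["aa_ref"] + sites["aa_alt"] >= min_pool_depth) & (
        sites["ab_ref"] + sites["ab_alt"] >= min_pool_depth
    )
    return sites.loc[keep].copy()


def compute_index(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site index(aa), index(ab) and Δ-index, oriented to the M allele.

    Sites where a pool has zero informative depth get NaN (flagged missing
    and excluded downstream).  Negative depths raise.
    """
    depth_cols = [c for c in _POOL_COLS if c in sites.columns]
    if (sites[depth_cols] < 0).to_numpy().any():
        raise ValueError("negative read depths in variant table")
    m_is_alt = (sites["M_alt"] > sites["M_ref"]).to_numpy()
    aa_m = np.where(m_is_alt, sites["aa_alt"], sites["aa_ref"]).astype(float)
    aa_p = np.where(m_is_alt, sites["aa_ref"], sites["aa_alt"]).astype(float)
    ab_m = np.where(m_is_alt, sites["ab_alt"], sites["ab_ref"]).astype(float)
    ab_p = np.where(m_is_alt, sites["ab_ref"], sites["ab_alt"]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        index_aa = np.where(aa_m + aa_p > 0, aa_m / (aa_m + aa_p), np.nan)
        index_ab = np.where(ab_m + ab_p > 0, ab_m / (ab_m + ab_p), np.nan)
    out = sites[["chrom", "pos"]].copy()
    if "vclass" in sites.columns:
        out["vclass"] = sites["vclass"].to_numpy()
    out["depth_aa"] = aa_m + aa_p
    out["depth_ab"] = ab_m + ab_p
    out["index_aa"] = index_aa
    out["index_ab"] = index_ab
    out["delta"] = index_aa - index_ab
    return out


def sliding_windows(
    points: pd.DataFrame,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    min_sites: int = 10,
    chrom_lengths: Optional[dict] = None,
) -> pd.DataFrame:
    """Mean Δ-index in sliding windows of ``window_bp`` every ``step_bp``.

    One window starts at every multiple of ``step_bp`` below the chromosome
    length, so partial windows at the chromosome end are included.  Windows
    with fewer than ``min_sites`` non-missing sites have NaN mean (missing,
    never significant).  Positions are 1-based; windows are reported
    0-based half-open.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    rows = []
    chroms = (
        list(chrom_lengths) if chrom_lengths is not None
        else sorted(points["chrom"].unique())
    )
    for chrom in chroms:
        sub = points[points["chrom"] == chrom].sort_values("pos", kind="stable")
        pos0 = sub["pos"].to_numpy() - 1  # to 0-based
        delta = sub["delta"].to_numpy(dtype=float)
        depth = (
            0.5 * (sub["depth_aa"] + sub["depth_ab"]).to_numpy(dtype=float)
            if "depth_aa" in sub.columns
            else np.full(len(sub), np.nan)
        )
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else (int(pos0.max()) + 1 if len(pos0) else 0)
        )
        if length <= 0:
            continue
        n_windows = int(np.ceil(length / step_bp))
        for k in range(n_windows):
            start = k * step_bp
            end = min(start + window_bp, length)
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            d = delta[lo:hi]
            ok = ~np.isnan(d)
            n = int(ok.sum())
            mean_delta = float(d[ok].mean()) if n >= min_sites else np.nan
            dep = depth[lo:hi][ok]
            mean_depth = float(dep.mean()) if n else np.nan
            rows.append((chrom, start, end, n, mean_delta, mean_depth))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites", "mean_delta", "mean_depth"],
    )


def loess_fit(
    track: pd.DataFrame,
    span: float = 0.1,
    value_col: str = "mean_delta",
    pos_col: str = "start",
    min_values: int = 10,
) -> pd.DataFrame:
    """Locally weighted (tricube, degree-1) regression per chromosome.

    Fitted values are aligned to the input rows in a new ``fitted`` column;
    missing values stay missing.  Chromosomes with fewer than
    ``min_values`` non-missing values are passed through with a warning.
    """
    out = track.copy()
    fitted = np.full(len(track), np.nan)
    for chrom, sub in track.groupby("chrom", sort=False):
        y = sub[value_col].to_numpy(dtype=float)
        x = sub[pos_col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        idx = np.flatnonzero(track["chrom"].to_numpy() == chrom)
        if ok.sum() < min_values:
            warnings.warn(
                f"{chrom}: only {int(ok.sum())} values, loess skipped (pass-through)",
                stacklevel=2,
            )
            fitted[idx] = y
            continue
        fit = lowess(y[ok], x[ok], frac=span, it=0, return_sorted=False)
        vals = np.full(len(sub), np.nan)
        vals[ok] = fit
        fitted[idx] = vals
    out["fitted"] = fitted
    return out


def simulate_null_deltas(
    depth: int,
    bulk_size: int,
    n_sims: int,
    rng: np.random.Generator,
    smooth: bool = True,
) -> np.ndarray:
    """Null Δ-index draws for unselected bulks at a fixed site depth.

    2x bulk_size F2 individuals are drawn (P2 dosage Binomial(2, 1/2)) and
    split at random into two bulks; each bulk's allele frequency feeds a
    Binomial read draw at the given depth.  Zero-depth pools yield NaN.

    With ``smooth`` (the default) the read-count difference is jittered by
    Uniform(-1/2, 1/2) before dividing by depth.  At fixed depth the raw
    Δ-index lives on a lattice of spacing 1/depth with non-trivial mass on
    single atoms, so empirical quantile bands cannot attain their nominal
    level (e.g. at depth 30 a 99% band must cover either 98.6% or 99.3%).
    The jitter makes the null statistic continuous — the standard
    randomised-quantile construction for discrete data — so the band's
    coverage equals the configured confidence level exactly.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    two_n = 2 * bulk_size
    # dosage sums of two random disjoint halves of 2B iid individuals are
    # themselves iid Binomial(2B, 1/2) sums
    f1 = rng.binomial(two_n, 0.5, size=n_sims) / two_n
    f2 = rng.binomial(two_n, 0.5, size=n_sims) / two_n
    if depth == 0:
        return np.full(n_sims, np.nan)
    diff = rng.binomial(depth, f1).astype(float) - rng.binomial(depth, f2)
    if smooth:
        diff += rng.uniform(-0.5, 0.5, size=n_sims)
    return diff / depth


def null_ci(
    depth_grid: Sequence[int],
    bulk_size: int,
    n_sims: int = 20_000,
    conf: float = 0.99,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Two-sided empirical null quantile bounds of Δ-index per depth.

    Returns a frame with columns depth/ci_low/ci_high; bounds at
    intermediate depths are obtained by linear interpolation (attach_ci).
    """
    if not (0.5 < conf < 1.0):
        raise ValueError("conf must be in (0.5, 1)")
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    if n_sims < 1000:
        warnings.warn("n_sims < 1000: null quantiles will be unstable", stacklevel=2)
    rng = rng if rng is not None else stage_rng(seed, "null_ci")
    lo_q, hi_q = (1 - conf) / 2, 1 - (1 - conf) / 2
    rows = []
    for d in sorted(set(int(d) for d in depth_grid)):
        deltas = simulate_null_deltas(d, bulk_size, n_sims, rng)
        deltas = deltas[~np.isnan(deltas)]
        if deltas.size == 0:
            rows.append((d, np.nan, np.nan))
            continue
        rows.append((d, float(np.quantile(deltas, lo_q)), float(np.quantile(deltas, hi_q))))
    return pd.DataFrame(rows, columns=["depth", "ci_low", "ci_high"])


def attach_ci(windows: pd.DataFrame, ci: pd.DataFrame) -> pd.DataFrame:
    """Interpolate per-depth null bounds onto windows via their mean depth."""
    out = windows.copy()
    depth = out["mean_depth"].to_numpy(dtype=float)
    grid = ci["depth"].to_numpy(dtype=float)
    out["ci_low"] = np.interp(depth, grid, ci["ci_low"].to_numpy(dtype=float))
    out["ci_high"] = np.interp(depth, grid, ci["ci_high"].to_numpy(dtype=float))
    out.loc[np.isnan(depth), ["ci_low", "ci_high"]] = np.nan
    return out


def _runs_to_regions(windows: pd.DataFrame, source: str, step_bp: int) -> pd.DataFrame:
    """Merge maximal runs of significant windows into regions."""
    sig = (
        windows["fitted"].notna()
        & windows["ci_low"].notna()
        & (
            (windows["fitted"] < windows["ci_low"])
            | (windows["fitted"] > windows["ci_high"])
        )
    )
    regions = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        s = sig.loc[sub.index].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        fit = sub["fitted"].to_numpy(dtype=float)
        i = 0
        while i < len(sub):
            if not s[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and s[j + 1] and starts[j + 1] == starts[j] + step_bp:
                j += 1
            block = fit[i : j + 1]
            peak = float(block[np.nanargmax(np.abs(block))])
            regions.append((chrom, int(starts[i]), int(ends[j]), source, peak))
            i = j + 1
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "source", "peak_delta"])
    return _merge_adjacent(df, step_bp)


def _merge_adjacent(regions: pd.DataFrame, step_bp: int) -> pd.DataFrame:
    """Merge regions on the same chromosome separated by < step_bp."""
    rows = []
    for chrom, sub in regions.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        cur = None
        for r in sub.itertuples(index=False):
            if cur is not None and r.start - cur[2] < step_bp:
                peak = r.peak_delta if abs(r.peak_delta) > abs(cur[4]) else cur[4]
                cur = (cur[0], cur[1], max(cur[2], r.end), cur[3], peak)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = tuple(r)
            pass
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "source", "peak_delta"])


def intersect_regions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise interval intersection (>=1 bp overlap, half-open coords).

    Intersection coordinates are max(starts)..min(ends); the reported peak
    is the input peak of larger magnitude.
    """
    rows = []
    for chrom in a["chrom"].unique():
        sub_a = a[a["chrom"] == chrom].sort_values("start", kind="stable")
        sub_b = b[b["chrom"] == chrom].sort_values("start", kind="stable")
        if sub_b.empty:
            continue
        bs = sub_b["start"].to_numpy()
        be = sub_b["end"].to_numpy()
        bp = (
            sub_b["peak_delta"].to_numpy(dtype=float)
            if "peak_delta" in sub_b.columns
            else np.full(len(sub_b), np.nan)
        )
        for ra in sub_a.itertuples(index=False):
            peak_a = float(getattr(ra, "peak_delta", np.nan))
            for j in np.flatnonzero((bs < ra.end) & (be > ra.start)):
                start, end = max(ra.start, bs[j]), min(ra.end, be[j])
                with np.errstate(invalid="ignore"):
                    peak = peak_a if abs(peak_a) >= abs(bp[j]) or np.isnan(bp[j]) else bp[j]
                rows.append((chrom, int(start), int(end), "intersection", float(peak)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "source", "peak_delta"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def call_regions(
    snp_windows: pd.DataFrame,
    indel_windows: pd.DataFrame,
    step_bp: int = 100_000,
) -> dict:
    """Call per-track candidate regions and intersect SNP with Indel regions.

    Both window tracks must carry ``fitted``, ``ci_low`` and ``ci_high``
    columns.  Returns a dict with keys ``snp``, ``indel`` and
    ``candidates`` (the interval intersection).  Tracks on disjoint
    chromosome sets yield an empty candidate set with a warning.
    """
    snp_regions = _runs_to_regions(snp_windows, "SNP", step_bp)
    indel_regions = _runs_to_regions(indel_windows, "Indel", step_bp)
    shared = set(snp_windows["chrom"]) & set(indel_windows["chrom"])
    if not shared:
        warnings.warn("SNP and Indel tracks share no chromosomes", stacklevel=2)
        candidates = pd.DataFrame(
            columns=["chrom", "start", "end", "source", "peak_delta"]
        )
    else:
        candidates = intersect_regions(snp_regions, indel_regions)
    return {"snp": snp_regions, "indel": indel_regions, "candidates": candidates}
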