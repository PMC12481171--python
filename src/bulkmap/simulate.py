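"""Synthetic F2 pooled-sequencing study generator.

Emulates a biparental seed-weight mapping design end to end: an F2
population segregating at planted QTLs, extreme-phenotype bulks, pooled
short-read depths at parent-differentiating SNP/indel sites, a two-line
RNA-seq count matrix with planted differentially expressed genes, gene
models for effect calling, and a promoter allele pair with planted
variants, some of which disrupt cis-regulatory motifs.

The genetic model is deliberately minimal: each marker is linked to its
nearest planted QTL on the same chromosome through a Haldane map at a
uniform cM/Mb rate (no interference, no marker-marker linkage), and the
phenotype is additive over QTLs with Gaussian environmental noise.
Unlinked markers segregate independently at expected frequency 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig, stage_rng
from .effects import GeneModel

__all__ = [
    "F2Individual",
    "simulate_population",
    "select_bulks",
    "make_variant_map",
    "simulate_pool_reads",
    "simulate_expression",
    "simulate_gene_models",
    "simulate_reference",
    "simulate_promoter_pair",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class F2Individual:
    """One selfed F2 plant: QTL genotypes (copies of the P2 allele) and trait."""

    index: int
    genotypes: tuple
    tsw: float


def simulate_population(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Draw an F2 population with 1:2:1 segregation at each planted QTL.

    The trait is ``midparent + sum(effect_q * dosage_q) + N(0, env_sd)``
    where dosage is the number of P2 alleles (0/1/2).
    """
    if cfg.pop_size < 2:
        raise ValueError("pop_size must be at least 2")
    rng = rng if rng is not None else stage_rng(cfg.seed, "population")
    n_q = len(cfg.qtls)
    geno = rng.binomial(2, 0.5, size=(cfg.pop_size, n_q)) if n_q else np.zeros(
        (cfg.pop_size, 0), dtype=int
    )
    baseline = 0.5 * (cfg.trait_mean_P1 + cfg.trait_mean_P2)
    effects = np.array([e for _, _, e in cfg.qtls], dtype=float)
    noise = rng.normal(0.0, cfg.env_sd, size=cfg.pop_size) if cfg.env_sd > 0 else 0.0
    tsw = baseline + geno @ effects + noise
    return [
        F2Individual(i, tuple(int(g) for g in geno[i]), float(tsw[i]))
        for i in range(cfg.pop_size)
    ]


def select_bulks(pop: Sequence[F2Individual], bulk_size: int):
    """Extreme-phenotype bulks: the ``bulk_size`` smallest and largest plants.

    Ties are broken by individual index (stable sort), so the selection is
    deterministic.  Returns ``(low_bulk, high_bulk)``, disjoint.
    """
    if 2 * bulk_size > len(pop):
        raise ValueError("population too small for two disjoint bulks")
    order = sorted(range(len(pop)), key=lambda i: (pop[i].tsw, pop[i].index))
    low = [pop[i] for i in order[:bulk_size]]
    high = [pop[i] for i in order[-bulk_size:]]
    return low, high


def _allocate_counts(chrom_lengths: dict, total: int) -> dict:
    lengths = np.array([chrom_lengths[c] for c in chrom_lengths], dtype=float)
    raw = lengths / lengths.sum() * total
    counts = np.floor(raw).astype(int)
    # distribute the remainder to the largest fractional parts, ties by order
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return dict(zip(chrom_lengths, counts))


def _sample_positions(rng, length: int, n: int, taken: set, margin: int) -> list:
    """Unique 1-based positions within [margin, length-margin]."""
    out = []
    lo, hi = margin, max(margin + 1, length - margin)
    while len(out) < n:
        draw = rng.integers(lo, hi, size=2 * (n - len(out)) + 8)
        for p in draw:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return sorted(out)


def make_variant_map(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    reference: Optional[dict] = None,
) -> pd.DataFrame:
    """Place SNP and indel sites on the genome with parent-defining alleles.

    When a reference genome is supplied the ref alleles are read from it so
    the emitted VCF is consistent with the FASTA; otherwise ref bases are
    drawn at random.  Positions are 1-based.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "variant_map")
    snp_per = _allocate_counts(cfg.chrom_lengths, cfg.n_snps)
    indel_per = _allocate_counts(cfg.chrom_lengths, cfg.n_indels)
    rows = []
    for chrom, length in cfg.chrom_lengths.items():
        taken: set = set()
        snp_pos = _sample_positions(rng, length, snp_per[chrom], taken, margin=10)
        indel_pos = _sample_positions(rng, length, indel_per[chrom], taken, margin=10)
        seq = reference.get(chrom) if reference else None
        for p in snp_pos:
            ref = seq[p - 1] if seq else str(rng.choice(_BASES))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append((chrom, p, ref, alt, "SNP"))
        for p in indel_pos:
            size = int(rng.integers(1, 7))
            if rng.random() < 0.5:  # deletion
                if seq:
                    ref = seq[p - 1 : p + size]
                else:
                    ref = "".join(rng.choice(_BASES, size=size + 1))
                alt = ref[0]
            else:  # insertion
                anchor = seq[p - 1] if seq else str(rng.choice(_BASES))
                ref = anchor
                alt = anchor + "".join(rng.choice(_BASES, size=size))
            rows.append((chrom, p, ref, alt, "Indel"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _recomb_fraction(dist_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Haldane map function at a uniform recombination rate."""
    morgans = dist_bp * cm_per_mb / 1e6 / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def simulate_pool_reads(
    low_bulk: Sequence[F2Individual],
    high_bulk: Sequence[F2Individual],
    variant_map: pd.DataFrame,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Pooled read depths at every variant site for parents and both bulks.

    Parents are fixed: P1 carries the reference allele, P2 the alternate.
    Each bulk's alternate-allele count at a site is drawn from the bulk
    members' genotypes at the nearest QTL on the chromosome, propagated
    haplotype-wise through the Haldane recombination fraction; chromosomes
    without a QTL reduce to independent 1:1 segregation (expected
    frequency 0.5).  Site depths are Poisson; read alleles are flipped with
    the symmetric sequencing-error rate.  Depth-0 sites are recorded as
    0/0 and must survive I/O.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "pool_reads")
    n = len(low_bulk)
    if len(high_bulk) != n:
        raise ValueError("bulks must be the same size")
    two_n = 2 * n
    qtl_by_chrom: dict = {}
    for j, (chrom, pos, _eff) in enumerate(cfg.qtls):
        qtl_by_chrom.setdefault(chrom, []).append((pos, j))
    # P2-allele counts at each QTL within each bulk
    low_dose = np.array([ind.genotypes for ind in low_bulk], dtype=int)
    high_dose = np.array([ind.genotypes for ind in high_bulk], dtype=int)
    n_qtl = len(cfg.qtls)
    low_n11 = low_dose.sum(axis=0) if n_qtl else np.zeros(0, dtype=int)
    high_n11 = high_dose.sum(axis=0) if n_qtl else np.zeros(0, dtype=int)

    m = len(variant_map)
    r = np.full(m, 0.5)
    nearest = np.full(m, -1)
    pos = variant_map["pos"].to_numpy()
    for chrom, qlist in qtl_by_chrom.items():
        mask = (variant_map["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qpos = np.array([p for p, _ in qlist])
        qidx = np.array([j for _, j in qlist])
        d = np.abs(pos[mask, None] - qpos[None, :])
        k = d.argmin(axis=1)
        nearest[mask] = qidx[k]
        r[mask] = _recomb_fraction(d[np.arange(mask.sum()), k], cfg.cm_per_mb)

    def bulk_freq(n11_per_qtl):
        n11 = np.where(nearest >= 0, n11_per_qtl[np.clip(nearest, 0, None)], 0) if n_qtl else np.zeros(m, dtype=int)
        alt = rng.binomial(n11, 1.0 - r) + rng.binomial(two_n - n11, r)
        return alt / two_n

    e = cfg.seq_error
    freqs = {
        "bulk_small": bulk_freq(low_n11),
        "bulk_large": bulk_freq(high_n11),
        "P1": np.zeros(m),
        "P2": np.ones(m),
    }
    depths = {
        "bulk_small": cfg.depth_aa,
        "bulk_large": cfg.depth_ab,
        "P1": cfg.depth_P1,
        "P2": cfg.depth_P2,
    }
    out = variant_map.copy()
    for sample in ("P1", "P2", "bulk_small", "bulk_large"):
        f_eff = freqs[sample] * (1 - e) + (1 - freqs[sample]) * e
        depth = rng.poisson(depths[sample], size=m)
        alt = rng.binomial(depth, f_eff)
        out[f"{sample}_ref"] = depth - alt
        out[f"{sample}_alt"] = alt
    return out


def simulate_expression(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    gene_ids: Optional[Sequence[str]] = None,
    gene_lengths: Optional[Sequence[int]] = None,
    de_gene_ids: Optional[Sequence[str]] = None,
):
    """Two-condition NB count matrix with planted differential expression.

    Gene base means are log-normal; a random subset of ``n_de_genes``
    (or the caller-chosen ``de_gene_ids``) has its second-condition mean
    shifted by ``2**de_log2fc`` with random sign.  Per-sample library-size
    factors are log-normal so size-factor normalisation is exercised.

    Returns ``(counts, lengths, truth, conditions)`` where ``truth`` holds
    each gene's planted log2 fold change (condition 2 over condition 1) and
    ``conditions`` maps sample name to condition label.
    """
    if cfg.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = rng if rng is not None else stage_rng(cfg.seed, "expression")
    if gene_ids is None:
        gene_ids = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)
    if cfg.n_de_genes > n_genes:
        raise ValueError("n_de_genes exceeds number of genes")
    if gene_lengths is None:
        gene_lengths = rng.integers(200, 1500, size=n_genes) * 3
    lengths = pd.Series(np.asarray(gene_lengths, dtype=int), index=gene_ids, name="length")

    base = rng.lognormal(mean=np.log(150.0), sigma=1.2, size=n_genes)
    lfc = np.zeros(n_genes)
    if de_gene_ids is not None:
        de_idx = np.array([gene_ids.index(g) for g in de_gene_ids])
    else:
        de_idx = rng.choice(n_genes, size=cfg.n_de_genes, replace=False)
    if de_idx.size:
        signs = rng.choice([-1.0, 1.0], size=de_idx.size)
        lfc[de_idx] = cfg.de_log2fc * signs

    samples = [f"P1_rep{i + 1}" for i in range(cfg.n_reps)] + [
        f"P2_rep{i + 1}" for i in range(cfg.n_reps)
    ]
    conditions = {s: ("P1" if s.startswith("P1") else "P2") for s in samples}
    sf = rng.lognormal(0.0, 0.15, size=len(samples))
    counts = np.empty((n_genes, len(samples)), dtype=int)
    a = cfg.nb_dispersion
    for j, s in enumerate(samples):
        mu = base * (2.0 ** lfc if conditions[s] == "P2" else 1.0) * sf[j]
        if a < 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / a
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    counts_df.attrs["true_size_factors"] = pd.Series(sf, index=samples)
    truth = pd.DataFrame({"gene_id": gene_ids, "true_log2fc": lfc}).set_index("gene_id")
    return counts_df, lengths, truth, conditions


def simulate_gene_models(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> list:
    """Non-overlapping strand-mixed gene models with 1-5 CDS segments each.

    Gene ids look like ``Bna<chrom>G<number>``.  Raises if the requested
    number of genes cannot be placed on the configured chromosomes.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "gene_models")
    per_chrom = _allocate_counts(cfg.chrom_lengths, cfg.n_genes)
    genes = []
    for chrom, length in cfg.chrom_lengths.items():
        n = per_chrom[chrom]
        if n == 0:
            continue
        # draw gene structures first (segment/intron lengths relative to 0)
        structures = []
        for _ in range(n):
            n_cds = int(rng.integers(1, 6))
            seg_lens = rng.integers(30, 300, size=n_cds)
            seg_lens[-1] += (3 - int(seg_lens.sum()) % 3) % 3
            introns = rng.integers(60, 500, size=n_cds - 1) if n_cds > 1 else []
            segs, p = [], 0
            for k, sl in enumerate(seg_lens):
                segs.append((p, p + int(sl)))
                p += int(sl)
                if k < n_cds - 1:
                    p += int(introns[k])
            structures.append((segs, p))
        total_span = sum(p for _, p in structures)
        margin = 2500  # keep promoters on-chromosome
        free = length - total_span - 2 * margin - 100 * (n - 1)
        if free < 0:
            raise ValueError(
                f"cannot fit {n} genes on {chrom} (length {length}); reduce n_genes"
            )
        # spread the remaining length as random intergenic gaps so genes
        # cover the whole chromosome
        gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
        cursor = margin + int(gaps[0])
        for i, (segs, span) in enumerate(structures):
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"Bna{chrom}G{len(genes):06d}"
            genes.append(
                GeneModel(gid, chrom, strand, tuple((a + cursor, b + cursor) for a, b in segs))
            )
            cursor += span + 100 + int(gaps[i + 1])
    return genes


def simulate_reference(
    chrom_lengths: dict, rng: Optional[np.random.Generator] = None, seed: int = 0
) -> dict:
    """Uniform-random DNA for each chromosome (uppercase ACGT)."""
    rng = rng if rng is not None else stage_rng(seed, "reference")
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for chrom, length in chrom_lengths.items():
        idx = rng.integers(0, 4, size=int(length))
        out[chrom] = lut[idx].tobytes().decode("ascii")
    return out


def _realise_iupac(consensus: str, rng) -> str:
    from .promoter import IUPAC  # local import to avoid a cycle at import time

    return "".join(str(rng.choice(sorted(IUPAC[c]))) for c in consensus.upper())


def _pick_spaced_positions(rng, lo, hi, n, existing, min_gap):
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 20000:
            raise ValueError("cannot place promoter variants with required spacing")
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) >= min_gap for q in existing + out):
            out.append(p)
    return sorted(out)


def simulate_promoter_pair(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    catalog: Optional[pd.DataFrame] = None,
    name: str = "promoter_pair",
):
    """A promoter allele pair with planted, well-separated SNPs and indels.

    Concrete instances of two catalog motifs are embedded in allele A; a
    configurable number of the planted substitutions fall inside those
    instances and break the motif match, so motif-loss detection has a
    known truth.  Planted events are separated by >=25 bp and indels are
    1-4 bp, which keeps every event recoverable as one alignment event.

    Returns ``((name, seq_a, seq_b), truth)`` with truth rows
    (type, pos_a, ref, alt) in 0-based allele-A coordinates.
    """
    from .promoter import IUPAC, load_catalog

    rng = rng if rng is not None else stage_rng(cfg.seed, "promoter")
    if catalog is None:
        catalog = load_catalog()
    L = cfg.promoter_len
    min_gap = 25
    seq = list(rng.choice(_BASES, size=L))

    # embed one instance each of the first two catalog motifs (MYC/WUN by default)
    planted_motifs = []
    motif_rows = catalog.head(2).to_dict("records")
    slot = L // (len(motif_rows) + 1)
    for k, row in enumerate(motif_rows):
        inst = _realise_iupac(row["iupac"], rng)
        start = (k + 1) * slot + int(rng.integers(-40, 40))
        seq[start : start + len(inst)] = list(inst)
        planted_motifs.append((row["name"], row["iupac"], start, inst))
    seq_a = "".join(seq)

    n_disrupt = min(cfg.promoter_n_motif_disruptions, cfg.promoter_n_snps, len(planted_motifs))
    events = []  # (pos, type, ref, alt)
    chosen: list = []
    for name_, iupac, start, inst in planted_motifs[:n_disrupt]:
        # substitute at an informative (non-N) motif position to break the match
        informative = [k for k, c in enumerate(iupac.upper()) if len(IUPAC[c]) < 4]
        k = int(rng.choice(informative))
        pos = start + k
        allowed = IUPAC[iupac.upper()[k]]
        bad = [b for b in "ACGT" if b not in allowed and b != seq_a[pos]]
        if not bad:
            bad = [b for b in "ACGT" if b != seq_a[pos]]
        events.append((pos, "SNP", seq_a[pos], str(rng.choice(bad))))
        chosen.append(pos)

    n_free_snps = cfg.promoter_n_snps - n_disrupt
    free = _pick_spaced_positions(
        rng, 20, L - 20, n_free_snps + cfg.promoter_n_indels, chosen, min_gap
    )
    rng.shuffle(free)
    for p in free[:n_free_snps]:
        alt = str(rng.choice([b for b in "ACGT" if b != seq_a[p]]))
        events.append((p, "SNP", seq_a[p], alt))
    for p in free[n_free_snps:]:
        size = int(rng.integers(1, 5))
        if rng.random() < 0.5:
            events.append((p, "deletion", seq_a[p : p + size], ""))
        else:
            ins = "".join(rng.choice(_BASES, size=size))
            events.append((p, "insertion", "", ins))

    events.sort(key=lambda e: e[0])
    seq_b = seq_a
    for pos, etype, ref, alt in reversed(events):
        if etype == "SNP":
            seq_b = seq_b[:pos] + alt + seq_b[pos + 1 :]
        elif etype == "deletion":
            seq_b = seq_b[:pos] + seq_b[pos + len(ref) :]
        else:
            seq_b = seq_b[:pos] + alt + seq_b[pos:]

    truth = pd.DataFrame(
        [(t, p, r, a) for (p, t, r, a) in events],
        columns=["type", "pos_a", "ref", "alt"],
    )
    return (name, seq_a, seq_b), truth
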