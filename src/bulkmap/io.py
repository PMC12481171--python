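"""Readers and writers for the pipeline's on-disk formats.

Variants travel as VCF v4.2 with per-sample AD (ref,alt depths); gene
models as GFF3; counts as TSV (gene_id, length, then one column per
sample); promoters and reference genomes as FASTA; called regions as BED6
(0-based half-open, name = source track, score = 1000*|peak Δ-index|).
VCF positions are 1-based; all internal region/window coordinates are
0-based half-open.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .effects import GeneModel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "read_gff3",
    "write_fasta",
    "read_fasta",
    "write_counts",
    "read_counts",
    "write_bed",
    "read_bed",
    "write_conditions",
    "read_conditions",
]

SAMPLES = ("P1", "P2", "bulk_small", "bulk_large")


def write_vcf(
    variants: pd.DataFrame,
    path,
    samples: Sequence[str] = SAMPLES,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write a variant table with per-sample ref/alt depths as VCF v4.2."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=bulkmap",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depths for ref and alt alleles">',
    ]
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={int(length)}>")
    else:
        for chrom in pd.unique(variants["chrom"]):
            lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in variants.itertuples(index=False):
        fields = [rec.chrom, str(int(rec.pos)), ".", rec.ref, rec.alt, ".", "PASS", "."]
        fields.append("GT:AD")
        for s in samples:
            ref_d = int(getattr(rec, f"{s}_ref"))
            alt_d = int(getattr(rec, f"{s}_alt"))
            tot = ref_d + alt_d
            if tot == 0:
                gt = "./."
            elif ref_d >= 0.9 * tot:
                gt = "0/0"
            elif alt_d >= 0.9 * tot:
                gt = "1/1"
            else:
                gt = "0/1"
            fields.append(f"{gt}:{ref_d},{alt_d}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF with AD into a depth table (one row per biallelic site).

    Adds a ``vclass`` column: SNP when ref and alt are both single bases,
    Indel otherwise.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        ad = v.format("AD")
        rec = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0],
            "vclass": "SNP" if len(v.REF) == 1 and len(v.ALT[0]) == 1 else "Indel",
        }
        for i, s in enumerate(samples):
            ref_d, alt_d = (int(x) for x in ad[i][:2])
            rec[f"{s}_ref"] = max(ref_d, 0)  # missing AD (-1) -> 0
            rec[f"{s}_alt"] = max(alt_d, 0)
        rows.append(rec)
    vcf.close()
    return pd.DataFrame(rows)


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + mRNA + CDS with phase)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chrom, "bulkmap", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", attrs]
            )
        )
        mrna_id = f"{g.gene_id}.t1"
        lines.append(
            "\t".join(
                [g.chrom, "bulkmap", "mRNA", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={mrna_id};Parent={g.gene_id}"]
            )
        )
        order = g.cds_segments if g.strand == "+" else tuple(reversed(g.cds_segments))
        cum = 0
        phases = {}
        for seg in order:
            phases[seg] = (3 - cum % 3) % 3
            cum += seg[1] - seg[0]
        for a, b in g.cds_segments:
            lines.append(
                "\t".join(
                    [g.chrom, "bulkmap", "CDS", str(a + 1), str(b), ".", g.strand,
                     str(phases[(a, b)]), f"ID=cds.{mrna_id};Parent={mrna_id}"]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> list:
    """Read GFF3 gene models (CDS grouped by Parent mRNA -> gene)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        segs = []
        for cds in db.children(gene, featuretype="CDS"):
            segs.append((cds.start - 1, cds.end))
        segs.sort()
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(segs)))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_counts(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    """Counts TSV: gene_id, length, then one integer column per sample."""
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index).astype(int))
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path):
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df["length"].astype(int)
    counts = df.drop(columns=["length"]).astype(int)
    return counts, lengths


def write_bed(regions: pd.DataFrame, path) -> None:
    """BED6: name = source, score = 1000*|peak Δ-index| (clipped to 1000)."""
    with open(path, "w") as fh:
        for r in regions.itertuples(index=False):
            peak = getattr(r, "peak_delta", 0.0)
            score = int(min(1000, round(1000 * abs(peak)))) if np.isfinite(peak) else 0
            fh.write(
                f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.source}\t{score}\t.\n"
            )


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append(
                (
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[3] if len(f) > 3 else ".",
                    int(f[4]) / 1000.0 if len(f) > 4 else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "source", "peak_delta"])


def write_conditions(conditions: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(conditions), fh, sort_keys=True)


def read_conditions(path) -> dict:
    with open(path) as fh:
        return {str(k): str(v) for k, v in yaml.safe_load(fh).items()}
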