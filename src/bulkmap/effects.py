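"""Variant-effect classification against strand-aware gene models.

Variants that distinguish the two parents are classified into the triage
classes used downstream: ``frameshift``, ``inframe_indel``,
``nonsynonymous``, ``synonymous``, ``upstream``, ``intronic`` and
``intergenic``.  Coding SNVs are resolved by translating the affected codon
on the coding strand with the standard nuclear code; coding indels are
resolved by the length difference modulo 3.  Indels that straddle a
CDS/intron boundary are conservatively reported as frameshift.

Coordinates are 0-based half-open internally; VCF positions are 1-based.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "annotate_variant",
    "annotate_table",
    "genes_in_regions",
    "EFFECT_CLASSES",
]

EFFECT_CLASSES = (
    "frameshift",
    "inframe_indel",
    "nonsynonymous",
    "synonymous",
    "upstream",
    "intronic",
    "intergenic",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ordered CDS segments on one strand.

    ``cds_segments`` are (start, end) pairs in genomic coordinates,
    0-based half-open, sorted in ascending genomic order regardless of
    strand.  Total CDS length must be a multiple of 3.  The transcription
    start (``tss``) is taken as the 5'-most coding coordinate (no UTRs are
    modelled).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        segs = tuple((int(a), int(b)) for a, b in self.cds_segments)
        if not segs:
            raise ValueError(f"{self.gene_id}: no CDS segments")
        for a, b in segs:
            if a >= b:
                raise ValueError(f"{self.gene_id}: empty CDS segment ({a},{b})")
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if b1 > a2:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or unsorted")
        if sum(b - a for a, b in segs) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        object.__setattr__(self, "cds_segments", segs)

    @property
    def start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def coding_length(self) -> int:
        return sum(b - a for a, b in self.cds_segments)

    def cds_offset(self, pos: int) -> Optional[int]:
        """Offset of genomic ``pos`` within the coding sequence, or None."""
        off = 0
        if self.strand == "+":
            for a, b in self.cds_segments:
                if a <= pos < b:
                    return off + (pos - a)
                off += b - a
            return None
        for a, b in reversed(self.cds_segments):
            if a <= pos < b:
                return off + (b - 1 - pos)
            off += b - a
        return None

    def genomic_positions(self, offsets: Sequence[int]) -> list:
        """Genomic coordinates of coding-sequence offsets (transcription order)."""
        order = self.cds_segments if self.strand == "+" else tuple(reversed(self.cds_segments))
        out = []
        for off in offsets:
            rem = off
            for a, b in order:
                n = b - a
                if rem < n:
                    out.append(a + rem if self.strand == "+" else b - 1 - rem)
                    break
                rem -= n
            else:
                raise IndexError(f"CDS offset {off} out of range for {self.gene_id}")
        return out


def _coding_base(base: str, strand: str) -> str:
    return base if strand == "+" else base.translate(_COMPLEMENT)


def _classify_coding_snv(gene: GeneModel, pos0: int, alt: str, seq: str) -> str:
    off = gene.cds_offset(pos0)
    codon_idx = off // 3
    in_codon = off % 3
    offsets = [codon_idx * 3 + k for k in range(3)]
    gpos = gene.genomic_positions(offsets)
    codon = "".join(_coding_base(seq[p], gene.strand) for p in gpos)
    mutant = list(codon)
    mutant[in_codon] = _coding_base(alt, gene.strand)
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq("".join(mutant)).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _classify_for_gene(
    gene: GeneModel,
    pos0: int,
    ref: str,
    alt: str,
    seq: Optional[str],
    upstream_bp: int,
) -> Optional[str]:
    is_indel = len(ref) != len(alt)
    if not is_indel:
        affected = (pos0, pos0 + 1)
    elif len(ref) > len(alt):  # deletion: anchored VCF style, bases after pos removed
        affected = (pos0 + 1, pos0 + len(ref))
    else:  # insertion between pos0 and pos0+1
        affected = (pos0, pos0 + 2)

    in_cds = [gene.cds_offset(p) is not None for p in range(affected[0], affected[1])]
    if is_indel:
        if any(in_cds):
            if len(ref) > len(alt) and not all(in_cds):
                return "frameshift"  # boundary-spanning: conservative
            if len(ref) < len(alt) and not all(in_cds):
                return "intronic" if gene.start <= pos0 < gene.end else None
            net = abs(len(ref) - len(alt))
            return "frameshift" if net % 3 != 0 else "inframe_indel"
    else:
        if in_cds[0]:
            if seq is None:
                raise ValueError(
                    "a reference sequence is required to classify coding SNVs"
                )
            return _classify_coding_snv(gene, pos0, alt, seq)

    if gene.start <= pos0 < gene.end or (
        is_indel and affected[0] < gene.end and affected[1] > gene.start
    ):
        return "intronic"

    if gene.strand == "+":
        if gene.start - upstream_bp <= pos0 < gene.start:
            return "upstream"
    else:
        if gene.end <= pos0 < gene.end + upstream_bp:
            return "upstream"
    return None


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: Sequence[GeneModel],
    ref_seqs: Optional[Mapping[str, str]] = None,
    upstream_bp: int = 2000,
) -> list:
    """Classify one variant against every overlapping/nearby gene.

    ``pos`` is 1-based (VCF convention).  Returns a list of dicts with keys
    ``gene_id``/``chrom``/``pos``/``ref``/``alt``/``effect``; a single
    ``intergenic`` record (gene_id None) when no gene is within reach.
    """
    pos0 = pos - 1
    seq = None
    if ref_seqs is not None:
        seq = ref_seqs.get(chrom)
        if seq is not None and seq[pos0 : pos0 + len(ref)].upper() != ref.upper():
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: VCF ref {ref!r} vs genome "
                f"{seq[pos0:pos0 + len(ref)]!r}"
            )
    records = []
    for gene in genes:
        if gene.chrom != chrom:
            continue
        eff = _classify_for_gene(gene, pos0, ref, alt, seq, upstream_bp)
        if eff is not None:
            records.append(
                {
                    "gene_id": gene.gene_id,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "effect": eff,
                }
            )
    if not records:
        records.append(
            {
                "gene_id": None,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "effect": "intergenic",
            }
        )
    return records


class _GeneIndex:
    """Per-chromosome positional index over (non-overlapping) genes."""

    def __init__(self, genes: Iterable[GeneModel], upstream_bp: int):
        self.upstream_bp = upstream_bp
        self.by_chrom: dict = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        self.starts = {}
        self.maxlen = {}
        for chrom, gl in self.by_chrom.items():
            gl.sort(key=lambda g: (g.start, g.gene_id))
            self.starts[chrom] = [g.start for g in gl]
            self.maxlen[chrom] = max(g.end - g.start for g in gl)

    def candidates(self, chrom: str, pos0: int, width: int = 1) -> list:
        gl = self.by_chrom.get(chrom)
        if not gl:
            return []
        starts = self.starts[chrom]
        reach = self.maxlen[chrom] + self.upstream_bp + width
        lo = bisect.bisect_left(starts, pos0 - reach)
        hi = bisect.bisect_right(starts, pos0 + self.upstream_bp + width)
        return gl[lo:hi]


def annotate_table(
    variants: pd.DataFrame,
    genes: Sequence[GeneModel],
    ref_seqs: Optional[Mapping[str, str]] = None,
    upstream_bp: int = 2000,
) -> pd.DataFrame:
    """Classify every variant in a table; one row per (gene, variant) pair."""
    index = _GeneIndex(genes, upstream_bp)
    rows = []
    for rec in variants.itertuples(index=False):
        cand = index.candidates(rec.chrom, rec.pos - 1, width=len(rec.ref))
        rows.extend(
            annotate_variant(
                rec.chrom, int(rec.pos), rec.ref, rec.alt, cand, ref_seqs, upstream_bp
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "pos", "ref", "alt", "effect"]
    )


def genes_in_regions(
    regions: pd.DataFrame, genes: Sequence[GeneModel]
) -> list:
    """Gene ids whose span overlaps any region by >=1 bp (half-open coords).

    Output is deduplicated and ordered by (chrom, gene start).
    """
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    hits = {}
    for chrom, gl in by_chrom.items():
        gl.sort(key=lambda g: (g.start, g.gene_id))
        starts = np.array([g.start for g in gl])
        ends = np.array([g.end for g in gl])
        sub = regions[regions["chrom"] == chrom]
        for r in sub.itertuples(index=False):
            # non-overlapping sorted genes: overlaps form a contiguous block
            lo = int(np.searchsorted(ends, r.start, side="right"))
            hi = int(np.searchsorted(starts, r.end, side="left"))
            for g in gl[lo:hi]:
                hits[g.gene_id] = (g.chrom, g.start)
    return sorted(hits, key=lambda gid: (hits[gid][0], hits[gid][1], gid))
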