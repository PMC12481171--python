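"""Promoter allele comparison: alignment, variant events, motif gains/losses.

Two cloned promoter alleles are compared by affine-gap global alignment
(Needleman-Wunsch/Gotoh, via Biopython's PairwiseAligner); aligned mismatch
columns become SNP events and maximal gap runs collapse to single
insertion/deletion events.  Cis-regulatory elements are located by IUPAC
consensus matching on both strands, and hits present in one allele but
absent at the aligned locus of the other are reported as motif gains or
losses together with the overlapping variant events.

The shipped motif catalog (``data/motifs.tsv``) carries PlantCARE-style
consensus strings (including MYC and WUN entries).  These are editable
configuration data — approximate community consensus, not measured binding
sites — and should be replaced when exact site definitions are available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "IUPAC",
    "load_catalog",
    "global_align",
    "enumerate_variants",
    "scan_motifs",
    "diff_motifs",
    "PromoterDiff",
]

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"empty {what}")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{what} contains non-IUPAC DNA characters: {sorted(bad)}")
    return seq


def load_catalog(path=None) -> pd.DataFrame:
    """Load a motif catalog TSV (columns: name, iupac, description)."""
    if path is None:
        with resources.files("bulkmap").joinpath("data/motifs.tsv").open() as fh:
            cat = pd.read_csv(fh, sep="\t", comment="#")
    else:
        cat = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "iupac", "description"}
    if not required <= set(cat.columns):
        raise ValueError(f"catalog must have columns {sorted(required)}")
    for cons in cat["iupac"]:
        if not cons or any(c not in IUPAC for c in str(cons).upper()):
            raise ValueError(f"invalid IUPAC consensus in catalog: {cons!r}")
    return cat


def global_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
):
    """Optimal affine-gap global alignment of two DNA sequences.

    A gap of length L scores ``gap_open + (L-1)*gap_extend``.  Returns
    ``(score, aligned_a, aligned_b)`` with '-' for gaps; the reported
    alignment is the aligner's deterministic first optimum.  The defaults
    make a 3-bp indel (score -6) preferable to three separate mismatches
    plus lost matches, so short indel runs stay single events.
    """
    a = _validate_dna(a, "sequence a")
    b = _validate_dna(b, "sequence b")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return float(aln.score), ga, gb


def enumerate_variants(aligned_a: str, aligned_b: str) -> pd.DataFrame:
    """Collapse an alignment into SNP / insertion / deletion events.

    Maximal gap runs count as ONE event; adjacent mismatch columns stay
    separate SNP events.  Positions are 0-based in seq_a coordinates (for
    insertions, the a-position before which the inserted bases sit).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    events = []
    i = 0
    pos_a = 0
    n = len(aligned_a)
    while i < n:
        ca, cb = aligned_a[i], aligned_b[i]
        if ca == "-" and cb == "-":
            raise ValueError("alignment column with gaps in both sequences")
        if cb == "-":  # deletion from a
            j = i
            while j < n and aligned_b[j] == "-":
                j += 1
            run = aligned_a[i:j]
            events.append(("deletion", pos_a, run, ""))
            pos_a += len(run)
            i = j
        elif ca == "-":  # insertion into a
            j = i
            while j < n and aligned_a[j] == "-":
                j += 1
            run = aligned_b[i:j]
            events.append(("insertion", pos_a, "", run))
            i = j
        else:
            if ca != cb:
                events.append(("SNP", pos_a, ca, cb))
            pos_a += 1
            i += 1
    return pd.DataFrame(events, columns=["type", "pos_a", "ref", "alt"])


def _consensus_regex(consensus: str) -> re.Pattern:
    parts = []
    for c in consensus.upper():
        opts = sorted(IUPAC[c])
        parts.append(opts[0] if len(opts) == 1 else "[" + "".join(opts) + "]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motifs(seq: str, catalog: pd.DataFrame) -> pd.DataFrame:
    """All IUPAC-consensus motif occurrences on both strands.

    A '-' strand hit at ``start`` means the reverse complement of the
    consensus matches the forward sequence at that locus.  Overlapping hits
    are all reported.  Columns: motif, strand, start, end (0-based,
    half-open, forward-strand coordinates).
    """
    seq = _validate_dna(seq)
    hits = []
    for row in catalog.itertuples(index=False):
        cons = str(row.iupac).upper()
        if any(c not in IUPAC for c in cons):
            raise ValueError(f"invalid IUPAC consensus: {cons!r}")
        L = len(cons)
        for m in _consensus_regex(cons).finditer(seq):
            hits.append((row.name_ if hasattr(row, "name_") else row.name, "+", m.start(), m.start() + L))
        for m in _consensus_regex(_revcomp(cons)).finditer(seq):
            hits.append((row.name_ if hasattr(row, "name_") else row.name, "-", m.start(), m.start() + L))
    df = pd.DataFrame(hits, columns=["motif", "strand", "start", "end"])
    return df.sort_values(["start", "motif", "strand"], kind="stable").reset_index(drop=True)


@dataclass
class PromoterDiff:
    """Variant events plus motif gains/losses between two promoter alleles."""

    name: str
    variants: pd.DataFrame
    losses: pd.DataFrame  # hits present in allele A, absent in allele B
    gains: pd.DataFrame  # hits present in allele B, absent in allele A


def _column_spans(aligned: str):
    """Map each ungapped position to its alignment column; return arrays."""
    cols = np.flatnonzero(np.frombuffer(aligned.encode(), dtype=np.uint8) != ord("-"))
    return cols  # cols[k] = alignment column of sequence position k


def diff_motifs(
    name: str,
    seq_a: str,
    seq_b: str,
    catalog: pd.DataFrame,
    alignment=None,
) -> PromoterDiff:
    """Report motif occurrences gained or lost between two promoter alleles.

    Two hits (same motif, same strand) correspond when their alignment-
    column spans overlap; a hit with no correspondent in the other allele
    is a loss (allele A) or gain (allele B).  Each gain/loss is annotated
    with the variant events overlapping its span.  The correspondence is
    symmetric, so swapping the alleles swaps gains and losses.
    """
    if alignment is None:
        alignment = global_align(seq_a, seq_b)
    _score, ga, gb = alignment
    variants = enumerate_variants(ga, gb)
    hits_a = scan_motifs(seq_a, catalog)
    hits_b = scan_motifs(seq_b, catalog)
    col_a = _column_spans(ga)
    col_b = _column_spans(gb)

    def spans(hits, cols):
        if hits.empty:
            return np.zeros((0, 2), dtype=int)
        s = cols[hits["start"].to_numpy()]
        e = cols[hits["end"].to_numpy() - 1] + 1
        return np.column_stack([s, e])

    span_a = spans(hits_a, col_a)
    span_b = spans(hits_b, col_b)

    def unmatched(hits_x, span_x, hits_y, span_y):
        keep = []
        for i in range(len(hits_x)):
            mi, si = hits_x.iloc[i]["motif"], hits_x.iloc[i]["strand"]
            matched = False
            for j in range(len(hits_y)):
                if hits_y.iloc[j]["motif"] != mi or hits_y.iloc[j]["strand"] != si:
                    continue
                if span_x[i, 0] < span_y[j, 1] and span_y[j, 0] < span_x[i, 1]:
                    matched = True
                    break
            if not matched:
                keep.append(i)
        return hits_x.iloc[keep].reset_index(drop=True)

    losses = unmatched(hits_a, span_a, hits_b, span_b)
    gains = unmatched(hits_b, span_b, hits_a, span_a)

    def attach_variants(df, cols):
        overlapping = []
        var_spans = []
        pos_to_col_a = col_a
        for v in variants.itertuples(index=False):
            if v.type == "deletion":
                s = pos_to_col_a[v.pos_a]
                e = pos_to_col_a[v.pos_a + len(v.ref) - 1] + 1
            elif v.type == "insertion":
                anchor = pos_to_col_a[v.pos_a] if v.pos_a < len(seq_a) else len(ga)
                s, e = anchor - len(v.alt), anchor
            else:
                s = pos_to_col_a[v.pos_a]
                e = s + 1
            var_spans.append((s, e))
        for i in range(len(df)):
            s = cols[df.iloc[i]["start"]]
            e = cols[df.iloc[i]["end"] - 1] + 1
            ov = [
                f"{variants.iloc[k]['type']}@{variants.iloc[k]['pos_a']}"
                for k, (vs, ve) in enumerate(var_spans)
                if vs < e and s < ve
            ]
            overlapping.append(",".join(ov))
        df = df.copy()
        df["variants"] = overlapping
        return df

    losses = attach_variants(losses, col_a)
    gains = attach_variants(gains, col_b)
    return PromoterDiff(name=name, variants=variants, losses=losses, gains=gains)
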