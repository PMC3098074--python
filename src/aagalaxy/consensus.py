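"""Vector-space consensus residues for alignment columns.

The consensus residue of an alignment column is the amino acid whose
vector lies closest (Euclidean) to the centroid of the vectors of the
residues observed in the column.  Duplicate residues weight the centroid;
gaps are ignored (or, optionally, dominate the column).  With BLOSUM62
vectors the column {H, R, V} yields T, a residue "between" a positive,
a polar and an aliphatic side chain.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .galaxy import Galaxy
from .residues import CANONICAL_ORDER, EXTENDED_CODES

__all__ = ["column_consensus", "consensus_sequence"]

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


def column_consensus(column, G: Galaxy) -> str:
    """Consensus residue of a multiset of one-letter codes.

    Gaps ('-', '.') are ignored.  Ties in the distance to the centroid are
    broken in favour of the earlier residue in canonical order (and logged).
    """
    residues = [c.upper() for c in column if c.upper() not in GAP_CHARS]
    if not residues:
        raise ValueError("all-gap column has no consensus")
    bad = [r for r in residues if r not in CANONICAL_ORDER]
    if bad:
        raise ValueError(f"non-canonical residues in column: {sorted(set(bad))}")
    idx = [CANONICAL_ORDER.index(r) for r in residues]
    centroid = G.points[idx].mean(axis=0)
    dists = np.linalg.norm(G.points - centroid, axis=1)
    best = int(np.argmin(dists))
    ties = np.flatnonzero(dists <= dists[best] + 1e-12)
    if ties.size > 1:
        logger.info(
            "consensus tie between %s; choosing %s",
            "".join(CANONICAL_ORDER[t] for t in ties),
            CANONICAL_ORDER[best],
        )
    return CANONICAL_ORDER[best]


def _read_alignment(alignment):
    if isinstance(alignment, (str, Path)):
        text = Path(alignment).read_text() if Path(str(alignment)).exists() else str(alignment)
        return AlignIO.read(StringIO(text), "fasta")
    if hasattr(alignment, "get_alignment_length"):
        return alignment
    # iterable of equal-length strings
    seqs = list(alignment)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    return seqs


def consensus_sequence(
    alignment, G: Galaxy, gap_rule: str = "ignore_gaps"
) -> str:
    """Per-column vector-space consensus of an aligned sequence set.

    ``alignment`` may be aligned FASTA text, a path to such a file, a
    Biopython alignment object, or an iterable of equal-length strings.
    ``gap_rule="majority_gap_emits_gap"`` emits '-' for columns in which
    gaps are the strict majority; ``"ignore_gaps"`` always computes a
    residue consensus from the non-gap symbols.
    """
    if gap_rule not in {"ignore_gaps", "majority_gap_emits_gap"}:
        raise ValueError(f"unknown gap rule {gap_rule!r}")
    aln = _read_alignment(alignment)
    if hasattr(aln, "get_alignment_length"):
        length = aln.get_alignment_length()
        columns = ["".join(str(rec.seq)[i] for rec in aln) for i in range(length)]
    else:
        lengths = {len(s) for s in aln}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: sequences differ in length")
        columns = ["".join(s[i] for s in aln) for i in range(lengths.pop())]
    out = []
    for col in columns:
        n_gap = sum(c in GAP_CHARS for c in col)
        if gap_rule == "majority_gap_emits_gap" and n_gap * 2 > len(col):
            out.append("-")
        else:
            out.append(column_consensus(col, G))
    return "".join(out)
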