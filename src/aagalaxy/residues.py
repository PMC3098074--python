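"""Canonical amino acid ordering used throughout the package.

Every 20-vector, 20x20 table and galaxy in this package is indexed by the
20 standard amino acids in alphabetical one-letter order.  Extended codes
(B, Z, X, J, U, O and the stop/gap symbols) are never part of the numeric
objects; parsers drop them on input.
"""

from __future__ import annotations

#: The 20 canonical residues, alphabetical by one-letter code.
CANONICAL_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue -> position in :data:`CANONICAL_ORDER`.
RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(CANONICAL_ORDER)}

#: Codes silently discarded when parsing matrix files or alignments.
EXTENDED_CODES: frozenset[str] = frozenset("BZXJUO*-.")

N_RESIDUES: int = 20


def is_canonical(code: str) -> bool:
    """True if *code* is one of the 20 standard one-letter residues."""
    return code.upper() in RESIDUE_INDEX
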