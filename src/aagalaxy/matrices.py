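"""Substitution matrix parsing, registry and elementary matrix algebra.

Matrices are read from NCBI/EMBOSS-style text files ('#' comment lines, a
header row of residue letters, one labelled row per residue).  The parser is
a thin wrapper around :mod:`Bio.Align.substitution_matrices`; on top of it we
restrict the table to the 20 canonical residues, reorder rows/columns to the
package-wide canonical order, enforce symmetry and harvest two pieces of
header metadata that matter for the downstream analyses:

* ``Entropy = <x>`` -- the relative entropy of the matrix in bits, as
  published with the matrix.  It is accepted as metadata, never recomputed
  from alignment counts.
* the score scale -- rounded matrices of the classical series are printed in
  fractional-bit units that differ per matrix (e.g. BLOSUM62 in 1/2-bit,
  BLOSUM30 in 1/5-bit units, PAM250 with scale ln(2)/3).  The parsed scale
  allows conversion of every matrix to common bit units, which is essential
  when matrix means or galaxy radii are compared across a series.

The bundled registry holds the rounded BLOSUM series (30..90 step 5, 62 and
100) and the rounded PAM series (10..500 step 10) in normalized 20x20 form.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices as _bio_subst

from .residues import CANONICAL_ORDER, EXTENDED_CODES, N_RESIDUES

logger = logging.getLogger(__name__)

_ENTROPY_RE = re.compile(r"Entropy\s*=\s*(-?\d+\.?\d*)")
_BIT_UNITS_RE = re.compile(r"in\s+1/(\d+)\s+Bit\s+Units", re.IGNORECASE)
_PAM_SCALE_RE = re.compile(r"scale\s*=\s*ln\(2\)\s*/\s*(\d+)", re.IGNORECASE)
_NAME_RE = re.compile(r"\b(BLOSUM|PAM)\s*(\d+)", re.IGNORECASE)

#: Symmetry tolerance for real-valued matrices.
SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 symmetric amino acid score table with provenance metadata.

    Attributes
    ----------
    scores:
        ``(20, 20)`` float array in canonical residue order.
    name:
        Identifier, e.g. ``"BLOSUM62"``.
    series:
        ``"BLOSUM"``, ``"PAM"`` or ``"OTHER"``.
    index:
        Series index (62 for BLOSUM62) or ``None``.
    rounded:
        Whether the entries are integer-rounded scores.
    units:
        Free-text scale annotation, e.g. ``"1/2 bits"``.
    relative_entropy:
        Matrix relative entropy in bits, from the file header, or ``None``.
    scale_bits:
        Multiplying ``scores`` by this factor expresses them in bits
        (``None`` when the file states no scale).
    """

    scores: np.ndarray
    name: str = "matrix"
    series: str = "OTHER"
    index: int | None = None
    rounded: bool = False
    units: str = "unknown"
    relative_entropy: float | None = None
    scale_bits: float | None = None
    comments: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError(f"expected a 20x20 table, got {scores.shape}")
        asym = np.abs(scores - scores.T).max()
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(
                np.abs(scores - scores.T).argmax(), scores.shape
            )
            raise ValueError(
                "matrix is not symmetric: "
                f"s[{CANONICAL_ORDER[i]}][{CANONICAL_ORDER[j]}]="
                f"{scores[i, j]} vs {scores[j, i]} (|diff|={asym:g})"
            )
        if self.relative_entropy is not None and self.relative_entropy < 0:
            raise ValueError("relative entropy must be nonnegative")
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    # -- convenience ----------------------------------------------------
    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(
            self.scores[CANONICAL_ORDER.index(a), CANONICAL_ORDER.index(b)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        labels = list(CANONICAL_ORDER)
        return pd.DataFrame(self.scores, index=labels, columns=labels)

    def in_bits(self) -> "SubstitutionMatrix":
        """Return the matrix rescaled to bit units.

        Raises if the file carried no scale annotation.
        """
        if self.scale_bits is None:
            raise ValueError(f"{self.name}: no scale metadata, cannot rescale")
        if self.scale_bits == 1.0:
            return self
        return replace(
            self,
            scores=self.scores * self.scale_bits,
            rounded=False,
            units="bits",
            scale_bits=1.0,
            name=self.name,
        )


def _metadata_from_comments(lines: list[str]) -> dict:
    meta: dict = {"comments": tuple(lines)}
    text = "\n".join(lines)
    if m := _ENTROPY_RE.search(text):
        meta["relative_entropy"] = float(m.group(1))
    if m := _BIT_UNITS_RE.search(text):
        meta["scale_bits"] = 1.0 / int(m.group(1))
        meta["units"] = f"1/{m.group(1)} bits"
    elif m := _PAM_SCALE_RE.search(text):
        meta["scale_bits"] = 1.0 / int(m.group(1))
        meta["units"] = f"1/{m.group(1)} bits"
    if m := _NAME_RE.search(text):
        meta.setdefault("name", f"{m.group(1).upper()}{m.group(2)}")
    return meta


def parse_matrix(text: str, name: str | None = None) -> SubstitutionMatrix:
    """Parse an NCBI/EMBOSS-style matrix file into a :class:`SubstitutionMatrix`.

    Rows/columns may appear in any order; extended codes (B, Z, X, ``*``,
    J, U, O) are dropped with a log message.  Missing canonical residues or
    asymmetric entries are hard errors.
    """
    comment_lines = [
        ln.lstrip("#").strip()
        for ln in text.splitlines()
        if ln.lstrip().startswith("#")
    ]
    array = _bio_subst.read(io.StringIO(text))
    alphabet = [str(c) for c in array.alphabet]
    present = {c.upper() for c in alphabet}
    missing = [aa for aa in CANONICAL_ORDER if aa not in present]
    if missing:
        raise ValueError(
            f"matrix is missing canonical residues: {', '.join(missing)}"
        )
    dropped = sorted(present - set(CANONICAL_ORDER))
    if dropped:
        logger.info("dropping extended residue codes: %s", ", ".join(dropped))
    idx = [alphabet.index(aa) for aa in CANONICAL_ORDER]
    scores = np.asarray(array)[np.ix_(idx, idx)].astype(float)
    asym = np.abs(scores - scores.T).max()
    if asym > SYMMETRY_TOL:
        i, j = np.unravel_index(np.abs(scores - scores.T).argmax(), scores.shape)
        raise ValueError(
            f"asymmetric entries beyond tolerance for pair "
            f"({CANONICAL_ORDER[i]}, {CANONICAL_ORDER[j]}): "
            f"{scores[i, j]} vs {scores[j, i]}"
        )
    meta = _metadata_from_comments(comment_lines)
    if name is not None:
        meta["name"] = name
    resolved = meta.get("name", "matrix")
    series, index = "OTHER", None
    if m := re.fullmatch(r"(BLOSUM|PAM)(\d+)(.*)", resolved.upper()):
        series, index = m.group(1), int(m.group(2))
    rounded = bool(np.allclose(scores, np.round(scores)))
    return SubstitutionMatrix(
        scores=scores,
        name=resolved,
        series=series,
        index=index,
        rounded=rounded,
        units=meta.get("units", "unknown"),
        relative_entropy=meta.get("relative_entropy"),
        scale_bits=meta.get("scale_bits"),
        comments=meta["comments"],
    )


def write_matrix(S: SubstitutionMatrix, decimals: int = 6) -> str:
    """Render *S* in NCBI-style text.  Integers print as integers."""
    lines = [f"# {c}" for c in S.comments] or [f"# {S.name}"]
    header = "   " + " ".join(f"{aa:>8s}" for aa in CANONICAL_ORDER)
    lines.append(header)
    for i, aa in enumerate(CANONICAL_ORDER):
        if S.rounded:
            row = " ".join(f"{int(round(v)):>8d}" for v in S.scores[i])
        else:
            row = " ".join(f"{v:>8.{decimals}f}" for v in S.scores[i])
        lines.append(f"{aa}  {row}")
    return "\n".join(lines) + "\n"


def to_tsv(S: SubstitutionMatrix) -> str:
    """Tab-separated export (residues as row/column labels)."""
    return S.to_dataframe().to_csv(sep="\t", float_format="%.6g")


# -- elementary algebra -------------------------------------------------

def matrix_mean(S: SubstitutionMatrix) -> float:
    """Arithmetic mean over all 400 cells (off-diagonal cells count twice)."""
    return float(S.scores.mean())


def shift_matrix(S: SubstitutionMatrix, c: float) -> SubstitutionMatrix:
    """Add the constant *c* to every entry."""
    if c == 0:
        return S
    return replace(
        S,
        scores=S.scores + c,
        name=f"{S.name}{c:+g}",
        rounded=bool(np.allclose(S.scores + c, np.round(S.scores + c))),
    )


def center_matrix(S: SubstitutionMatrix) -> SubstitutionMatrix:
    """Shift *S* so that its 400-element mean is zero."""
    out = shift_matrix(S, -matrix_mean(S))
    return replace(out, name=f"{S.name}~centered")


def frobenius_norm(S: SubstitutionMatrix) -> float:
    """Square root of the sum of all 400 squared entries."""
    return float(np.linalg.norm(S.scores))


# -- bundled fixture registry -------------------------------------------

_DATA = resources.files("aagalaxy.data") / "matrices"

#: BLOSUM indices available in the bundle (BLOSUM95 is not distributed
#: with any of the public matrix collections this package draws on).
BLOSUM_INDICES = (30, 35, 40, 45, 50, 55, 60, 62, 65, 70, 75, 80, 85, 90, 100)
PAM_INDICES = tuple(range(10, 501, 10))


def available_matrices() -> list[str]:
    """Names accepted by :func:`load_matrix`."""
    return [f"BLOSUM{i}" for i in BLOSUM_INDICES] + [
        f"PAM{i}" for i in PAM_INDICES
    ]


def load_matrix(name: str, rounded: bool = True) -> SubstitutionMatrix:
    """Load a bundled matrix by name (e.g. ``"BLOSUM62"``, ``"PAM250"``).

    Only the rounded (integer) forms are bundled; the non-rounded BLOCKS
    tables are not redistributable here, so ``rounded=False`` raises.
    """
    if not rounded:
        raise FileNotFoundError(
            "non-rounded (BLOCKS database) matrices are not bundled; "
            "parse your own copy with parse_matrix() instead"
        )
    key = name.upper().replace(" ", "")
    path = _DATA / f"{key}.txt"
    try:
        text = path.read_text()
    except (FileNotFoundError, OSError) as exc:
        raise KeyError(
            f"unknown matrix {name!r}; available: {', '.join(available_matrices())}"
        ) from exc
    return parse_matrix(text, name=key)


def blosum_series(in_bits: bool = False) -> list[SubstitutionMatrix]:
    """The bundled BLOSUM series, optionally on a common bit scale."""
    out = [load_matrix(f"BLOSUM{i}") for i in BLOSUM_INDICES]
    return [m.in_bits() for m in out] if in_bits else out


def pam_series(in_bits: bool = False) -> list[SubstitutionMatrix]:
    """The bundled PAM series (PAM10..PAM500 step 10)."""
    out = [load_matrix(f"PAM{i}") for i in PAM_INDICES]
    return [m.in_bits() for m in out] if in_bits else out
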