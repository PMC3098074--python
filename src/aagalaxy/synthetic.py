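"""Generators with known ground truth for exercising every analysis stage.

Two families are provided:

* :func:`random_gram` -- Gram matrices of known centered point sets, plus
  an optional constant shift.  These are the exact oracles for the SVD
  round trip, the shift/translation refinement and the shift-invariance of
  the galaxy: a positively shifted Gram matrix decomposes into the same
  centered point cloud.

* :func:`random_pseudo_matrix` -- pseudo substitution matrices built from
  random symmetric joint distributions ``q_ab`` (Dirichlet-type draw over
  the 210 unordered residue pairs).  Scores are the log-odds
  ``log2(q_ab / (p_a p_b))`` against the marginals ``p``, and the model
  records the mutual information ``sum q_ab log2(q_ab/(p_a p_b))`` -- zero
  exactly at independence, maximal (the marginal entropy) when residues
  always covary.  An ensemble of such draws reproduces, in sign, the
  anti-correlation between matrix mean and mutual information observed for
  the real series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import SubstitutionMatrix
from .residues import N_RESIDUES

__all__ = [
    "SyntheticGram",
    "PseudoMatrixModel",
    "random_gram",
    "random_pseudo_matrix",
    "independent_pseudo_matrix",
]


@dataclass(frozen=True)
class SyntheticGram:
    """Known point set, its (optionally shifted) Gram matrix, and the shift."""

    true_points: np.ndarray
    gram: np.ndarray
    applied_shift: float

    def to_substitution_matrix(self, name: str = "synthetic-gram") -> SubstitutionMatrix:
        if self.gram.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError("only 20-point Gram matrices map onto residues")
        return SubstitutionMatrix(scores=self.gram, name=name)


@dataclass(frozen=True)
class PseudoMatrixModel:
    """Random joint distribution and the pseudo substitution matrix it implies."""

    q: np.ndarray
    p: np.ndarray
    scores: np.ndarray
    mutual_information: float

    def to_substitution_matrix(self, name: str = "pseudo") -> SubstitutionMatrix:
        return SubstitutionMatrix(
            scores=self.scores,
            name=name,
            units="bits",
            relative_entropy=self.mutual_information,
            scale_bits=1.0,
        )

    @property
    def expected_score(self) -> float:
        """Background expectation ``sum_ab p_a p_b s_ab`` (negative whenever
        the mutual information is positive)."""
        return float(self.p @ self.scores @ self.p)


def random_gram(
    n: int = N_RESIDUES, d: int = 5, shift: float = 0.0, seed: int = 0
) -> SyntheticGram:
    """Gram matrix of ``n`` random centered points in ``d`` dimensions,
    shifted by a constant.  Deterministic per seed."""
    if not 1 <= d <= n:
        raise ValueError("need n >= d >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, d))
    pts -= pts.mean(axis=0)
    gram = pts @ pts.T + shift
    gram = (gram + gram.T) / 2.0
    return SyntheticGram(true_points=pts, gram=gram, applied_shift=float(shift))


def random_pseudo_matrix(
    seed: int = 0, concentration: float = 1.0
) -> PseudoMatrixModel:
    """Pseudo substitution matrix from a random symmetric joint distribution.

    A symmetric Dirichlet draw over the 210 unique cells (diagonal plus
    upper triangle) is symmetrized and renormalized over the full 20x20
    table.  ``concentration`` controls how far the draw strays from
    uniformity; any positive value yields a valid model.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(N_RESIDUES)
    cells = rng.gamma(shape=concentration, scale=1.0, size=iu[0].size)
    q = np.zeros((N_RESIDUES, N_RESIDUES))
    q[iu] = cells
    q = q + q.T - np.diag(np.diag(q))
    q /= q.sum()
    return _model_from_q(q)


def independent_pseudo_matrix(p: np.ndarray) -> PseudoMatrixModel:
    """The independence model ``q_ab = p_a p_b`` (zero mutual information)."""
    p = np.asarray(p, dtype=float)
    if p.shape != (N_RESIDUES,) or np.any(p <= 0):
        raise ValueError("p must be 20 positive probabilities")
    p = p / p.sum()
    return _model_from_q(np.outer(p, p))


def _model_from_q(q: np.ndarray) -> PseudoMatrixModel:
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-12:
        raise ValueError("q must be a probability table summing to 1")
    p = q.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = q / np.outer(p, p)
        scores = np.log2(ratio)
    if not np.isfinite(scores).all():
        raise ValueError("zero cells in q make log-odds scores undefined")
    mi = float(np.sum(q * scores))
    return PseudoMatrixModel(
        q=q, p=p, scores=(scores + scores.T) / 2.0, mutual_information=max(mi, 0.0)
    )
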