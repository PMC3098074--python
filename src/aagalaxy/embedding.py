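"""Euclidean amino acid vectors from the SVD of a substitution matrix.

A symmetric score matrix :math:`S` factorizes as
:math:`S = \\sum_K w_K\\, U_K \\otimes V_K` with positive singular values
:math:`w_K` in decreasing order.  For a symmetric matrix each component has
:math:`U_K = \\pm V_K`; components with :math:`U_K = -V_K` correspond to
negative eigenvalues and cannot be realized by real vectors, so they are
dropped.  The retained components give one vector per amino acid,

.. math:: A_{aK} = U_{Ka} \\sqrt{w_K},

whose dot products :math:`A_a \\cdot A_b` approximate :math:`s_{ab}`.

Two refinements are provided:

* centering the matrix before decomposition (the amino acid "galaxy" is
  shift-invariant, and centered matrices are far closer to positive
  semidefinite, so the dot products reconstruct them much better);
* an affine refinement :math:`\\hat s_{ab} = (A_a+T)\\cdot(A_b+T) + shift`
  whose translation :math:`T` and scalar ``shift`` are obtained by exact
  linear least squares (see :func:`fit_shift_translation`).

Reconstruction agreement is measured by a quality index in percent,

.. math:: Q = 100\\,\\bigl(1 - \\|S-\\hat S\\|_F^2 / \\|S\\|_F^2\\bigr),

and by the Pearson correlation over the 210 upper-triangular entries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .galaxy import Galaxy
from .matrices import SubstitutionMatrix, center_matrix, matrix_mean
from .residues import CANONICAL_ORDER, N_RESIDUES

__all__ = [
    "Embedding",
    "ShiftFit",
    "MatrixEmbedder",
    "decompose",
    "gram",
    "quality_index",
    "upper_tri_correlation",
    "fit_shift_translation",
    "center_vectors",
]

#: Default relative tolerance below which a component is rank noise.
RANK_TOL = 1e-10


@dataclass(frozen=True)
class Embedding:
    """Per-residue vectors retained from the SVD of a substitution matrix.

    ``vectors[a, K]`` is the K-th coordinate of residue ``a`` (canonical
    order); columns are ranked by decreasing singular value.
    ``dropped_components`` lists ``(rank, w_K, reason)`` for the omitted
    components (``"negative"`` eigenvalue or below the rank ``"tolerance"``).
    """

    vectors: np.ndarray
    singular_values: np.ndarray
    dropped_components: tuple[tuple[int, float, str], ...]
    source: str = "matrix"
    centered_input: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        w = np.asarray(self.singular_values, dtype=float)
        if v.ndim != 2 or v.shape[1] != w.size:
            raise ValueError("vectors must be (n, R) matching singular values")
        if w.size and (np.any(w <= 0) or np.any(np.diff(w) > 1e-12)):
            raise ValueError("singular values must be positive, non-increasing")
        v.setflags(write=False)
        w.setflags(write=False)
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "singular_values", w)

    @property
    def dimensionality(self) -> int:
        return int(self.vectors.shape[1])

    def all_singular_values(self) -> np.ndarray:
        """Retained and dropped singular values together (decreasing)."""
        ws = list(self.singular_values) + [w for _, w, _ in self.dropped_components]
        return np.sort(np.asarray(ws))[::-1]

    def to_tsv(self) -> str:
        header = "residue\t" + "\t".join(
            f"x{k + 1}" for k in range(self.dimensionality)
        )
        rows = [
            aa + "\t" + "\t".join(f"{x:.6g}" for x in self.vectors[i])
            for i, aa in enumerate(CANONICAL_ORDER)
        ]
        return "\n".join([header, *rows]) + "\n"


@dataclass(frozen=True)
class ShiftFit:
    """Result of the shift+translation refinement of a reconstruction."""

    translation: np.ndarray
    shift: float
    quality: float
    correlation: float
    reconstruction: SubstitutionMatrix
    pinv_fallback: bool = False


def decompose(
    S: SubstitutionMatrix | np.ndarray,
    tol: float = RANK_TOL,
    centered_input: bool | None = None,
) -> Embedding:
    """SVD-factorize *S* into amino acid vectors.

    Components whose left/right singular vectors are opposed (negative
    eigenvalues) are dropped, as are components with
    ``w_K <= tol * w_1`` (rank noise).  Sign ambiguity of each retained
    axis is resolved by making its largest-magnitude coordinate positive.
    """
    if isinstance(S, SubstitutionMatrix):
        scores, source = S.scores, S.name
        if centered_input is None:
            centered_input = abs(matrix_mean(S)) < 1e-9
    else:
        scores = np.asarray(S, dtype=float)
        if not np.allclose(scores, scores.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        scores = (scores + scores.T) / 2.0
        source = "array"
        if centered_input is None:
            centered_input = abs(scores.mean()) < 1e-9
    # For a symmetric matrix the SVD coincides with the eigendecomposition:
    # w_K = |lambda_K|, and U_K = -V_K exactly when lambda_K < 0.
    eigvals, eigvecs = np.linalg.eigh(scores)
    order = np.argsort(-np.abs(eigvals), kind="stable")
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    w = np.abs(eigvals)
    wmax = w[0] if w.size else 0.0
    cols, dropped = [], []
    for rank, (lam, wk) in enumerate(zip(eigvals, w)):
        if wmax > 0 and wk <= tol * wmax:
            dropped.append((rank, float(wk), "tolerance"))
        elif lam < 0:
            dropped.append((rank, float(wk), "negative"))
        else:
            u = eigvecs[:, rank]
            if u[np.abs(u).argmax()] < 0:
                u = -u
            cols.append(u * np.sqrt(wk))
    vectors = (
        np.column_stack(cols) if cols else np.empty((scores.shape[0], 0))
    )
    retained = np.array([wk for rank, wk in enumerate(w)
                         if rank not in {r for r, _, _ in dropped}])
    return Embedding(
        vectors=vectors,
        singular_values=retained,
        dropped_components=tuple(dropped),
        source=source,
        centered_input=bool(centered_input),
    )


def gram(E: Embedding) -> SubstitutionMatrix:
    """Dot-product matrix of the embedding vectors."""
    g = E.vectors @ E.vectors.T
    g = (g + g.T) / 2.0
    return SubstitutionMatrix(scores=g, name=f"{E.source}~gram")


def _scores(S) -> np.ndarray:
    return S.scores if isinstance(S, SubstitutionMatrix) else np.asarray(S, float)


def quality_index(S, S_hat) -> float:
    """Percent agreement ``100 * (1 - ||S - S_hat||_F^2 / ||S||_F^2)``.

    100% iff the reconstruction is exact; can go negative when the
    discrepancy exceeds the norm of the matrix itself.
    """
    s, sh = _scores(S), _scores(S_hat)
    denom = np.linalg.norm(s) ** 2
    if denom == 0:
        raise ValueError("quality index undefined for the zero matrix")
    return float(100.0 * (1.0 - np.linalg.norm(s - sh) ** 2 / denom))


def upper_tri_correlation(S, S_hat) -> float:
    """Pearson correlation over the 210 upper-triangular entries."""
    s, sh = _scores(S), _scores(S_hat)
    iu = np.triu_indices(N_RESIDUES)
    x, y = s[iu], sh[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def center_vectors(E: Embedding) -> tuple[Galaxy, np.ndarray]:
    """Subtract the geometric center from the vector set.

    Returns the centered :class:`~aagalaxy.galaxy.Galaxy` and the centroid
    that was removed.
    """
    centroid = E.vectors.mean(axis=0)
    return Galaxy(points=E.vectors - centroid, source=E.source), centroid


def fit_shift_translation(
    S: SubstitutionMatrix | np.ndarray, E: Embedding
) -> ShiftFit:
    """Least-squares translation + shift refinement of the reconstruction.

    Minimizes ``sum_ab (s_ab - (A_a+T).(A_b+T) - shift)^2``.  At the optimum
    the shift is tied to the matrix mean ``s_mean`` and the translated
    centroid ``c = t + T`` of the vectors by ``shift = s_mean - ||c||^2``;
    substituting it back makes the model exactly linear in ``c``, so the
    translation solves a small linear system (normal equations in the
    centered vector coordinates).
    """
    s = _scores(S)
    n = s.shape[0]
    A = E.vectors
    t = A.mean(axis=0)
    At = A - t
    s_mean = float(s.mean())
    g = s.sum(axis=1) - n * s_mean  # centered row sums
    B = At.T @ At
    rhs = At.T @ g / n
    pinv = False
    if B.size == 0:
        c = np.zeros(0)
    else:
        try:
            c = np.linalg.solve(B, rhs)
        except np.linalg.LinAlgError:
            c = np.linalg.lstsq(B, rhs, rcond=None)[0]
            pinv = True
        if not np.isfinite(c).all() or np.linalg.cond(B) > 1e12:
            c = np.linalg.lstsq(B, rhs, rcond=None)[0]
            pinv = True
    translation = c - t
    shift = s_mean - float(c @ c)
    Ap = A + translation
    recon = Ap @ Ap.T + shift
    recon = (recon + recon.T) / 2.0
    recon_m = SubstitutionMatrix(scores=recon, name=f"{E.source}~refined")
    return ShiftFit(
        translation=translation,
        shift=shift,
        quality=quality_index(s, recon),
        correlation=upper_tri_correlation(s, recon),
        reconstruction=recon_m,
        pinv_fallback=pinv,
    )


class MatrixEmbedder(BaseEstimator):
    """Estimator computing amino acid vectors from a substitution matrix.

    Parameters
    ----------
    center : bool, default True
        Center the matrix (subtract its 400-element mean) before the SVD.
        The centered galaxy is shift-invariant and reconstructs the matrix
        far better than the raw decomposition.
    tol : float, default 1e-10
        Relative rank tolerance passed to :func:`decompose`.
    refine : bool, default False
        Additionally fit the shift+translation refinement against the
        original (uncentered) matrix.

    Attributes
    ----------
    embedding_ : Embedding
    vectors_ : ndarray of shape (20, R)
    singular_values_ : ndarray
    galaxy_ : Galaxy              -- centered vector set
    centroid_ : ndarray           -- centroid removed from the raw vectors
    quality_ : float              -- reconstruction quality (percent) against
                                     the matrix that was decomposed
    correlation_ : float
    shift_fit_ : ShiftFit | None  -- present when ``refine=True``
    """

    def __init__(self, center: bool = True, tol: float = RANK_TOL,
                 refine: bool = False):
        self.center = center
        self.tol = tol
        self.refine = refine

    def fit(self, X: SubstitutionMatrix | np.ndarray, y=None):
        if not isinstance(X, SubstitutionMatrix):
            X = SubstitutionMatrix(scores=np.asarray(X, dtype=float))
        target = center_matrix(X) if self.center else X
        self.matrix_ = X
        self.embedding_ = decompose(target, tol=self.tol)
        self.vectors_ = self.embedding_.vectors
        self.singular_values_ = self.embedding_.singular_values
        self.galaxy_, self.centroid_ = center_vectors(self.embedding_)
        recon = gram(self.embedding_)
        self.quality_ = quality_index(target, recon)
        self.correlation_ = upper_tri_correlation(target, recon)
        self.shift_fit_ = (
            fit_shift_translation(X, self.embedding_) if self.refine else None
        )
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the fitted residue vectors (20 x R)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "vectors_")
        return self.vectors_
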