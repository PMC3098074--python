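"""Similarity-to-distance conversions and distance-based embeddings.

Two classical conversions of a similarity matrix ``s`` into a putative
distance are implemented: the linear form ``d = s_aa + s_bb - 2 s_ab`` and
its square root.  Neither is guaranteed to be a metric -- the triangle
audit counts, over all C(20,3) = 1140 unordered residue triplets, those in
which any of the three triangle inequalities fails.  Three ways of
recovering point coordinates from a distance matrix are provided
(classical Torgerson scaling, direct stress minimization, and maximizing
the anti-correlation between similarities and distances), alongside the
always-metric Euclidean distance computed from the SVD galaxy itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS

from .galaxy import Galaxy
from .matrices import SubstitutionMatrix
from .residues import CANONICAL_ORDER, N_RESIDUES

__all__ = [
    "DistanceMatrix",
    "similarity_to_distance",
    "triangle_violations",
    "TriangleAudit",
    "torgerson_embed",
    "stress_fit",
    "anticorrelation_fit",
    "vector_metric",
    "StressEmbedding",
]

N_TRIPLETS = 1140  # C(20, 3)
_TRI_TOL = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative 20x20 table with zero diagonal."""

    values: np.ndarray
    formula: str = "VECTOR_METRIC"
    source: str = "matrix"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError("expected a 20x20 distance table")
        if np.abs(v - v.T).max() > 1e-9:
            raise ValueError("distance table is not symmetric")
        if np.abs(np.diag(v)).max() > 1e-9:
            raise ValueError("distance diagonal must be zero")
        if v.min() < -1e-9:
            raise ValueError("negative distances")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(
            self.values[CANONICAL_ORDER.index(a), CANONICAL_ORDER.index(b)]
        )


def similarity_to_distance(
    S: SubstitutionMatrix, form: str = "SQRT"
) -> DistanceMatrix:
    """Convert a similarity matrix to ``d = s_aa + s_bb - 2 s_ab``
    (``form="LINEAR"``) or its square root (``form="SQRT"``).

    Raises when the linear expression goes negative (possible for shifted
    matrices), naming the offending pairs.
    """
    form = form.upper()
    if form not in {"LINEAR", "SQRT"}:
        raise ValueError(f"unknown form {form!r}")
    s = S.scores
    diag = np.diag(s)
    lin = diag[:, None] + diag[None, :] - 2.0 * s
    neg = np.argwhere(lin < -_TRI_TOL)
    if neg.size:
        pairs = sorted(
            {
                tuple(sorted((CANONICAL_ORDER[i], CANONICAL_ORDER[j])))
                for i, j in neg
            }
        )
        raise ValueError(
            f"negative distance argument for pairs: "
            + ", ".join("".join(p) for p in pairs[:8])
        )
    lin = np.clip(lin, 0.0, None)
    np.fill_diagonal(lin, 0.0)
    values = np.sqrt(lin) if form == "SQRT" else lin
    return DistanceMatrix(values=values, formula=form, source=S.name)


class TriangleAudit(NamedTuple):
    """Triangle-inequality audit of a distance table.

    ``count``/``fraction`` refer to unordered triplets (out of 1140) in
    which at least one of the three inequalities fails; ``inequality_count``
    and ``inequality_fraction`` count the individual failed inequalities
    (out of 3 x 1140).  Unpacking as ``count, fraction = audit`` works.
    """

    count: int
    fraction: float
    inequality_count: int
    inequality_fraction: float


def triangle_violations(D: DistanceMatrix) -> TriangleAudit:
    """Audit the triangle inequality over all C(20,3) residue triplets.

    A triplet is flagged if any of ``d_ij <= d_ik + d_kj`` (three
    assignments of the middle residue) fails by more than 1e-9; the audit
    also tallies how many individual inequalities fail.
    """
    d = D.values
    triplets = 0
    inequalities = 0
    for i, j, k in combinations(range(N_RESIDUES), 3):
        a, b, c = d[i, j], d[i, k], d[j, k]
        bad = (
            (a > b + c + _TRI_TOL)
            + (b > a + c + _TRI_TOL)
            + (c > a + b + _TRI_TOL)
        )
        if bad:
            triplets += 1
            inequalities += int(bad)
    return TriangleAudit(
        count=triplets,
        fraction=100.0 * triplets / N_TRIPLETS,
        inequality_count=inequalities,
        inequality_fraction=100.0 * inequalities / (3 * N_TRIPLETS),
    )


def torgerson_embed(D: DistanceMatrix, dims: int) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, eigendecomposes it and
    keeps the top ``dims`` components with positive eigenvalues.  If fewer
    positive components exist the result is truncated (zero-padded columns
    are not invented).
    """
    import warnings

    d2 = D.values**2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(-eigvals)
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = int(np.sum(eigvals > 1e-9 * max(eigvals.max(), 1.0)))
    if dims > positive:
        warnings.warn(
            f"only {positive} positive components available, truncating "
            f"from the requested {dims}",
            stacklevel=2,
        )
        dims = positive
    return eigvecs[:, :dims] * np.sqrt(eigvals[:dims])


def _config_distances(X: np.ndarray) -> np.ndarray:
    return pdist(X)


class StressEmbedding(BaseEstimator):
    """Metric-stress embedding of a precomputed distance matrix.

    Thin estimator over :class:`sklearn.manifold.MDS` (SMACOF) with
    deterministic seeding and best-of-``n_init`` restarts.
    """

    def __init__(self, dims: int = 3, seed: int = 0, n_init: int = 20):
        self.dims = dims
        self.seed = seed
        self.n_init = n_init

    def fit(self, D: DistanceMatrix | np.ndarray, y=None):
        values = D.values if isinstance(D, DistanceMatrix) else np.asarray(D)
        mds = MDS(
            n_components=self.dims,
            metric="precomputed",
            init="random",
            n_init=self.n_init,
            max_iter=1000,
            eps=1e-9,
            random_state=self.seed,
            normalized_stress=False,
        )
        self.embedding_ = mds.fit_transform(values)
        self.stress_ = float(mds.stress_)
        return self


def stress_fit(
    D: DistanceMatrix, dims: int, seed: int = 0, restarts: int = 20
) -> np.ndarray:
    """Direct least-squares fit of vector distances to the given distances."""
    if dims < 1:
        raise ValueError("dims must be >= 1")
    return StressEmbedding(dims=dims, seed=seed, n_init=restarts).fit(D).embedding_


def anticorrelation_fit(
    S: SubstitutionMatrix,
    dims: int,
    seed: int = 0,
    restarts: int = 20,
) -> np.ndarray:
    """Point configuration maximizing the negative correlation between
    substitution scores and inter-point distances.

    The objective is the Pearson correlation between the 190 off-diagonal
    scores ``s_ab`` and the configuration distances ``||v_a - v_b||``,
    minimized (made as negative as possible) by gradient-based local
    optimization from ``restarts`` seeded random starts.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    s = S.scores[np.triu_indices(N_RESIDUES, k=1)]
    s_c = s - s.mean()
    s_norm = np.linalg.norm(s_c)
    rng = np.random.default_rng(seed)

    def objective(flat: np.ndarray) -> float:
        X = flat.reshape(N_RESIDUES, dims)
        d = _config_distances(X)
        d_c = d - d.mean()
        dn = np.linalg.norm(d_c)
        if dn == 0:
            return 1.0
        return float(s_c @ d_c / (s_norm * dn))

    best, best_val = None, np.inf
    for _ in range(restarts):
        x0 = rng.standard_normal(N_RESIDUES * dims)
        res = minimize(objective, x0, method="L-BFGS-B")
        if res.fun < best_val:
            best_val, best = float(res.fun), res.x
    return best.reshape(N_RESIDUES, dims)


def vector_metric(G: Galaxy) -> DistanceMatrix:
    """Pairwise Euclidean distances between the galaxy's residue vectors.

    Positivity, symmetry and the triangle inequality hold by construction.
    """
    return DistanceMatrix(
        values=squareform(pdist(G.points)),
        formula="VECTOR_METRIC",
        source=G.source,
    )
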