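"""Geometry and statistics of the centered amino acid vector set.

The 20 residue vectors obtained from a (centered) substitution matrix form
a point cloud -- the amino acid "galaxy".  This module measures its radius
(mean distance of the residues from the centroid), superposes galaxies from
different matrices by a multidimensional orthogonal Procrustes fit,
clusters residues by k-means in the full retained dimensionality, and
tabulates matrix mean / relative entropy / galaxy radius across a matrix
series together with their pairwise correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import svd as _svd
from sklearn.cluster import KMeans

from .matrices import SubstitutionMatrix, matrix_mean
from .residues import CANONICAL_ORDER, N_RESIDUES

__all__ = [
    "Galaxy",
    "SuperpositionResult",
    "ClusterPartition",
    "galaxy_radius",
    "superpose",
    "cluster_residues",
    "series_summary",
]


@dataclass(frozen=True)
class Galaxy:
    """A centered set of labeled points (one per residue, canonical order)."""

    points: np.ndarray
    source: str = "matrix"

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2:
            raise ValueError("points must be a 2-D array")
        p.setflags(write=False)
        object.__setattr__(self, "points", p)

    @property
    def dimensionality(self) -> int:
        return int(self.points.shape[1])

    @property
    def radius(self) -> float:
        return galaxy_radius(self)

    def vector(self, residue: str) -> np.ndarray:
        return self.points[CANONICAL_ORDER.index(residue.upper())]


@dataclass(frozen=True)
class SuperpositionResult:
    """Orthogonal (optionally scaled) map of one galaxy onto another."""

    orthogonal_map: np.ndarray
    scale: float
    rmsd: float


@dataclass(frozen=True)
class ClusterPartition:
    """k-means partition of the residues."""

    k: int
    assignment: dict[str, int]
    inertia: float

    def groups(self) -> list[frozenset[str]]:
        """Clusters as residue sets, ordered by cluster id."""
        out: list[set[str]] = [set() for _ in range(self.k)]
        for aa, cid in self.assignment.items():
            out[cid].add(aa)
        return [frozenset(g) for g in out]


def galaxy_radius(G: Galaxy) -> float:
    """Mean Euclidean distance of the points from their centroid."""
    centered = G.points - G.points.mean(axis=0)
    return float(np.linalg.norm(centered, axis=1).mean())


def _pad(points: np.ndarray, dims: int) -> np.ndarray:
    if points.shape[1] == dims:
        return points
    out = np.zeros((points.shape[0], dims))
    out[:, : points.shape[1]] = points
    return out


def superpose(
    A: Galaxy,
    B: Galaxy,
    allow_scaling: bool = False,
    allow_reflection: bool = True,
) -> SuperpositionResult:
    """Least-squares orthogonal map of *A* onto *B* over matched residues.

    Galaxies of unequal dimensionality are zero-padded to a common space
    (the unique isometric choice).  With ``allow_reflection=False`` the map
    is restricted to proper rotations (Kabsch); otherwise any orthogonal
    transform is admitted -- appropriate when comparing SVD galaxies, whose
    axes carry arbitrary signs.
    """
    d = max(A.dimensionality, B.dimensionality)
    X = _pad(A.points - A.points.mean(axis=0), d)
    Y = _pad(B.points - B.points.mean(axis=0), d)
    U, sig, Vt = _svd(X.T @ Y)
    signs = np.ones(d)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        signs[-1] = -1.0
    R = (U * signs) @ Vt
    trace = float(sig @ signs)
    normX = float(np.sum(X**2))
    scale = trace / normX if (allow_scaling and normX > 0) else 1.0
    resid = scale * X @ R - Y
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SuperpositionResult(orthogonal_map=R, scale=scale, rmsd=rmsd)


def cluster_residues(
    G: Galaxy, k: int, seed: int = 0, restarts: int = 50
) -> ClusterPartition:
    """Best-of-``restarts`` k-means partition of the 20 residues.

    Cluster ids are relabelled in order of first appearance along the
    canonical residue order, so the partition is deterministic given the
    seed.
    """
    if not 2 <= k <= N_RESIDUES:
        raise ValueError(f"k must be in [2, 20], got {k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(G.points)
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel)
    assignment = {
        aa: relabel[lab] for aa, lab in zip(CANONICAL_ORDER, labels)
    }
    return ClusterPartition(k=k, assignment=assignment, inertia=float(km.inertia_))


def series_summary(
    matrices: list[SubstitutionMatrix], use_bit_scale: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean, relative entropy and galaxy radius across a matrix series.

    Returns ``(table, correlations)``: one row per matrix, and the 3x3
    Pearson correlation table of the statistics across the series.  With
    ``use_bit_scale=True`` matrices carrying a scale annotation are first
    converted to bit units so means and radii are comparable across
    matrices printed at different fractional-bit scales.
    """
    from .embedding import center_vectors, decompose  # local: avoid cycle
    from .matrices import center_matrix

    if len(matrices) < 3:
        raise ValueError("need at least 3 matrices for a series summary")
    missing = [m.name for m in matrices if m.relative_entropy is None]
    if missing:
        raise ValueError(
            "matrices lack relative_entropy metadata: " + ", ".join(missing)
        )
    rows = []
    for m in matrices:
        mb = m.in_bits() if (use_bit_scale and m.scale_bits) else m
        galaxy, _ = center_vectors(decompose(center_matrix(mb)))
        rows.append(
            {
                "name": m.name,
                "index": m.index,
                "mean": matrix_mean(mb),
                "entropy": m.relative_entropy,
                "radius": galaxy_radius(galaxy),
            }
        )
    table = pd.DataFrame(rows)
    stats = table[["mean", "entropy", "radius"]]
    if (stats.std() == 0).any():
        raise ValueError("degenerate series: a statistic has zero variance")
    return table, stats.corr()
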