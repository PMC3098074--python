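"""Physicochemical property axes in the amino acid vector space.

A scalar property (hydrophobicity, charge, mass, ...) assigns one number
:math:`p_a` to each residue.  After centering and scaling the 20 values to
unit Euclidean norm, the best one-dimensional representation of the galaxy
by that property is the line through the origin minimizing

.. math:: \\sum_a \\| \\lambda p_a \\hat n - \\tilde A_a \\|^2,

whose optimal direction is the property-weighted vector sum
:math:`\\hat n \\propto \\sum_a p_a \\tilde A_a` and whose optimal scale is
:math:`\\lambda = \\|\\sum_a p_a \\tilde A_a\\|` (the weights' self-sum is 1
because the property is centered and normalized).  The *contribution* of the
property to the matrix is the spread of the scaled property values along the
line relative to the total spread of the galaxy,

.. math::
   C = 100\\, \\lambda^2 \\Big/ \\sum_a \\|\\tilde A_a\\|^2 ,

bounded above by the share of the leading SVD component,
:math:`100\\, w_1 / \\sum_K w_K`.

The bundled table ships 17 property scales keyed by short names
(``1rsvol`` ... ``17mass``); see the CSV header for per-scale provenance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .embedding import Embedding
from .galaxy import Galaxy
from .residues import CANONICAL_ORDER, N_RESIDUES

__all__ = [
    "PropertyScale",
    "PropertyProjection",
    "normalize_property",
    "fit_property_axis",
    "contribution",
    "max_contribution",
    "random_property_baseline",
    "load_property_scales",
]


@dataclass(frozen=True)
class PropertyScale:
    """A 20-value scalar property in canonical residue order."""

    name: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_RESIDUES,):
            raise ValueError("a property scale needs exactly 20 values")
        if not np.isfinite(v).all():
            raise ValueError(f"{self.name}: non-finite property values")
        if self.normalized:
            if abs(v.mean()) > 1e-12 or abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError(
                    f"{self.name}: flagged normalized but not centered/unit-norm"
                )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def value(self, residue: str) -> float:
        return float(self.values[CANONICAL_ORDER.index(residue.upper())])


@dataclass(frozen=True)
class PropertyProjection:
    """Fitted property axis: unit direction, scale and contribution."""

    axis: np.ndarray
    scale: float
    contribution: float
    projections: np.ndarray
    property_name: str = "property"


def normalize_property(raw, name: str = "property") -> PropertyScale:
    """Center the 20 raw values and scale them to unit Euclidean norm."""
    v = np.asarray(raw, dtype=float)
    if v.shape != (N_RESIDUES,):
        raise ValueError("expected 20 values")
    v = v - v.mean()
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError(f"{name}: constant property has no direction")
    return PropertyScale(name=name, values=v / norm, normalized=True)


def _spread(G: Galaxy) -> float:
    centered = G.points - G.points.mean(axis=0)
    return float(np.sum(centered**2))


def fit_property_axis(G: Galaxy, p: PropertyScale) -> PropertyProjection:
    """Best-fit axis of property *p* in galaxy *G* (see module docstring)."""
    if not p.normalized:
        p = normalize_property(p.values, p.name)
    pts = G.points - G.points.mean(axis=0)
    m = pts.T @ p.values
    lam = float(np.linalg.norm(m))
    if lam < 1e-12:
        raise ValueError(
            f"{p.name}: degenerate weighted vector sum, no axis direction"
        )
    axis = m / lam
    spread = _spread(G)
    contrib = 100.0 * lam**2 / spread if spread > 0 else 0.0
    return PropertyProjection(
        axis=axis,
        scale=lam,
        contribution=float(contrib),
        projections=lam * p.values,
        property_name=p.name,
    )


def contribution(proj: PropertyProjection, G: Galaxy) -> float:
    """Percent of the galaxy's spatial spread explained along the axis."""
    spread = _spread(G)
    if spread == 0:
        raise ValueError("galaxy has zero spread")
    return float(100.0 * proj.scale**2 / spread)


def max_contribution(E: Embedding | Galaxy) -> float:
    """Upper limit of any property contribution: the leading component's
    share ``100 * w_1 / sum_K w_K`` of the total spread."""
    if isinstance(E, Embedding):
        w = E.singular_values
    else:
        pts = E.points - E.points.mean(axis=0)
        w = np.linalg.svd(pts, compute_uv=False) ** 2
        w = w[w > 1e-12 * (w[0] if w.size else 1.0)]
    if w.size == 0:
        raise ValueError("embedding has no retained components")
    return float(100.0 * w[0] / w.sum())


def random_property_baseline(
    G: Galaxy, n: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Contribution of a random centered, normalized pseudo-property.

    Draws ``n`` standard-normal 20-vectors, centers and normalizes each,
    and returns the mean and standard deviation of their contributions.
    """
    if n < 2:
        raise ValueError("need at least 2 draws")
    rng = np.random.default_rng(seed)
    pts = G.points - G.points.mean(axis=0)
    spread = float(np.sum(pts**2))
    draws = rng.standard_normal((n, N_RESIDUES))
    draws -= draws.mean(axis=1, keepdims=True)
    draws /= np.linalg.norm(draws, axis=1, keepdims=True)
    lam2 = np.sum((draws @ pts) ** 2, axis=1)
    contribs = 100.0 * lam2 / spread
    return float(contribs.mean()), float(contribs.std(ddof=1))


_PROPERTY_CSV = resources.files("aagalaxy.data") / "property_scales.csv"


def load_property_scales(normalized: bool = False) -> dict[str, PropertyScale]:
    """The 17 bundled property scales, keyed by short name.

    With ``normalized=True`` each scale is centered and unit-normalized,
    ready for :func:`fit_property_axis`.
    """
    text = _PROPERTY_CSV.read_text()
    rows = [
        r
        for r in csv.reader(
            ln for ln in text.splitlines() if not ln.startswith("#")
        )
        if r
    ]
    header = rows[0]
    order = [header.index(aa) for aa in CANONICAL_ORDER]
    out: dict[str, PropertyScale] = {}
    for row in rows[1:]:
        name = row[0]
        values = np.array([float(row[i]) for i in order])
        scale = PropertyScale(name=name, values=values)
        out[name] = normalize_property(values, name) if normalized else scale
    return out
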