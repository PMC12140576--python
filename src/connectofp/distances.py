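"""Correlation distance between connectomes and the labeled distance matrix.

Because FCs (and their tangent images) are symmetric, distances are
computed on the n(n-1)/2 strictly-upper-triangular entries only, in fixed
row-major order. The correlation distance is one minus the Pearson
correlation of those two vectors, so it lies in [0, 2]: 0 for identical
patterns, 2 for perfectly anticorrelated ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .connectivity import FCMatrix
from .spd import TangentFC, geodesic_distance

__all__ = [
    "DistanceMatrix",
    "upper_triangle_vector",
    "correlation_distance",
    "pairwise_distances",
]

METHODS = ("tangent", "non_tangent", "geodesic")


@dataclass
class DistanceMatrix:
    """m x m pairwise distances with (subject, session, condition) labels."""

    values: np.ndarray
    row_labels: list[tuple[str, str, str]]
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.row_labels) != v.shape[0]:
            raise ValueError("labels must match matrix size")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12:
            raise ValueError("distances must be nonnegative")
        if self.method != "geodesic" and v.max() > 2.0 + 1e-10:
            raise ValueError("correlation distances cannot exceed 2")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def subjects(self) -> list[str]:
        return [lab[0] for lab in self.row_labels]


def upper_triangle_vector(x) -> np.ndarray:
    """Strictly-upper-triangle entries in row-major order
    (x_{0,1}, x_{0,2}, ..., x_{n-2,n-1})."""
    a = x.values if isinstance(x, (FCMatrix, TangentFC)) else np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be a square matrix")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least a 2x2 matrix")
    return a[np.triu_indices(n, k=1)]


def correlation_distance(x1, x2) -> float:
    """1 - Pearson correlation of the two upper-triangle vectors."""
    v1 = upper_triangle_vector(x1)
    v2 = upper_triangle_vector(x2)
    if v1.shape != v2.shape:
        raise ValueError("matrices must share a shape")
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("constant upper triangle: correlation distance undefined")
    r = np.corrcoef(v1, v2)[0, 1]
    return float(1.0 - r)


def pairwise_distances(items: Sequence, method: str, lam: float = 1.0) -> DistanceMatrix:
    """All-pairs distance matrix over a homogeneous list of connectomes.

    ``tangent``: correlation distance between TangentFC items, which must
    all share one reference. ``non_tangent``: correlation distance between
    FCMatrix items. ``geodesic``: affine-invariant distance between
    FCMatrix items with lambda*I regularisation.

    Each unordered pair is evaluated once and mirrored; the diagonal is
    zero; labels are preserved in input order.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if len(items) < 2:
        raise ValueError("need at least two items")
    if method == "tangent":
        if not all(isinstance(it, TangentFC) for it in items):
            raise TypeError("tangent method expects TangentFC items")
        refs = {it.reference_id for it in items}
        if len(refs) > 1:
            raise ValueError(f"mixed tangent references: {sorted(refs)}")
    labels = [it.key for it in items]
    m = len(items)
    d = np.zeros((m, m))
    if method in ("tangent", "non_tangent"):
        v = np.stack([upper_triangle_vector(it) for it in items])
        sd = v.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0).tolist()
            raise ValueError(f"constant upper triangle in items {bad}")
        d = 1.0 - np.corrcoef(v)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    else:
        for i, j in combinations(range(m), 2):
            d[i, j] = d[j, i] = geodesic_distance(items[i], items[j], lam=lam)
    return DistanceMatrix(values=d, row_labels=labels, method=method)
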