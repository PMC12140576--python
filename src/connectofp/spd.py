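"""Geometry of the SPD manifold for functional connectomes.

Correlation matrices live on a curved manifold (the compact elliptope
inside the SPD cone), so Euclidean comparisons between them are biased.
This module provides the geometry-aware primitives: symmetric matrix
functions through the eigendecomposition, identity-shift regularisation
``C + lambda*I``, the log-Euclidean mean used as the projection reference

    C_ref = expm( (1/N) sum_i logm(P_i + lambda*I) ),

the tangent-space projection at that reference

    Q = logm( C_ref^{-1/2} P C_ref^{-1/2} ),

and the affine-invariant geodesic distance

    delta(P1, P2) = || logm( P1^{-1/2} P2 P1^{-1/2} ) ||_F
                  = sqrt( sum_k log^2 eig_k(P2, P1) ).

All matrix functions go through the symmetric eigensolver, never a general
matrix-function routine: inputs are symmetric by invariant, and the
symmetric path is stable and guarantees real outputs.

Rank-deficient FCs (short recordings) make the raw matrix log undefined;
the mean therefore regularises each input before its log (reducing to the
plain formula for PD inputs at lambda = 0), and the projection exposes an
eigenvalue floor applied to the whitened matrix before the log, recorded
on each TangentFC for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass
from hashlib import sha1
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .connectivity import FCMatrix

__all__ = [
    "ReferencePoint",
    "TangentFC",
    "sym_eig_apply",
    "regularize",
    "log_euclidean_mean",
    "tangent_project",
    "tangent_unproject",
    "geodesic_distance",
]

_SYM_TOL = 1e-8


@dataclass
class ReferencePoint:
    """The SPD reference matrix C_ref at which the tangent space is erected."""

    values: np.ndarray
    lambda_used: float
    source_ids: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.abs(v - v.T).max() > _SYM_TOL:
            raise ValueError("reference must be symmetric")
        v = (v + v.T) / 2.0
        lo = np.linalg.eigvalsh(v).min()
        if lo <= 0:
            raise ValueError(f"reference must be strictly PD (min eig {lo:.2e})")
        self.values = v
        self.source_ids = tuple(self.source_ids)

    @property
    def key(self) -> str:
        """Stable short identifier of the reference matrix content."""
        return sha1(np.ascontiguousarray(self.values).tobytes()).hexdigest()[:12]


@dataclass
class TangentFC:
    """Tangent-space image Q of an FC; symmetric, eigenvalues of any sign."""

    values: np.ndarray
    reference_id: str
    subject_id: str
    session_id: str
    condition: str
    eigenvalue_floor_used: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("tangent matrix must be symmetric")
        self.values = (v + v.T) / 2.0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.session_id, self.condition)


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, (FCMatrix, ReferencePoint, TangentFC)):
        return x.values
    return np.asarray(x, dtype=float)


def sym_eig_apply(m, f: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Apply a scalar function to a symmetric matrix through its spectrum.

    For f = log every eigenvalue must be strictly positive (after any floor
    applied by the caller).
    """
    a = _as_matrix(m)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be square")
    if np.abs(a - a.T).max() > _SYM_TOL:
        raise ValueError("input must be symmetric")
    w, v = np.linalg.eigh((a + a.T) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fw = f(w)
    if not np.all(np.isfinite(fw)):
        raise ValueError(
            f"matrix function produced non-finite values "
            f"(min eigenvalue {w.min():.3e})"
        )
    out = (v * fw) @ v.T
    return (out + out.T) / 2.0


def _logm(a: np.ndarray) -> np.ndarray:
    lo = np.linalg.eigvalsh(a).min()
    if lo <= 0:
        raise ValueError(f"matrix log undefined: min eigenvalue {lo:.3e} <= 0")
    return sym_eig_apply(a, np.log)


def _expm(a: np.ndarray) -> np.ndarray:
    return sym_eig_apply(a, np.exp)


def regularize(c, lam: float) -> np.ndarray:
    """Identity-shift regularisation C + lambda*I (raises every eigenvalue
    by exactly lambda)."""
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    a = _as_matrix(c)
    return a + lam * np.eye(a.shape[0])


def log_euclidean_mean(
    fcs: Sequence, lam: float = 1.0, regularize_inputs: bool = True
) -> ReferencePoint:
    """Log-Euclidean mean of a set of FCs, used as the tangent reference.

    With ``regularize_inputs`` (default) each P_i is shifted by lambda*I
    before its matrix log, which keeps the mean defined for rank-deficient
    FCs and reduces to the unregularised mean at lambda = 0. With the flag
    off, raw logs are taken (inputs must be PD) and lambda*I is added to the
    final mean instead.
    """
    if len(fcs) == 0:
        raise ValueError("cannot average an empty FC list")
    mats = [_as_matrix(f) for f in fcs]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all FCs must share one dimension")
    if regularize_inputs:
        logs = [_logm(regularize(m, lam)) for m in mats]
        ref = _expm(np.mean(logs, axis=0))
    else:
        logs = [_logm(m) for m in mats]
        ref = regularize(_expm(np.mean(logs, axis=0)), lam)
    ids = tuple(f.key for f in fcs if isinstance(f, FCMatrix))
    return ReferencePoint(values=ref, lambda_used=lam, source_ids=ids)


def tangent_project(p, ref: ReferencePoint, eigenvalue_floor: float = 1e-6) -> TangentFC:
    """Project an FC onto the tangent space at the reference.

    Whitens P by the reference (W = C_ref^{-1/2} P C_ref^{-1/2}), floors
    W's eigenvalues at ``eigenvalue_floor`` (if > 0) and takes the matrix
    log. A zero floor with a nonpositive whitened eigenvalue is an error;
    raise the floor or use a larger regularisation when building the
    reference.
    """
    if eigenvalue_floor < 0:
        raise ValueError("eigenvalue_floor must be nonnegative")
    pv = _as_matrix(p)
    inv_sqrt = sym_eig_apply(ref.values, lambda w: w ** -0.5)
    w_mat = inv_sqrt @ pv @ inv_sqrt
    w_mat = (w_mat + w_mat.T) / 2.0
    w, v = np.linalg.eigh(w_mat)
    if eigenvalue_floor > 0:
        w = np.maximum(w, eigenvalue_floor)
    elif w.min() <= 0:
        raise ValueError(
            f"whitened FC has nonpositive eigenvalue {w.min():.3e}; "
            "set eigenvalue_floor > 0 or increase lambda"
        )
    q = (v * np.log(w)) @ v.T
    meta = p if isinstance(p, FCMatrix) else None
    return TangentFC(
        values=(q + q.T) / 2.0,
        reference_id=ref.key,
        subject_id=meta.subject_id if meta else "",
        session_id=meta.session_id if meta else "",
        condition=meta.condition if meta else "",
        eigenvalue_floor_used=eigenvalue_floor,
    )


def tangent_unproject(q, ref: ReferencePoint) -> np.ndarray:
    """Inverse projection P = C_ref^{1/2} expm(Q) C_ref^{1/2} (exact for a
    zero floor)."""
    sqrt = sym_eig_apply(ref.values, np.sqrt)
    p = sqrt @ _expm(_as_matrix(q)) @ sqrt
    return (p + p.T) / 2.0


def geodesic_distance(p1, p2, lam: float = 1.0) -> float:
    """Affine-invariant geodesic distance after lambda*I regularisation of
    both inputs.

    Computed from the generalized eigenvalues of (P2 + lambda*I, P1 +
    lambda*I), which are the eigenvalues of the whitened matrix
    P1^{-1/2} P2 P1^{-1/2}.
    """
    a = regularize(_as_matrix(p1), lam)
    b = regularize(_as_matrix(p2), lam)
    if a.shape != b.shape:
        raise ValueError("matrices must share a shape")
    w = scipy.linalg.eigh(b, a, eigvals_only=True)
    if w.min() <= 0:
        raise ValueError(
            f"nonpositive generalized eigenvalue {w.min():.3e} after "
            f"regularisation lambda={lam}; increase lambda"
        )
    return float(np.sqrt(np.sum(np.log(w) ** 2)))
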