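"""Correlation functional connectomes from (masked) recordings.

An FC is the matrix of pairwise zero-lag Pearson correlations between
region time courses, computed after censored frames are removed. Kept
frames are concatenated in their original order; zero-lag correlation is
unaffected by the resulting gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import Recording

__all__ = ["FCMatrix", "apply_mask", "correlation_fc", "restrict_to_subnetwork"]


@dataclass
class FCMatrix:
    """Symmetric PSD correlation matrix with unit diagonal, plus provenance.

    Invariants (enforced at construction): symmetric, diagonal exactly 1,
    entries in [-1, 1], eigenvalues >= -1e-8.
    """

    values: np.ndarray
    region_labels: tuple[str, ...]
    subject_id: str
    session_id: str
    condition: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC values must be a square matrix")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym >= 1e-10:
            raise ValueError(f"FC not symmetric (max asymmetry {asym:.2e})")
        v = (v + v.T) / 2.0
        if np.abs(np.diag(v) - 1.0).max() > 1e-12:
            raise ValueError("FC diagonal must be 1")
        if v.min() < -1.0 - 1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("FC entries must lie in [-1, 1]")
        lo = np.linalg.eigvalsh(v).min()
        if lo < -1e-8:
            raise ValueError(f"FC not PSD (min eigenvalue {lo:.2e})")
        self.values = v
        self.region_labels = tuple(self.region_labels)
        if len(self.region_labels) != v.shape[0]:
            raise ValueError("region_labels length must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.session_id, self.condition)


def apply_mask(recording: Recording) -> Recording:
    """Drop censored frames, keeping survivors in original order.

    The returned recording has an all-ones mask. A missing or
    length-mismatched mask is an error naming the recording (length checks
    happen at Recording construction).
    """
    if recording.mask is None:
        raise ValueError(
            f"recording ({recording.subject_id}, {recording.session_id}, "
            f"{recording.condition}) has no temporal mask"
        )
    keep = recording.mask.astype(bool)
    data = recording.data[:, keep]
    return replace(recording, data=data, mask=np.ones(data.shape[1], dtype=int))


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"r{i}" for i in range(n))


def correlation_fc(
    recording: Recording, region_labels: tuple[str, ...] | None = None
) -> FCMatrix:
    """Pairwise Pearson correlation FC of a recording.

    A mask, if present, is applied first. The result is symmetrised and its
    diagonal pinned to exactly 1 to suppress floating-point drift. Regions
    with zero variance over the kept frames are an error (all FCs must share
    dimensions, so silent dropping is not allowed).
    """
    rec = apply_mask(recording) if recording.mask is not None else recording
    data = rec.data
    n, t = data.shape
    if t < 2:
        raise ValueError(f"need at least 2 frames to correlate, got {t}")
    sd = data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance regions {dead.tolist()} in recording "
            f"({rec.subject_id}, {rec.session_id}, {rec.condition})"
        )
    p = np.corrcoef(data)
    p = np.clip((p + p.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(p, 1.0)
    return FCMatrix(
        values=p,
        region_labels=region_labels or _default_labels(n),
        subject_id=rec.subject_id,
        session_id=rec.session_id,
        condition=rec.condition,
    )


def restrict_to_subnetwork(fc: FCMatrix, roi_indices) -> FCMatrix:
    """Principal submatrix of an FC on an ordered region-index list.

    Identical to correlating the restricted time series, since Pearson
    correlations are pairwise.
    """
    idx = list(roi_indices)
    if len(idx) < 2:
        raise ValueError("subnetwork restriction needs at least 2 regions")
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate region index in subnetwork")
    for i in idx:
        if not 0 <= i < fc.n:
            raise ValueError(f"region index {i} out of range for {fc.n} regions")
    sub = fc.values[np.ix_(idx, idx)]
    return FCMatrix(
        values=sub,
        region_labels=tuple(fc.region_labels[i] for i in idx),
        subject_id=fc.subject_id,
        session_id=fc.session_id,
        condition=fc.condition,
    )
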