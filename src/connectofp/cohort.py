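"""Synthetic multi-subject resting/task cohort generator.

Emulates the structure of a precision-imaging study: ``N`` subjects scanned
over ``S`` sessions under one or more conditions, each recording being a
parcellated region x time BOLD-like matrix plus a binary temporal censoring
mask (motion/fixation scrubbing). Subject identity is encoded as a
subject-specific latent correlation structure; sessions add a fresh random
perturbation of that structure; task conditions add a shared latent signal
to a configured subset of regions.

The generative model works directly in covariance space. Each latent
covariance is low-rank-plus-diagonal (``A A^T + I`` with Gaussian factors),
renormalised to a correlation matrix, which guarantees strict positive
definiteness and produces the block-like structure typical of functional
connectomes. Subject structure mixes a cohort-shared component with a
per-subject component under the *distinctiveness* weight; each session
mixes the subject structure with a per-session component under the
*session_noise* weight.

Every quantity is a deterministic function of the config seed and the
(subject, session, condition) indices, via named SeedSequence spawn keys,
so cohorts are bit-reproducible and individual recordings can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConditionSpec",
    "CohortConfig",
    "Recording",
    "make_subject_structure",
    "simulate_session",
    "simulate_mask",
    "generate_cohort",
]

# named RNG substreams
_SHARED, _SUBJECT, _SESSION, _MASK = 0, 1, 2, 3


@dataclass(frozen=True)
class ConditionSpec:
    """A recording condition: a tag, a modulation strength in [0, 1] and the
    region indices receiving the shared task signal."""

    name: str
    modulation: float = 0.0
    regions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation <= 1.0:
            raise ValueError(f"modulation must be in [0, 1], got {self.modulation}")


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic cohort.

    Defaults emulate a 9-subject x 10-session resting-state design with a
    strong subject fingerprint (distinctiveness 0.8), mild session
    variability (0.2) and 28% frame censoring, at a desk-scale parcellation
    of 30 regions and 300 frames per session.
    """

    n_subjects: int = 9
    n_sessions: int = 10
    n_regions: int = 30
    n_frames: int = 300
    distinctiveness: float = 0.8
    session_noise: float = 0.2
    conditions: tuple[ConditionSpec, ...] = (ConditionSpec("rest"),)
    censor_fraction: float = 0.28
    latent_rank: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("need at least one subject and one session")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if not 0.0 <= self.distinctiveness <= 1.0:
            raise ValueError("distinctiveness must be in [0, 1]")
        if not 0.0 <= self.session_noise <= 1.0:
            raise ValueError("session_noise must be in [0, 1]")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must be in [0, 1)")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        for c in self.conditions:
            for r in c.regions:
                if not 0 <= r < self.n_regions:
                    raise ValueError(
                        f"condition {c.name!r}: region index {r} out of range"
                    )

    def subject_label(self, i: int) -> str:
        return f"S{i + 1:02d}"

    def session_label(self, j: int) -> str:
        return f"ses{j + 1:02d}"


@dataclass
class Recording:
    """One (subject, session, condition) parcellated time series.

    ``data`` is regions x frames; ``mask`` (if present) is a 0/1 keep-vector
    over frames, 1 meaning the frame survives censoring.
    """

    subject_id: str
    session_id: str
    condition: str
    data: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D regions x frames matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=int)
            if self.mask.shape != (self.data.shape[1],):
                raise ValueError(
                    f"mask length {self.mask.shape} does not match "
                    f"{self.data.shape[1]} frames for recording "
                    f"({self.subject_id}, {self.session_id}, {self.condition})"
                )
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask entries must be 0 or 1")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.session_id, self.condition)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _normalize_correlation(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise AssertionError("covariance has non-positive diagonal")
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _lowrank_correlation(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    """Low-rank-plus-diagonal covariance A A^T + I, scaled to unit diagonal."""
    a = rng.standard_normal((n, rank))
    cov = a @ a.T + np.eye(n)
    return _normalize_correlation(cov)


def make_subject_structure(config: CohortConfig, subject_index: int) -> np.ndarray:
    """Subject-specific latent correlation structure.

    Convex mix of one cohort-shared and one per-subject low-rank-plus-diagonal
    correlation matrix under the distinctiveness weight, renormalised to unit
    diagonal. At distinctiveness 0 all subjects share one structure (no
    identity signal); at 1 each subject is fully idiosyncratic.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    delta = config.distinctiveness
    shared = _lowrank_correlation(
        _rng(config.seed, _SHARED), config.n_regions, config.latent_rank
    )
    unique = _lowrank_correlation(
        _rng(config.seed, _SUBJECT, subject_index),
        config.n_regions,
        config.latent_rank,
    )
    structure = _normalize_correlation((1.0 - delta) * shared + delta * unique)
    assert np.linalg.eigvalsh(structure).min() > 0, "structure lost definiteness"
    return structure


def simulate_mask(
    t_raw: int, censor_fraction: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Binary keep-vector with floor(censor_fraction * t_raw) zeros placed
    uniformly without replacement."""
    if not 0.0 <= censor_fraction < 1.0:
        raise ValueError(f"censor_fraction must be in [0, 1), got {censor_fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = np.ones(t_raw, dtype=int)
    n_zero = int(np.floor(censor_fraction * t_raw))
    if n_zero > 0:
        mask[rng.choice(t_raw, size=n_zero, replace=False)] = 0
    return mask


def simulate_session(
    structure: np.ndarray,
    config: CohortConfig,
    subject_index: int,
    session_index: int,
    condition_index: int = 0,
) -> Recording:
    """Draw one session's recording from the subject structure.

    The session covariance is a convex mix of the subject structure and a
    fresh per-session low-rank-plus-diagonal correlation matrix under the
    session_noise weight; frames are i.i.d. zero-mean Gaussian. A nonzero
    condition modulation adds a shared unit-variance latent signal, scaled
    by the modulation strength, to the condition's region set. A censoring
    mask is attached (not applied).
    """
    structure = np.asarray(structure, dtype=float)
    if structure.shape != (config.n_regions, config.n_regions):
        raise ValueError("structure shape does not match config.n_regions")
    if not np.allclose(structure, structure.T, atol=1e-10):
        raise ValueError("structure must be symmetric")
    cond = config.conditions[condition_index]
    rng = _rng(config.seed, _SESSION, subject_index, session_index, condition_index)
    rho = config.session_noise
    session_corr = _lowrank_correlation(rng, config.n_regions, config.latent_rank)
    cov = _normalize_correlation((1.0 - rho) * structure + rho * session_corr)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - PD by construction
        raise ValueError(
            f"degenerate session covariance for subject {subject_index}, "
            f"session {session_index}: {exc}"
        ) from exc
    data = chol @ rng.standard_normal((config.n_regions, config.n_frames))
    if cond.modulation > 0 and cond.regions:
        signal = rng.standard_normal(config.n_frames)
        data[list(cond.regions), :] += cond.modulation * signal
    mask = simulate_mask(
        config.n_frames,
        config.censor_fraction,
        _rng(config.seed, _MASK, subject_index, session_index, condition_index),
    )
    return Recording(
        subject_id=config.subject_label(subject_index),
        session_id=config.session_label(session_index),
        condition=cond.name,
        data=data,
        mask=mask,
    )


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """All n_subjects x n_sessions x |conditions| recordings, subject-major,
    fully reproducible from the config."""
    recordings = []
    for i in range(config.n_subjects):
        structure = make_subject_structure(config, i)
        for j in range(config.n_sessions):
            for c in range(len(config.conditions)):
                recordings.append(simulate_session(structure, config, i, j, c))
    return recordings
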