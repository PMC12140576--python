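"""Experiment drivers for connectome fingerprinting studies.

Each driver consumes a list of Recordings plus an ExperimentConfig and runs
one study end to end: whole-cohort fingerprinting under a chosen distance
method, the cross-condition reference grid, per-subnetwork fingerprinting,
the recording-length bootstrap, database-style subject identification,
session-to-session drift, and the within- vs between-session block
analysis. For the tangent method the reference is always rebuilt in the
same (windowed, restricted, database-only) space as the FCs being compared.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .cohort import Recording
from .connectivity import FCMatrix, apply_mask, correlation_fc, restrict_to_subnetwork
from .distances import DistanceMatrix, pairwise_distances
from .metrics import ClassifierResult, classifier_result, split_intra_inter
from .spd import log_euclidean_mean, tangent_project

__all__ = [
    "ExperimentConfig",
    "SubnetworkDefinition",
    "compute_fcs",
    "build_distance_matrix",
    "run_fingerprint",
    "cross_reference_grid",
    "subnetwork_fingerprint",
    "subsample_auc",
    "database_identification",
    "drift_analysis",
    "session_block_analysis",
    "DriftResult",
    "BlockResult",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs shared by the experiment drivers.

    method: distance method (tangent / non_tangent / geodesic).
    lam: identity-shift regularisation lambda (default 1).
    eigenvalue_floor: spectrum floor for the tangent projection.
    reference_condition: which condition's FCs build C_ref (None = all).
    min_subnetwork_size: subnetworks below this region count are dropped.
    window_halfwidth: l in the 2l+1 recording-length bootstrap.
    database_k: known FCs per subject in identification.
    n_identification_trials: identification repetitions (default 100).
    n_blocks: blocks per session in the block analysis.
    seed: root seed for every stochastic driver.
    """

    method: str = "tangent"
    lam: float = 1.0
    eigenvalue_floor: float = 1e-6
    reference_condition: str | None = None
    min_subnetwork_size: int = 10
    window_halfwidth: int | None = None
    database_k: int = 1
    n_identification_trials: int = 100
    n_blocks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("tangent", "non_tangent", "geodesic"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.min_subnetwork_size < 1 or self.database_k < 1:
            raise ValueError("counts must be positive")
        if self.window_halfwidth is not None and self.window_halfwidth < 1:
            raise ValueError("window halfwidth l must be >= 1")
        if self.n_identification_trials < 1 or self.n_blocks < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class SubnetworkDefinition:
    """Named resting-state subnetwork given by its region indices."""

    name: str
    roi_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.roi_indices)) != len(self.roi_indices):
            raise ValueError(f"subnetwork {self.name!r} has duplicate indices")

    @property
    def size(self) -> int:
        return len(self.roi_indices)


def compute_fcs(recordings: Sequence[Recording]) -> list[FCMatrix]:
    """Masked correlation FC for every recording."""
    return [correlation_fc(r) for r in recordings]


def _reference_fcs(fcs: Sequence[FCMatrix], config: ExperimentConfig):
    if config.reference_condition is None:
        return list(fcs)
    chosen = [f for f in fcs if f.condition == config.reference_condition]
    if not chosen:
        raise ValueError(
            f"no FCs with reference condition {config.reference_condition!r}"
        )
    return chosen


def build_distance_matrix(
    fcs: Sequence[FCMatrix],
    config: ExperimentConfig,
    reference_fcs: Sequence[FCMatrix] | None = None,
) -> DistanceMatrix:
    """Distance matrix over FCs under the configured method.

    For the tangent method the reference is the log-Euclidean mean of
    ``reference_fcs`` (defaults to the config's reference condition, or all
    FCs) and all FCs are projected at it before the correlation distance.
    """
    if config.method == "tangent":
        ref_set = (
            list(reference_fcs)
            if reference_fcs is not None
            else _reference_fcs(fcs, config)
        )
        ref = log_euclidean_mean(ref_set, lam=config.lam)
        tans = [tangent_project(f, ref, config.eigenvalue_floor) for f in fcs]
        return pairwise_distances(tans, "tangent")
    if config.method == "non_tangent":
        return pairwise_distances(fcs, "non_tangent")
    return pairwise_distances(fcs, "geodesic", lam=config.lam)


def run_fingerprint(
    recordings: Sequence[Recording], config: ExperimentConfig
) -> ClassifierResult:
    """Whole-cohort fingerprinting: FCs, distances, threshold sweep."""
    fcs = compute_fcs(recordings)
    d = build_distance_matrix(fcs, config)
    return classifier_result(split_intra_inter(d))


def cross_reference_grid(
    recordings: Sequence[Recording], config: ExperimentConfig
) -> pd.DataFrame:
    """Tangent-method AUC and Delta for every (target condition, reference
    condition) pair: targets are projected at a reference built only from
    the reference condition's FCs."""
    fcs = compute_fcs(recordings)
    conditions = sorted({f.condition for f in fcs})
    rows = []
    for ref_cond in conditions:
        ref_set = [f for f in fcs if f.condition == ref_cond]
        ref = log_euclidean_mean(ref_set, lam=config.lam)
        for target_cond in conditions:
            targets = [f for f in fcs if f.condition == target_cond]
            tans = [tangent_project(f, ref, config.eigenvalue_floor) for f in targets]
            res = classifier_result(
                split_intra_inter(pairwise_distances(tans, "tangent"))
            )
            rows.append(
                {
                    "target_condition": target_cond,
                    "reference_condition": ref_cond,
                    "auc": res.auc_roc,
                    "delta": res.delta,
                }
            )
    return pd.DataFrame(rows)


def subnetwork_fingerprint(
    recordings: Sequence[Recording],
    atlas: Sequence[SubnetworkDefinition],
    config: ExperimentConfig,
) -> pd.DataFrame:
    """Per-subnetwork fingerprinting AUC, for tangent and non-tangent
    methods, separately per condition.

    Subnetworks smaller than ``min_subnetwork_size`` are dropped; the
    tangent reference is rebuilt inside each restricted space.
    """
    fcs = compute_fcs(recordings)
    conditions = sorted({f.condition for f in fcs})
    kept = [s for s in atlas if s.size >= max(config.min_subnetwork_size, 2)]
    rows = []
    for subnet in kept:
        sub_fcs = [restrict_to_subnetwork(f, subnet.roi_indices) for f in fcs]
        for method in ("tangent", "non_tangent"):
            cfg = replace(config, method=method)
            for cond in conditions:
                cond_fcs = [f for f in sub_fcs if f.condition == cond]
                d = build_distance_matrix(cond_fcs, replace(cfg, reference_condition=None))
                res = classifier_result(split_intra_inter(d))
                rows.append(
                    {
                        "subnetwork": subnet.name,
                        "method": method,
                        "condition": cond,
                        "auc": res.auc_roc,
                    }
                )
    return pd.DataFrame(rows)


def _masked(recordings: Sequence[Recording]) -> list[Recording]:
    return [apply_mask(r) if r.mask is not None else r for r in recordings]


def subsample_auc(
    recordings: Sequence[Recording], l: int, config: ExperimentConfig
) -> tuple[float, float, int]:
    """Bootstrap AUC from random (2l+1)-frame windows of each recording.

    Per trial every recording independently contributes one window centred
    at a uniformly drawn frame with l-frame margins (in post-censoring
    frame order); FCs and, for the tangent method, the reference are
    rebuilt from the windows alone. The trial count is floor(L / 2l) with
    L the shortest censored recording. Returns (mean AUC, sd, n_trials).
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    kept = _masked(recordings)
    lengths = [r.n_frames for r in kept]
    big_l = min(lengths)
    if 2 * l + 1 > big_l:
        shortest = kept[int(np.argmin(lengths))]
        raise ValueError(
            f"window 2l+1={2 * l + 1} exceeds shortest recording "
            f"{shortest.key} with {big_l} kept frames"
        )
    n_trials = max(1, big_l // (2 * l))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(100, l)))
    aucs = []
    for _ in range(n_trials):
        windows = []
        for r in kept:
            c = int(rng.integers(l, r.n_frames - l))
            windows.append(replace(r, data=r.data[:, c - l : c + l + 1], mask=None))
        fcs = compute_fcs(windows)
        d = build_distance_matrix(fcs, config)
        res = classifier_result(split_intra_inter(d))
        aucs.append(res.auc_roc)
    aucs = np.asarray(aucs)
    sd = float(aucs.std(ddof=1)) if n_trials > 1 else 0.0
    return float(aucs.mean()), sd, n_trials


def database_identification(
    recordings: Sequence[Recording], k: int, config: ExperimentConfig
) -> float:
    """Success rate of nearest-mean-distance subject identification.

    Per trial: k FCs per subject form the known database; for the tangent
    method the reference is the log-Euclidean mean of the N*k database FCs
    only; one target is drawn from the remainder and assigned to the
    subject with the lowest mean distance to its k database FCs (ties going
    to the lowest subject label). Returns the success fraction over
    ``n_identification_trials`` trials.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fcs = compute_fcs(recordings)
    subjects = sorted({f.subject_id for f in fcs})
    by_subject = {s: [i for i, f in enumerate(fcs) if f.subject_id == s] for s in subjects}
    min_sessions = min(len(v) for v in by_subject.values())
    if k >= min_sessions:
        raise ValueError(
            f"k={k} must be below the smallest per-subject session count "
            f"({min_sessions})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(200, k)))
    successes = 0
    for _ in range(config.n_identification_trials):
        db_idx: dict[str, np.ndarray] = {
            s: rng.choice(by_subject[s], size=k, replace=False) for s in subjects
        }
        db_all = np.concatenate([db_idx[s] for s in subjects])
        pool = np.setdiff1d(np.arange(len(fcs)), db_all)
        target = int(rng.choice(pool))
        truth = fcs[target].subject_id
        if config.method == "tangent":
            ref = log_euclidean_mean([fcs[i] for i in db_all], lam=config.lam)
            proj = {
                i: tangent_project(fcs[i], ref, config.eigenvalue_floor)
                for i in np.append(db_all, target)
            }
            items = lambda i: proj[i]  # noqa: E731
            dist_method = "tangent"
        else:
            items = lambda i: fcs[i]  # noqa: E731
            dist_method = config.method
        means = []
        for s in subjects:
            pair = [items(target)] + [items(int(i)) for i in db_idx[s]]
            d = pairwise_distances(pair, dist_method, lam=config.lam)
            means.append(d.values[0, 1:].mean())
        predicted = subjects[int(np.argmin(means))]
        successes += predicted == truth
    return successes / config.n_identification_trials


@dataclass
class DriftResult:
    """Distance from each subject's first session at each session lag."""

    lags: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    slope: float | None
    p_value: float | None


def drift_analysis(
    recordings: Sequence[Recording], config: ExperimentConfig, n_permutations: int = 999
) -> DriftResult:
    """Session-to-session drift: per subject, the distance from the first
    session's FC to each later session's, averaged across subjects per lag,
    with a permutation test (lags shuffled within subject) on the pooled
    least-squares slope."""
    fcs = compute_fcs(recordings)
    d = build_distance_matrix(fcs, config)
    sessions = sorted({lab[1] for lab in d.row_labels})
    if len(sessions) < 2:
        raise ValueError("drift analysis needs >= 2 sessions")
    subjects = sorted({lab[0] for lab in d.row_labels})
    index = {lab: i for i, lab in enumerate(d.row_labels)}
    per_subject = []
    for s in subjects:
        conds = sorted({lab[2] for lab in d.row_labels if lab[0] == s})
        cond = conds[0]
        base = index[(s, sessions[0], cond)]
        per_subject.append(
            [d.values[base, index[(s, ses, cond)]] for ses in sessions[1:]]
        )
    dists = np.asarray(per_subject)  # subjects x lags
    lags = np.arange(1, len(sessions))
    mean = dists.mean(axis=0)
    sd = dists.std(axis=0, ddof=1) if len(subjects) > 1 else np.zeros_like(mean)
    if len(lags) < 2:
        return DriftResult(lags=lags, mean=mean, sd=sd, slope=None, p_value=None)
    x = np.tile(lags, len(subjects)).astype(float)
    y = dists.ravel()
    slope = float(np.polyfit(x, y, 1)[0])
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(300,)))
    hits = 0
    for _ in range(n_permutations):
        perm = np.concatenate([rng.permutation(lags) for _ in subjects]).astype(float)
        b = np.polyfit(perm, y, 1)[0]
        hits += abs(b) >= abs(slope)
    p = (1 + hits) / (1 + n_permutations)
    return DriftResult(lags=lags, mean=mean, sd=sd, slope=slope, p_value=float(p))


@dataclass
class BlockResult:
    """Within- vs between-session distances of per-block FCs."""

    within_mean: float
    between_mean: float
    p_value: float
    n_within: int
    n_between: int


def session_block_analysis(
    recordings: Sequence[Recording], n_blocks: int, config: ExperimentConfig
) -> BlockResult:
    """Split each recording's kept frames into equal contiguous blocks,
    build per-block FCs, and compare within-subject distances between
    blocks of the same session against blocks of different sessions
    (two-sided Mann-Whitney)."""
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    kept = _masked(recordings)
    block_recs = []
    for r in kept:
        size = r.n_frames // n_blocks
        if size < 2:
            raise ValueError(
                f"recording {r.key} too short ({r.n_frames} frames) for "
                f"{n_blocks} blocks of >= 2 frames"
            )
        for b in range(n_blocks):
            block_recs.append(
                Recording(
                    subject_id=r.subject_id,
                    session_id=r.session_id,
                    condition=f"{r.condition}#b{b}",
                    data=r.data[:, b * size : (b + 1) * size],
                    mask=None,
                )
            )
    fcs = compute_fcs(block_recs)
    d = build_distance_matrix(fcs, replace(config, reference_condition=None))
    within, between = [], []
    for i in range(d.m):
        si, sesi, _ = d.row_labels[i]
        for j in range(i + 1, d.m):
            sj, sesj, _ = d.row_labels[j]
            if si != sj:
                continue
            (within if sesi == sesj else between).append(d.values[i, j])
    if not within or not between:
        raise ValueError("need both within- and between-session block pairs")
    stat = scipy.stats.mannwhitneyu(within, between, alternative="two-sided")
    return BlockResult(
        within_mean=float(np.mean(within)),
        between_mean=float(np.mean(between)),
        p_value=float(stat.pvalue),
        n_within=len(within),
        n_between=len(between),
    )
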