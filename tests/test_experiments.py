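"""Experiment drivers: fingerprinting runs, reference grids, subnetworks,
recording-length bootstrap, database identification, drift and blocks."""

import numpy as np
import pytest

from connectofp import (
    CohortConfig,
    ConditionSpec,
    ExperimentConfig,
    Recording,
    SubnetworkDefinition,
    cross_reference_grid,
    database_identification,
    drift_analysis,
    generate_cohort,
    make_subject_structure,
    run_fingerprint,
    session_block_analysis,
    simulate_session,
    subnetwork_fingerprint,
    subsample_auc,
)


def test_fingerprint_is_deterministic(small_cohort):
    cfg = ExperimentConfig(method="tangent", seed=11)
    a = run_fingerprint(small_cohort, cfg)
    b = run_fingerprint(small_cohort, cfg)
    assert a.auc_roc == b.auc_roc and a.delta == b.delta
    np.testing.assert_array_equal(a.thresholds, b.thresholds)


def test_strong_cohort_separates_perfectly(small_cohort):
    res = run_fingerprint(small_cohort, ExperimentConfig(method="tangent"))
    assert res.auc_roc == pytest.approx(1.0)
    assert res.delta > 0


@pytest.fixture(scope="module")
def two_condition_cohort():
    cfg = CohortConfig(
        n_subjects=4,
        n_sessions=3,
        n_regions=16,
        n_frames=100,
        conditions=(
            ConditionSpec("rest"),
            ConditionSpec("motor", 0.6, tuple(range(6))),
        ),
        seed=21,
    )
    return generate_cohort(cfg)


def test_cross_reference_grid_shape_and_single_condition(small_cohort, two_condition_cohort):
    cfg = ExperimentConfig(seed=21)
    grid = cross_reference_grid(two_condition_cohort, cfg)
    assert len(grid) == 4  # |C| x |C|
    assert set(grid.target_condition) == {"rest", "motor"}
    single = cross_reference_grid(small_cohort, ExperimentConfig(seed=11))
    assert len(single) == 1
    whole = run_fingerprint(small_cohort, ExperimentConfig(seed=11))
    assert single.auc.iloc[0] == pytest.approx(whole.auc_roc)
    assert single.delta.iloc[0] == pytest.approx(whole.delta)


def test_subnetwork_filter_and_whole_brain_equivalence(small_cohort):
    atlas = [
        SubnetworkDefinition("ALL", tuple(range(20))),
        SubnetworkDefinition("tiny", (0, 1, 2, 3)),
    ]
    cfg = ExperimentConfig(seed=11)
    table = subnetwork_fingerprint(small_cohort, atlas, cfg)
    assert "tiny" not in set(table.subnetwork)  # below the 10-node filter
    whole = run_fingerprint(small_cohort, ExperimentConfig(method="tangent", seed=11))
    row = table[(table.subnetwork == "ALL") & (table.method == "tangent")]
    assert row.auc.iloc[0] == pytest.approx(whole.auc_roc)


def test_subnetwork_with_identity_signal_outperforms_noise_block():
    """Only the first 10 regions carry subject structure; a pure-noise block
    of regions cannot fingerprint."""
    rng = np.random.default_rng(5)
    cfg = CohortConfig(
        n_subjects=5, n_sessions=4, n_regions=10, n_frames=150,
        censor_fraction=0.0, seed=5,
    )
    recordings = []
    for rec in generate_cohort(cfg):
        noise = rng.standard_normal((10, rec.n_frames))
        recordings.append(
            Recording(
                rec.subject_id, rec.session_id, rec.condition,
                np.vstack([rec.data, noise]), mask=None,
            )
        )
    atlas = [
        SubnetworkDefinition("structured", tuple(range(10))),
        SubnetworkDefinition("noise", tuple(range(10, 20))),
    ]
    table = subnetwork_fingerprint(recordings, atlas, ExperimentConfig(seed=5))
    by = table[table.method == "tangent"].set_index("subnetwork").auc
    assert by["structured"] > by["noise"]
    assert abs(by["noise"] - 0.5) < 0.2


def test_subsample_window_and_trial_arithmetic():
    cfg = CohortConfig(
        n_subjects=3, n_sessions=3, n_regions=12, n_frames=100,
        censor_fraction=0.0, seed=8,
    )
    recs = generate_cohort(cfg)
    mean, sd, n_trials = subsample_auc(recs, 5, ExperimentConfig(seed=8))
    assert n_trials == 10  # floor(L / 2l) with L = 100
    assert 0 <= mean <= 1 and sd >= 0


def test_subsample_rejects_oversized_window():
    cfg = CohortConfig(
        n_subjects=2, n_sessions=2, n_regions=8, n_frames=30,
        censor_fraction=0.0, seed=8,
    )
    with pytest.raises(ValueError, match="shortest"):
        subsample_auc(generate_cohort(cfg), 20, ExperimentConfig(seed=8))


def test_database_identification_perfect_on_strong_cohort(small_cohort):
    cfg = ExperimentConfig(method="tangent", n_identification_trials=30, seed=11)
    assert database_identification(small_cohort, 1, cfg) == 1.0


def test_database_identification_single_subject_trivial():
    cfg = CohortConfig(n_subjects=1, n_sessions=4, n_regions=10, n_frames=80, seed=3)
    recs = generate_cohort(cfg)
    rate = database_identification(
        recs, 1, ExperimentConfig(method="non_tangent", n_identification_trials=10)
    )
    assert rate == 1.0


def test_database_identification_rejects_large_k(small_cohort):
    with pytest.raises(ValueError, match="k="):
        database_identification(small_cohort, 4, ExperimentConfig())


def test_drift_stationary_cohort_rarely_rejects():
    """Sessions are exchangeable, so the slope test is null calibrated."""
    rejections = 0
    for seed in range(12):
        cfg = CohortConfig(
            n_subjects=4, n_sessions=6, n_regions=12, n_frames=80, seed=seed
        )
        res = drift_analysis(
            generate_cohort(cfg),
            ExperimentConfig(method="tangent", seed=seed),
            n_permutations=499,
        )
        rejections += res.p_value < 0.05
    assert rejections <= 2


def test_drift_detects_increasing_session_noise():
    """Sessions drawn with growing session-noise weight drift away from the
    first session."""
    base = CohortConfig(
        n_subjects=5, n_sessions=6, n_regions=14, n_frames=120,
        censor_fraction=0.0, seed=17,
    )
    recordings = []
    for i in range(base.n_subjects):
        structure = make_subject_structure(base, i)
        for j in range(base.n_sessions):
            cfg_j = CohortConfig(
                n_subjects=base.n_subjects, n_sessions=base.n_sessions,
                n_regions=base.n_regions, n_frames=base.n_frames,
                censor_fraction=0.0, session_noise=0.05 + 0.15 * j, seed=17,
            )
            recordings.append(simulate_session(structure, cfg_j, i, j, 0))
    res = drift_analysis(
        recordings, ExperimentConfig(method="tangent", seed=17), n_permutations=499
    )
    assert res.slope > 0
    assert res.p_value < 0.05


def test_drift_single_lag_has_no_slope():
    cfg = CohortConfig(n_subjects=3, n_sessions=2, n_regions=10, n_frames=80, seed=2)
    res = drift_analysis(generate_cohort(cfg), ExperimentConfig(method="non_tangent"))
    assert res.lags.size == 1
    assert res.slope is None and res.p_value is None


def test_session_blocks_detect_session_perturbation(small_cohort):
    res = session_block_analysis(
        small_cohort, 2, ExperimentConfig(method="tangent", seed=11)
    )
    assert res.within_mean < res.between_mean
    assert res.p_value < 0.05
    # 4 sessions x 2 blocks per subject: C(2,1) within pairs per session
    assert res.n_within == 5 * 4 * 1


def test_session_blocks_reject_short_recordings():
    cfg = CohortConfig(n_subjects=2, n_sessions=2, n_regions=6, n_frames=10,
                       censor_fraction=0.0, seed=1)
    with pytest.raises(ValueError, match="too short"):
        session_block_analysis(generate_cohort(cfg), 8, ExperimentConfig())


def test_experiment_config_validation():
    with pytest.raises(ValueError):
        ExperimentConfig(method="euclid")
    with pytest.raises(ValueError):
        ExperimentConfig(window_halfwidth=0)
    with pytest.raises(ValueError):
        ExperimentConfig(database_k=0)
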