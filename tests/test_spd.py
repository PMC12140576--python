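"""SPD geometry: matrix functions, log-Euclidean mean, projection, geodesic.

Independent oracles: scipy.linalg.logm / expm (general Schur-based matrix
functions) cross-check the symmetric-eigensolver path.
"""

import numpy as np
import pytest
import scipy.linalg

from connectofp import (
    ReferencePoint,
    geodesic_distance,
    log_euclidean_mean,
    regularize,
    sym_eig_apply,
    tangent_project,
    tangent_unproject,
)
from conftest import random_spd


def test_log_of_identity_is_zero():
    np.testing.assert_allclose(sym_eig_apply(np.eye(3), np.log), 0.0, atol=1e-14)


def test_log_of_diagonal():
    out = sym_eig_apply(np.diag([np.e, 1.0]), np.log)
    np.testing.assert_allclose(out, np.diag([1.0, 0.0]), atol=1e-14)


def test_matrix_functions_match_general_oracle(rng):
    """Symmetric-path log/exp agree with scipy's general matrix functions."""
    a = random_spd(rng, 5)
    np.testing.assert_allclose(
        sym_eig_apply(a, np.log), scipy.linalg.logm(a), atol=1e-10
    )
    np.testing.assert_allclose(
        sym_eig_apply(a, np.exp), scipy.linalg.expm(a), atol=1e-8
    )


def test_exp_log_roundtrip_up_to_high_condition(rng):
    for cond in (10.0, 1e3, 1e6):
        a = random_spd(rng, 6, cond=cond)
        back = sym_eig_apply(sym_eig_apply(a, np.log), np.exp)
        rel = np.linalg.norm(back - a) / np.linalg.norm(a)
        assert rel < 1e-8


def test_sym_eig_apply_rejects_asymmetric():
    with pytest.raises(ValueError, match="symmetric"):
        sym_eig_apply(np.array([[1.0, 2.0], [0.0, 1.0]]), np.log)


def test_log_rejects_singular():
    with pytest.raises(ValueError):
        sym_eig_apply(np.diag([1.0, 0.0]), np.log)


def test_regularize_shifts_spectrum(rng):
    a = random_spd(rng, 4)
    np.testing.assert_array_equal(regularize(a, 0.0), a)
    w0 = np.linalg.eigvalsh(a)
    w1 = np.linalg.eigvalsh(regularize(a, 2.5))
    np.testing.assert_allclose(w1, w0 + 2.5, atol=1e-10)
    np.testing.assert_array_equal(regularize(np.eye(3), 10.0), 11.0 * np.eye(3))
    with pytest.raises(ValueError):
        regularize(a, -0.1)


def test_mean_of_single_matrix_is_itself(rng):
    a = random_spd(rng, 4)
    ref = log_euclidean_mean([a], lam=0.0)
    np.testing.assert_allclose(ref.values, a, atol=1e-8)


def test_mean_of_commuting_diagonals_is_geometric():
    a, b = np.diag([1.0, 4.0]), np.diag([9.0, 1.0])
    ref = log_euclidean_mean([a, b], lam=0.0)
    np.testing.assert_allclose(ref.values, np.diag([3.0, 2.0]), atol=1e-10)


def test_mean_matches_general_matrix_function_oracle(rng):
    mats = [random_spd(rng, 4) for _ in range(3)]
    ref = log_euclidean_mean(mats, lam=0.0)
    oracle = scipy.linalg.expm(np.mean([scipy.linalg.logm(m) for m in mats], axis=0))
    np.testing.assert_allclose(ref.values, oracle, atol=1e-8)


def test_mean_of_copies_is_the_matrix(rng):
    a = random_spd(rng, 5)
    ref = log_euclidean_mean([a] * 4, lam=0.0)
    np.testing.assert_allclose(ref.values, a, atol=1e-8)


def test_mean_regularization_modes(rng):
    """Input-side regularisation handles rank-deficient matrices; the
    output-side mode requires PD inputs."""
    u = rng.standard_normal((5, 2))
    singular = u @ u.T  # rank 2
    ref = log_euclidean_mean([singular, np.eye(5)], lam=1.0)
    assert np.linalg.eigvalsh(ref.values).min() > 0
    with pytest.raises(ValueError):
        log_euclidean_mean([singular], lam=1.0, regularize_inputs=False)
    with pytest.raises(ValueError):
        log_euclidean_mean([], lam=1.0)


def test_projection_of_reference_is_zero(rng):
    a = random_spd(rng, 5)
    ref = ReferencePoint(a, lambda_used=0.0)
    q = tangent_project(a, ref, eigenvalue_floor=0.0)
    np.testing.assert_allclose(q.values, 0.0, atol=1e-10)


def test_projection_at_identity_is_matrix_log(rng):
    a = random_spd(rng, 4)
    ref = ReferencePoint(np.eye(4), lambda_used=0.0)
    q = tangent_project(a, ref, eigenvalue_floor=0.0)
    np.testing.assert_allclose(q.values, sym_eig_apply(a, np.log), atol=1e-10)


def test_projection_commuting_diagonal_case():
    ref = ReferencePoint(np.eye(2), lambda_used=0.0)
    q = tangent_project(np.diag([4.0, 1.0]), ref, eigenvalue_floor=0.0)
    np.testing.assert_allclose(q.values, np.diag([np.log(4.0), 0.0]), atol=1e-12)


def test_projection_is_invertible_without_floor(rng):
    p = random_spd(rng, 6)
    ref = ReferencePoint(random_spd(rng, 6), lambda_used=0.0)
    q = tangent_project(p, ref, eigenvalue_floor=0.0)
    back = tangent_unproject(q, ref)
    assert np.linalg.norm(back - p) / np.linalg.norm(p) < 1e-8


def test_projection_floor_handles_rank_deficiency(rng):
    u = rng.standard_normal((5, 2))
    p = u @ u.T
    ref = ReferencePoint(np.eye(5), lambda_used=0.0)
    with pytest.raises(ValueError, match="floor"):
        tangent_project(p, ref, eigenvalue_floor=0.0)
    q = tangent_project(p, ref, eigenvalue_floor=1e-6)
    assert np.all(np.isfinite(q.values))
    assert q.eigenvalue_floor_used == 1e-6


def test_geodesic_self_distance_zero(rng):
    a = random_spd(rng, 4)
    assert geodesic_distance(a, a, lam=0.0) == pytest.approx(0.0, abs=1e-8)


def test_geodesic_known_diagonal_value():
    d = geodesic_distance(np.eye(2), np.diag([np.e**2, 1.0]), lam=0.0)
    assert d == pytest.approx(2.0, abs=1e-12)


def test_geodesic_symmetry_and_nonnegativity(rng):
    for _ in range(10):
        a, b = random_spd(rng, 4), random_spd(rng, 4)
        d1, d2 = geodesic_distance(a, b, 0.0), geodesic_distance(b, a, 0.0)
        assert d1 >= 0
        assert d1 == pytest.approx(d2, abs=1e-8)


def test_geodesic_affine_invariance(rng):
    for _ in range(10):
        p1, p2 = random_spd(rng, 4), random_spd(rng, 4)
        a = rng.standard_normal((4, 4)) + 0.5 * np.eye(4)
        d0 = geodesic_distance(p1, p2, lam=0.0)
        d1 = geodesic_distance(a @ p1 @ a.T, a @ p2 @ a.T, lam=0.0)
        assert d1 == pytest.approx(d0, abs=1e-8 * max(1.0, d0))


def test_geodesic_triangle_inequality_spot_check(rng):
    for _ in range(10):
        a, b, c = (random_spd(rng, 4) for _ in range(3))
        dab = geodesic_distance(a, b, 0.0)
        dbc = geodesic_distance(b, c, 0.0)
        dac = geodesic_distance(a, c, 0.0)
        assert dac <= dab + dbc + 1e-10


def test_geodesic_finite_across_lambda_grid_for_singular_inputs(rng):
    u, v = rng.standard_normal((6, 2)), rng.standard_normal((6, 2))
    p1, p2 = u @ u.T, v @ v.T
    vals = [geodesic_distance(p1, p2, lam) for lam in (0.1, 1.0, 10.0)]
    assert all(np.isfinite(v) for v in vals)
    # continuity in lambda: a small perturbation moves the distance a little
    base = geodesic_distance(p1, p2, 1.0)
    near = geodesic_distance(p1, p2, 1.0 + 1e-6)
    assert abs(near - base) < 1e-3
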