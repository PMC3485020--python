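import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import limbloads as ll
from limbloads._quat import from_axis_angle, qmul, to_matrix
from limbloads.kinematics import (UnitQuaternionSeries, absolute_orientation,
                                  apply_axial_rotation,
                                  differentiate_quaternions, filter_series,
                                  joint_angles_zxy, relative_orientation)

RATE = 200.0


# ---------------------------------------------------------------- Horn pose

def test_horn_identity():
    ref = np.array([[0.1, 0, 0], [0, 0.2, 0], [0, 0, 0.3], [0.1, 0.1, 0.1]])
    q, t = absolute_orientation(ref, ref)
    np.testing.assert_allclose(q, [1, 0, 0, 0], atol=1e-12)
    np.testing.assert_allclose(t, 0.0, atol=1e-12)


def test_horn_quarter_turn_about_z():
    ref = np.array([[0.1, 0, 0], [0, 0.2, 0], [0, 0, 0.3], [0.05, 0.05, 0]])
    Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    q, t = absolute_orientation(ref, ref @ Rz.T)
    np.testing.assert_allclose(q, [np.sqrt(2) / 2, 0, 0, np.sqrt(2) / 2],
                               atol=1e-12)


def test_horn_errors():
    ref = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        absolute_orientation(ref, ref)
    with pytest.raises(ValueError, match="point counts"):
        absolute_orientation(np.zeros((4, 3)), np.zeros((3, 3)))


def test_horn_beats_euler_grid_search_on_noisy_cloud():
    """Closed-form least squares vs a 0.1-degree local Euler grid search."""
    rng = np.random.default_rng(42)
    ref = rng.uniform(-0.1, 0.1, (6, 3))
    true = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
    obs = ref @ true.as_matrix().T + rng.normal(0, 1e-3, (6, 3))
    q, t = absolute_orientation(ref, obs)
    R_hat = to_matrix(q)
    resid = np.sum((ref @ R_hat.T + t - obs) ** 2)
    base = Rotation.from_matrix(R_hat).as_euler("xyz", degrees=True)
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)
    grid = np.arange(-1.0, 1.0001, 0.1)
    best = np.inf
    for dx in grid:
        for dy in grid:
            for dz in grid:
                R = Rotation.from_euler("xyz", base + [dx, dy, dz],
                                        degrees=True).as_matrix()
                best = min(best, np.sum((ref_c @ R.T - obs_c) ** 2))
    assert resid <= best + 1e-12


def test_horn_agrees_with_scipy_align_vectors():
    rng = np.random.default_rng(3)
    ref = rng.uniform(-0.2, 0.2, (5, 3))
    true = Rotation.random(random_state=7)
    obs = ref @ true.as_matrix().T + rng.normal(0, 5e-4, (5, 3))
    q, _ = absolute_orientation(ref, obs)
    est, _ = Rotation.align_vectors(obs - obs.mean(0), ref - ref.mean(0))
    np.testing.assert_allclose(to_matrix(q), est.as_matrix(), atol=1e-9)


# ------------------------------------------------------------------- filter

@pytest.mark.parametrize("mode", ["woltring", "butterworth"])
def test_filter_dc_gain_unity(mode):
    x = np.full(400, 3.7)
    y = filter_series(x, 10.0, RATE, mode=mode)
    np.testing.assert_allclose(y, x, atol=1e-9)


@pytest.mark.parametrize("mode", ["woltring", "butterworth"])
def test_filter_passband_and_stopband(mode):
    t = np.arange(1200) / RATE
    for freq, check in ((1.0, lambda a: a > 0.99), (50.0, lambda a: a < 0.10)):
        x = np.sin(2 * np.pi * freq * t)
        y = filter_series(x, 10.0, RATE, mode=mode)
        amp = np.max(np.abs(y[200:-200]))
        assert check(amp), f"{mode} at {freq} Hz -> amplitude {amp}"


def test_filter_preserves_quadratic_trend():
    t = np.arange(300) / RATE
    x = 2.0 + 3.0 * t - 4.0 * t**2
    y = filter_series(x, 10.0, RATE, mode="woltring")
    np.testing.assert_allclose(y, x, atol=1e-8)


def test_filter_input_validation():
    with pytest.raises(ValueError, match="twice the cutoff"):
        filter_series(np.zeros(100), 10.0, 15.0)
    with pytest.raises(ValueError, match="warm-up"):
        filter_series(np.zeros(5), 10.0, 200.0)


# -------------------------------------------------------------- derivatives

def _spin_series(rate=RATE, n=200, omega=2.0, alpha=0.0):
    t = np.arange(n) / rate
    ang = omega * t + 0.5 * alpha * t * t
    q = np.stack([np.cos(ang / 2), np.zeros(n), np.zeros(n),
                  np.sin(ang / 2)], axis=1)
    return UnitQuaternionSeries(q=q, origin=np.zeros((n, 3)), dt=1.0 / rate)


def test_constant_orientation_has_zero_rates():
    q = np.tile([1.0, 0, 0, 0], (50, 1))
    s = differentiate_quaternions(
        UnitQuaternionSeries(q=q, origin=np.zeros((50, 3)), dt=0.005))
    np.testing.assert_allclose(s.omega, 0.0, atol=1e-14)
    np.testing.assert_allclose(s.alpha, 0.0, atol=1e-14)


def test_uniform_spin_recovers_angular_velocity():
    s = differentiate_quaternions(_spin_series(omega=2.0))
    np.testing.assert_allclose(s.omega[2:-2], [[0, 0, 2.0]] * 196, atol=1e-4)


def test_accelerated_spin_recovers_angular_acceleration():
    s = differentiate_quaternions(_spin_series(omega=1.0, alpha=1.0))
    np.testing.assert_allclose(s.alpha[3:-3, 2], 1.0, atol=1e-3)


def test_sign_discontinuous_series_rejected():
    q = np.tile([1.0, 0, 0, 0], (10, 1))
    q[5] = -q[5]
    s = UnitQuaternionSeries(q=q, origin=np.zeros((10, 3)), dt=0.005)
    with pytest.raises(ValueError, match="canonicalize"):
        differentiate_quaternions(s)


def test_omega_matches_rotation_matrix_finite_difference():
    """omega from quaternions vs skew(R' R^T) on an analytic trajectory."""
    s = differentiate_quaternions(_spin_series(omega=3.0, alpha=2.0))
    R = s.rotation_matrices()
    dR = np.gradient(R, s.dt, axis=0)
    W = np.einsum("nij,nkj->nik", dR, R)  # R' R^T, skew of omega
    omega_fd = np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=1)
    np.testing.assert_allclose(s.omega[3:-3], omega_fd[3:-3], atol=1e-3)


# -------------------------------------------------- axial rotation offsets

def test_axial_offset_zero_is_identity(jump_trial):
    shank = jump_trial.truth["poses"]["shank"]
    assert apply_axial_rotation(shank, 0.0) is shank


def test_axial_offset_inverse_composition(jump_trial):
    shank = jump_trial.truth["poses"]["shank"]
    back = apply_axial_rotation(apply_axial_rotation(shank, 0.1), -0.1)
    np.testing.assert_allclose(back.q, shank.q, atol=1e-12)
    np.testing.assert_array_equal(back.origin, shank.origin)


def test_axial_offset_shifts_knee_rotation_angle_exactly(jump_trial):
    poses = jump_trial.truth["poses"]
    before = joint_angles_zxy(relative_orientation(poses["thigh"],
                                                   poses["shank"]))
    shifted = apply_axial_rotation(poses["shank"], 0.1)
    after = joint_angles_zxy(relative_orientation(poses["thigh"], shifted))
    np.testing.assert_allclose(after["rotation"] - before["rotation"], 0.1,
                               atol=1e-10)
    np.testing.assert_allclose(after["flexion"], before["flexion"], atol=1e-10)


def test_axial_offset_warns_beyond_artifact_range(jump_trial):
    with pytest.warns(UserWarning, match="0.15 rad"):
        apply_axial_rotation(jump_trial.truth["poses"]["shank"], 0.2)


def test_axial_offset_commutes_with_filtering(jump_trial):
    """A constant local offset is linear in q, so it commutes with any
    linear time-filter applied to the components."""
    shank = jump_trial.truth["poses"]["shank"]
    r = from_axis_angle([0, 1, 0], 0.1)
    rotated_then_filtered = filter_series(qmul(shank.q, r), 10.0, RATE)
    filtered_then_rotated = qmul(filter_series(shank.q, 10.0, RATE), r)
    np.testing.assert_allclose(rotated_then_filtered, filtered_then_rotated,
                               atol=1e-12)


# ------------------------------------------------------------ reconstruction

def test_reconstruction_recovers_truth_poses(jump_trial, model):
    poses = ll.reconstruct_poses(jump_trial.markers, model.marker_clouds)
    for seg in ("foot", "shank", "thigh", "pelvis"):
        np.testing.assert_allclose(poses[seg].q,
                                   jump_trial.truth["poses"][seg].q,
                                   atol=1e-10)
        np.testing.assert_allclose(poses[seg].origin,
                                   jump_trial.truth["poses"][seg].origin,
                                   atol=1e-10)


def test_non_unit_quaternion_series_rejected():
    q = np.tile([1.0, 0.1, 0, 0], (10, 1))
    with pytest.raises(ValueError, match="unit-norm"):
        UnitQuaternionSeries(q=q, origin=np.zeros((10, 3)), dt=0.005)
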