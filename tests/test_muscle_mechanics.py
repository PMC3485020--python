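import numpy as np
import pytest

import limbloads as ll
from limbloads._quat import to_matrix
from limbloads.kinematics import UnitQuaternionSeries, apply_axial_rotation
from limbloads.model import JOINTS, MuscleElement, MuscleSet, load_reference_muscles
from limbloads.muscle_mechanics import (compute_paths, moment_arms,
                                        muscle_geometry_series)
from limbloads.synthetic_data import _configuration

from oracles import tendon_excursion_arms

IDENT = np.array([1.0, 0, 0, 0])


def _pose_frame(model, theta):
    cfg = _configuration(np.array([theta]), model)
    poses = {seg: (q[0], o[0]) for seg, (q, o) in cfg.items()}
    centres = {j: poses[seg][1] + to_matrix(poses[seg][0]) @ loc
               for j, (seg, loc) in model.joint_centres.items()}
    return poses, centres


def _toy_set(**kw):
    defaults = dict(name="toy", origin=("shank", np.array([0.0, 0.0, 0.0])),
                    insertion=("foot", np.array([0.0, -0.3, 0.0])),
                    pcsa=10.0, crosses=("ankle",))
    defaults.update(kw)
    rotators = [
        MuscleElement(name=n, origin=("thigh", np.array([0.0, -0.4, 0.02])),
                      insertion=("shank", np.array([0.0, -0.05, 0.01 * k])),
                      pcsa=2.0, crosses=("knee",))
        for k, n in enumerate(("gracilis", "plantaris", "popliteus",
                               "sartorius", "tfl"), 1)]
    return MuscleSet((MuscleElement(**defaults), *rotators))


def _simple_poses():
    return {seg: (IDENT, np.array([0.0, 0.5 * lvl, 0.0]))
            for seg, lvl in (("foot", 0), ("shank", 1), ("thigh", 2),
                             ("pelvis", 3))}


def test_two_point_path_along_axis():
    paths = compute_paths(_toy_set(), _simple_poses())
    toy = paths[0]
    assert toy.length == pytest.approx(0.3 + 0.5)  # origin at shank frame 0.5
    u, p = toy.action["ankle"]
    np.testing.assert_allclose(u, [0, 1, 0], atol=1e-12)


def test_zero_length_path_rejected():
    bad = _toy_set(origin=("shank", np.array([0.0, -0.5, 0.0])),
                   insertion=("foot", np.array([0.0, 0.0, 0.0])))
    with pytest.raises(ValueError, match="zero-length"):
        compute_paths(bad, _simple_poses())


def test_missing_segment_pose_errors():
    poses = _simple_poses()
    del poses["foot"]
    with pytest.raises(KeyError, match="foot"):
        compute_paths(_toy_set(), poses)


def test_moment_arm_hand_cross_product():
    """Unit pull along +x applied at (0, 0.1, 0) from the centre -> moment
    (0, 0, -0.1)."""
    m = MuscleElement(name="toy", origin=("thigh", np.array([0.3, 0.1, 0.0])),
                      insertion=("shank", np.array([0.0, -0.4, 0.0])),
                      pcsa=1.0, crosses=("knee",))
    muscles = _toy_set()
    poses = _simple_poses()
    # place insertion so the strand application point sits at centre + (0,0.1,0)
    paths = compute_paths(MuscleSet((m, *muscles.elements[1:])), poses)
    u, p = paths[0].action["knee"]
    centre = p - np.array([0.0, 0.1, 0.0])
    R = moment_arms(paths, {"knee": centre, "ankle": np.zeros(3),
                            "hip": np.zeros(3)})
    expected = np.cross([0.0, 0.1, 0.0], u)
    np.testing.assert_allclose(R[3:6, 0], expected, atol=1e-12)


def test_non_crossing_joint_entries_are_zero(model):
    poses, centres = _pose_frame(model, 0.7)
    R = moment_arms(compute_paths(model.muscles, poses), centres)
    names = model.muscles.names
    j = names.index("soleus")       # ankle only
    np.testing.assert_array_equal(R[3:9, j], 0.0)
    j = names.index("glut_max")     # hip only
    np.testing.assert_array_equal(R[0:6, j], 0.0)


def test_muscle_parallel_through_centre_has_zero_arm():
    m = MuscleElement(name="axial", origin=("thigh", np.array([0.0, 0.1, 0.0])),
                      insertion=("shank", np.array([0.0, -0.4, 0.0])),
                      pcsa=1.0, crosses=("knee",))
    muscles = MuscleSet((m, *_toy_set().elements[1:]))
    poses = _simple_poses()
    paths = compute_paths(muscles, poses)
    # centre anywhere on the (vertical) line of action
    centre = paths[0].polyline[1] + np.array([0.0, 0.2, 0.0])
    R = moment_arms(paths, {"knee": centre, "ankle": np.zeros(3),
                            "hip": np.zeros(3)})
    np.testing.assert_allclose(R[3:6, 0], 0.0, atol=1e-12)


def test_moment_arms_match_tendon_excursion_oracle(model):
    """Geometric arms equal -dL/dtheta by finite differences, 20 poses."""
    rng = np.random.default_rng(7)
    thetas = rng.uniform(0.2, 1.8, 20)
    for theta in thetas:
        poses, centres = _pose_frame(model, theta)
        R = moment_arms(compute_paths(model.muscles, poses), centres)
        joint = ("ankle", "knee", "hip")[rng.integers(3)]
        axis = int(rng.integers(3))
        dl = tendon_excursion_arms(model.muscles, poses, centres, joint, axis)
        row = 3 * JOINTS.index(joint) + axis
        np.testing.assert_allclose(R[row], dl, atol=1e-4)


def test_path_length_continuity_on_jump(jump_trial, jump_kin, model):
    centres = {j: jump_kin[seg].point_trajectory(loc)
               for j, (seg, loc) in model.joint_centres.items()}
    geom = muscle_geometry_series(model.muscles, jump_kin, centres)
    dL = np.abs(np.diff(geom.lengths, axis=0))
    v_max = 5.0  # m/s, generous muscle-tip speed bound
    assert dL.max() < v_max / jump_trial.markers.rate


def test_vectorized_series_matches_per_frame_path_computation(model, jump_kin):
    centres = {j: jump_kin[seg].point_trajectory(loc)
               for j, (seg, loc) in model.joint_centres.items()}
    geom = muscle_geometry_series(model.muscles, jump_kin, centres)
    for i in (0, 150, 400):
        poses = {seg: (jump_kin[seg].q[i], jump_kin[seg].origin[i])
                 for seg in jump_kin}
        R = moment_arms(compute_paths(model.muscles, poses),
                        {j: c[i] for j, c in centres.items()})
        np.testing.assert_allclose(geom.arms[i], R, atol=1e-12)


def _local_knee_arms(model, thetas, offset):
    cfg = _configuration(thetas, model)
    poses = {seg: UnitQuaternionSeries(q=q, origin=o, dt=0.005)
             for seg, (q, o) in cfg.items()}
    if offset:
        poses["shank"] = apply_axial_rotation(poses["shank"], offset)
    centres = {j: poses[seg].point_trajectory(loc)
               for j, (seg, loc) in model.joint_centres.items()}
    geom = muscle_geometry_series(model.muscles, poses, centres)
    R = to_matrix(poses["shank"].q)
    return np.einsum("nji,njm->nim", R, geom.arms[:, 3:6, :])


def test_external_rotation_mechanism_on_popliteus_and_tfl(model):
    """External shank rotation increases the popliteus arm about the shank
    long (superoinferior) axis and the TFL arm about the anteroposterior
    axis at mid-flexion poses."""
    thetas = np.linspace(0.6, 1.4, 5)
    base = _local_knee_arms(model, thetas, 0.0)
    ext = _local_knee_arms(model, thetas, -0.1)
    names = model.muscles.names
    jp, jt = names.index("popliteus"), names.index("tfl")
    assert np.all(np.abs(ext[:, 1, jp]) > np.abs(base[:, 1, jp]))
    assert np.all(np.abs(ext[:, 0, jt]) > np.abs(base[:, 0, jt]))
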