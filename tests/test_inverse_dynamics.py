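import numpy as np
import pytest

import limbloads as ll
from limbloads.inverse_dynamics import (GroundReaction, Wrench,
                                        segment_inertial_wrench, solve_chain)
from limbloads.kinematics import (UnitQuaternionSeries, apply_axial_rotation,
                                  differentiate_quaternions)
from limbloads.model import scale_inertia

from oracles import newton_euler_recursion, random_smooth_chain

G = np.array([0.0, -9.81, 0.0])


def test_wrench_transport_rule():
    w = Wrench(force=np.array([10.0, 0, 0]), moment=np.array([0.0, 0, 5.0]),
               point=np.array([1.0, 2.0, 0.0]))
    moved = w.transported_to([0.0, 0.0, 0.0])
    d = w.point - moved.point
    np.testing.assert_allclose(moved.moment, w.moment + np.cross(d, w.force))
    back = moved.transported_to(w.point)
    np.testing.assert_allclose(back.moment, w.moment, atol=1e-12)


def test_static_segment_inertial_wrench_is_weight():
    inert = scale_inertia(ll.SubjectAnthro(mass=80, height=1.8), "shank")
    w = segment_inertial_wrench(inert, np.eye(3), np.zeros(3), np.zeros(3),
                                np.zeros(3))
    np.testing.assert_allclose(w.force, -inert.mass * G)
    np.testing.assert_allclose(w.moment, 0.0)


def test_free_fall_gives_zero_wrench():
    inert = scale_inertia(ll.SubjectAnthro(mass=80, height=1.8), "thigh")
    w = segment_inertial_wrench(inert, np.eye(3), G, np.zeros(3), np.zeros(3))
    np.testing.assert_allclose(w.force, 0.0, atol=1e-12)
    np.testing.assert_allclose(w.moment, 0.0, atol=1e-12)


def test_spin_about_symmetry_axis_has_no_gyroscopic_moment():
    inert = scale_inertia(ll.SubjectAnthro(mass=80, height=1.8), "shank")
    omega = np.array([0.0, 7.0, 0.0])  # shank long axis
    w = segment_inertial_wrench(inert, np.eye(3), G, omega, np.zeros(3))
    np.testing.assert_allclose(w.moment, 0.0, atol=1e-12)


def _static_two_segment_case():
    """Quiet standing: constant poses, bodyweight GRF under the foot."""
    n = 20
    ident = np.tile([1.0, 0, 0, 0], (n, 1))

    def still(origin):
        s = UnitQuaternionSeries(q=ident.copy(),
                                 origin=np.tile(origin, (n, 1)), dt=0.005)
        return differentiate_quaternions(s)

    kin = {"foot": still([0.0, 0.07, 0.0]),
           "shank": still([0.0, 0.51, 0.0]),
           "thigh": still([0.0, 0.95, 0.0])}
    grf = np.tile([0.0, 800.0, 0.0], (n, 1))
    cop = np.tile([0.06, 0.0, 0.0], (n, 1))
    gr = GroundReaction(grf=grf, cop=cop, rate=200.0)
    centres = {"ankle": ("shank", np.array([0.0, -0.44, 0.0])),
               "knee": ("thigh", np.array([0.0, -0.44, 0.0])),
               "hip": ("thigh", np.zeros(3))}
    anthro = ll.SubjectAnthro(mass=80.0, height=1.8)
    inertias = {seg: scale_inertia(anthro, seg)
                for seg in ("foot", "shank", "thigh")}
    return kin, gr, centres, inertias


def test_static_knee_moment_matches_hand_lever_computation():
    """Standing: knee moment = r x F for GRF and segment weights below."""
    kin, gr, centres, inertias = _static_two_segment_case()
    wr = solve_chain(kin, gr, inertias, centres)
    knee = np.array([0.0, 0.51, 0.0])  # thigh origin + (0,-0.44,0)
    f_grf = gr.grf[0]
    hand_force = -f_grf.copy()
    hand_moment = -np.cross(gr.cop[0] - knee, f_grf)
    # weights of foot and shank act at their CoMs
    for seg, base in (("foot", [0.0, 0.07, 0.0]), ("shank", [0.0, 0.51, 0.0])):
        inert = inertias[seg]
        com = np.asarray(base) + inert.com_offset
        w = inert.mass * G
        hand_force -= w
        hand_moment -= np.cross(com - knee, w)
    np.testing.assert_allclose(wr["knee"].force[5], hand_force, atol=1e-8)
    np.testing.assert_allclose(wr["knee"].moment[5], hand_moment, atol=1e-8)


def test_airborne_ankle_wrench_is_foot_inertial_wrench(jump_trial, jump_kin,
                                                       jump_wrenches, model):
    i0, i1 = jump_trial.truth["ballistic_interval"]
    mid = (i0 + i1) // 2
    from limbloads.inverse_dynamics import com_kinematics
    com, acc = com_kinematics(jump_kin["foot"], model.inertias["foot"])
    iw = segment_inertial_wrench(
        model.inertias["foot"], jump_kin["foot"].rotation_matrices()[mid],
        acc[mid], jump_kin["foot"].omega[mid], jump_kin["foot"].alpha[mid])
    np.testing.assert_allclose(jump_wrenches["ankle"].force[mid], iw.force,
                               atol=1e-9)


def test_input_validation_errors():
    kin, gr, centres, inertias = _static_two_segment_case()
    bad = GroundReaction(grf=gr.grf[:-1], cop=gr.cop[:-1], rate=200.0)
    with pytest.raises(ValueError, match="mismatch"):
        solve_chain(kin, bad, inertias, centres)
    gr2 = GroundReaction(grf=gr.grf.copy(), cop=gr.cop, rate=200.0)
    gr2.grf[7, 1] = np.nan
    with pytest.raises(ValueError, match="frame 7"):
        solve_chain(kin, gr2, inertias, centres)


def test_one_step_solution_matches_recursion_oracle():
    """The assembled linear system equals the explicit Newton-Euler
    recursion on 100 random smooth frames."""
    rng = np.random.default_rng(2024)
    kin_raw, grf, cop = random_smooth_chain(rng, n=110)
    kin = {s: differentiate_quaternions(q) for s, q in kin_raw.items()}
    gr = GroundReaction(grf=grf, cop=cop, rate=200.0)
    centres = {"ankle": ("shank", np.array([0.0, -0.44, 0.0])),
               "knee": ("thigh", np.array([0.0, -0.42, 0.0])),
               "hip": ("pelvis", np.zeros(3))}
    anthro = ll.SubjectAnthro(mass=83.5, height=1.79)
    inertias = {seg: scale_inertia(anthro, seg)
                for seg in ("foot", "shank", "thigh")}
    wr = solve_chain(kin, gr, inertias, centres)
    for frame in range(5, 105):
        oracle = newton_euler_recursion(kin, gr, inertias, centres, frame)
        for joint in ("ankle", "knee", "hip"):
            f, m = oracle[joint]
            scale = max(1.0, np.linalg.norm(f))
            np.testing.assert_allclose(wr[joint].force[frame], f,
                                       atol=1e-8 * scale)
            scale_m = max(1.0, np.linalg.norm(m))
            np.testing.assert_allclose(wr[joint].moment[frame], m,
                                       atol=1e-8 * scale_m)


def test_whole_limb_force_closure(jump_trial, jump_kin, jump_wrenches, model):
    """Sum of segment inertial forces = GRF + hip force, every frame."""
    from limbloads.inverse_dynamics import com_kinematics
    gr = jump_trial.ground_reaction
    total = np.zeros((gr.n_frames, 3))
    for seg in ("foot", "shank", "thigh"):
        _, acc = com_kinematics(jump_kin[seg], model.inertias[seg])
        total += model.inertias[seg].mass * (acc - G)
    residual = total - gr.grf - jump_wrenches["hip"].force
    assert np.abs(residual).max() < 1e-6


def test_joint_wrenches_invariant_to_shank_axial_offsets(jump_trial, jump_kin,
                                                         jump_wrenches, model):
    for offset in (-0.1, 0.05):
        kin = dict(jump_kin)
        kin["shank"] = apply_axial_rotation(jump_kin["shank"], offset)
        wr = solve_chain(kin, jump_trial.ground_reaction, model.inertias,
                         model.joint_centres)
        for joint in ("ankle", "knee", "hip"):
            np.testing.assert_allclose(wr[joint].moment,
                                       jump_wrenches[joint].moment, atol=1e-9)
            np.testing.assert_allclose(wr[joint].force,
                                       jump_wrenches[joint].force, atol=1e-9)
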