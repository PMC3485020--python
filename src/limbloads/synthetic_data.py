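"""Synthetic maximal counter-movement jump trials.

Generates marker trajectories, force-plate series and ground truth for a
sagittal-dominant vertical jump: quiet stance, counter-movement to a deep
knee-flexion trough, extension to take-off, a ballistic flight whose duration
matches the requested jump height, landing absorption and recovery. The jump
is bilateral with one instrumented plate under the right foot: on contact
frames the plate force is exactly half the whole-body inertial force
m (a_com + g) (the right-leg share), and the flight interval is exactly
ballistic with zero GRF.

Small fixed out-of-plane segment rotations (internal shank rotation and thigh
adduction, 0.05 rad each) keep the non-sagittal joint moments nonzero so that
the knee-rotator muscles are recruited, without full 3-D motion synthesis.
An axial soft-tissue-artifact term can be injected into the shank markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BPoly

from ._quat import canonicalize, qmul, to_matrix
from .inverse_dynamics import GroundReaction
from .kinematics import MarkerSet, UnitQuaternionSeries
from .model import (HAT_COM_PELVIS, HAT_MASS_FRAC, REFERENCE_HEIGHT,
                    ScaledModel, SubjectAnthro, build_model)

G = 9.81
#: fixed out-of-plane offsets (rad): internal shank rotation, thigh adduction
SHANK_AXIAL_OFFSET = 0.05
THIGH_ADDUCTION_OFFSET = 0.05
#: share of knee flexion taken by the shank tilt (rest by the thigh); the
#: smaller shank share keeps the knee over the foot as in a real squat
SHANK_TILT_FRACTION = 0.4
#: knee state at take-off: near-extension angle (rad), a physiological
#: extension rate (rad/s) and a gentle deceleration (rad/s^2); the ankle-rise
#: (heel-lift) channel, the surrogate for plantarflexion, supplies the rest
#: of the take-off velocity
TAKEOFF_KNEE_ANGLE = 0.5
TAKEOFF_KNEE_RATE = -4.0
TAKEOFF_KNEE_ACCEL = 10.0
ANKLE_RISE = 0.12  # m of heel lift at take-off
#: CoP sits this far anterior of the ankle at flat foot, and travels toward
#: the forefoot in proportion to heel lift (both scaled by stature)
COP_BASE_OFFSET = 0.05
COP_TRAVEL_GAIN = 0.8
#: vertical free moment of the plate as a fraction (m) of vertical force;
#: negative (external plate torque) so the *internal* rotators of the tibia
#: (the knee-rotator group) are the muscles loaded by it
FREE_MOMENT_ARM = -0.004

__all__ = ["JumpParams", "SyntheticTrial", "generate_jump",
           "inject_axial_artifact", "draw_subjects"]


@dataclass(frozen=True)
class JumpParams:
    """Conditions of one synthetic jump trial.

    jump_height is the ballistic rise of the centre of mass (m);
    countermove_depth is the peak knee flexion of the counter movement (rad).
    """

    subject: SubjectAnthro = field(
        default_factory=lambda: SubjectAnthro(mass=83.5, height=1.79))
    jump_height: float = 0.40
    countermove_depth: float = 1.9
    trial_duration: float = 2.8
    rate: float = 200.0
    noise_sd: float = 0.0
    shank_artifact_amp: float = 0.0
    artifact_profile: str = "constant"
    seed: int = 0

    def __post_init__(self):
        if not (0.05 <= self.jump_height <= 0.8):
            raise ValueError("jump_height outside a plausible range")
        if self.rate <= 0 or self.trial_duration <= 0:
            raise ValueError("rate and trial_duration must be positive")


@dataclass
class SyntheticTrial:
    """Markers + force plate + ground truth for one generated jump."""

    markers: MarkerSet
    ground_reaction: GroundReaction
    truth: dict
    params: JumpParams
    model: ScaledModel
    noise: dict = field(default_factory=dict, repr=False)


def _quat_axis(angles, axis: int) -> np.ndarray:
    """(n,4) quaternions for rotations about a coordinate axis."""
    angles = np.atleast_1d(np.asarray(angles, float))
    q = np.zeros((len(angles), 4))
    q[:, 0] = np.cos(angles / 2.0)
    q[:, 1 + axis] = np.sin(angles / 2.0)
    return q


def _configuration(theta_k, model: ScaledModel):
    """Segment poses for knee flexion theta_k with the ankle at the origin.

    Foot flat; the shank tilts anteriorly by a fixed fraction of the knee
    flexion (plus a constant internal-rotation offset) and the thigh
    posteriorly by the remainder (plus a constant adduction offset); the
    pelvis stays upright at the hip. Returns dict segment ->
    (q (n,4), origin (n,3)).
    """
    theta_k = np.atleast_1d(np.asarray(theta_k, float))
    n = len(theta_k)
    Ls = model.segment_lengths["shank"]
    Lt = model.segment_lengths["thigh"]
    phi = SHANK_TILT_FRACTION * theta_k            # anterior shank tilt
    psi = (1.0 - SHANK_TILT_FRACTION) * theta_k    # posterior thigh tilt
    q_shank = canonicalize(qmul(_quat_axis(-phi, 2),
                                _quat_axis(np.full(n, SHANK_AXIAL_OFFSET), 1)))
    q_thigh = canonicalize(qmul(_quat_axis(psi, 2),
                                _quat_axis(np.full(n, THIGH_ADDUCTION_OFFSET), 0)))
    q_ident = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    ankle = np.zeros((n, 3))
    R_s = to_matrix(q_shank)
    R_t = to_matrix(q_thigh)
    knee = ankle - np.einsum("nij,j->ni", R_s, np.array([0.0, -Ls, 0.0]))
    hip = knee - np.einsum("nij,j->ni", R_t, np.array([0.0, -Lt, 0.0]))
    return {
        "foot": (q_ident, ankle),
        "shank": (q_shank, knee),
        "thigh": (q_thigh, hip),
        "pelvis": (q_ident, hip),
    }


def _body_com(poses, model: ScaledModel) -> np.ndarray:
    """Whole-body CoM: right leg + mirrored left leg + pelvis + HAT mass."""
    s = model.anthro.height / REFERENCE_HEIGHT
    total = np.zeros_like(poses["foot"][1])
    mass = 0.0
    mirror = np.array([1.0, 1.0, -1.0])
    for seg in ("foot", "shank", "thigh"):
        q, org = poses[seg]
        inert = model.inertias[seg]
        com = org + np.einsum("nij,j->ni", to_matrix(q), inert.com_offset)
        total += inert.mass * (com + com * mirror)  # right + mirrored left
        mass += 2.0 * inert.mass
    q, org = poses["pelvis"]
    pel = model.inertias["pelvis"]
    com_p = org + np.einsum("nij,j->ni", to_matrix(q), pel.com_offset)
    total += pel.mass * com_p
    mass += pel.mass
    m_hat = HAT_MASS_FRAC * model.anthro.mass
    total += m_hat * (org + HAT_COM_PELVIS[None, :] * s)
    mass += m_hat
    return total / mass


def generate_jump(params: JumpParams) -> SyntheticTrial:
    """Build one deterministic synthetic jump trial.

    Knee flexion theta(t) and an ankle-rise (heel-lift) channel a(t) are
    prescribed as smooth piecewise quintics; all segment poses follow by
    forward kinematics, the whole-body CoM is evaluated, and the plate force
    on contact frames is the right-leg share (one half, bilateral jump) of
    the whole-body inertial force m (a_com + g). Take-off velocity is split
    between the ankle rise and knee extension so neither channel needs an
    implausible rate; the flight interval is exactly ballistic.
    """
    subject = params.subject
    model = build_model(subject)
    s = subject.height / REFERENCE_HEIGHT
    rate, dt = params.rate, 1.0 / params.rate
    n = int(round(params.trial_duration * rate)) + 1
    t = np.arange(n) * dt
    ankle_h = 0.070 * s
    rise = ANKLE_RISE * s

    th_stand, th_to = 0.12, TAKEOFF_KNEE_ANGLE
    th_dip = params.countermove_depth
    th_land = 0.85 * params.countermove_depth
    if th_dip <= th_to + 0.2 or th_dip > 2.6:
        raise ValueError("countermove_depth incompatible with the take-off/"
                         "landing configuration")

    # CoM sensitivity to knee flexion at the take-off configuration
    eps = 1e-5
    c_hi = _body_com(_configuration(np.array([th_to + eps]), model), model)[0]
    c_lo = _body_com(_configuration(np.array([th_to - eps]), model), model)[0]
    dcom_dth = (c_hi - c_lo) / (2 * eps)         # 3-vector, y < 0
    v_to_com = np.sqrt(2.0 * G * params.jump_height)
    thdot_to = TAKEOFF_KNEE_RATE
    v_a = v_to_com - dcom_dth[1] * thdot_to      # ankle-rise takeoff velocity
    v_com = np.array([0.0, v_a, 0.0]) + dcom_dth * thdot_to

    t_stand, t_dip, t_to = 0.35, 0.90, 1.20
    tf = 2.0 * v_com[1] / G
    t_td = t_to + tf
    t_land = t_td + 0.40
    t_rec = t_land + 0.50
    if t_rec > params.trial_duration:
        raise ValueError(f"trial_duration {params.trial_duration} s too short; "
                         f"needs >= {t_rec:.2f} s")

    contact_pre = t <= t_to
    flight = (t > t_to) & (t < t_td)
    contact_post = t >= t_td

    thddot_to = TAKEOFF_KNEE_ACCEL
    a_accel_to = -G - dcom_dth[1] * thddot_to    # ankle accel completing -g
    th_up = BPoly.from_derivatives(
        [0.0, t_stand, t_dip, t_to],
        [[th_stand, 0.0, 0.0], [th_stand, 0.0, 0.0], [th_dip, 0.0, -20.0],
         [th_to, thdot_to, thddot_to]])
    # matching second derivatives at both flight boundaries keep the segment
    # accelerations (hence the inverse-dynamics input) continuous; the guide
    # knots let the knee finish extending just after take-off, tuck at
    # mid-flight, and re-flex before touchdown without polynomial overshoot
    # in flight the knee finishes extending, holds, then returns to the
    # take-off angle for touchdown; gentle rates keep flight joint moments
    # within muscular capacity (no violent tuck)
    th_ext = max(0.5 * th_stand, th_to - 0.2)
    t_stop = min(2.0 * (th_to - th_ext) / max(abs(thdot_to), 1e-6), 0.35 * tf)
    th_flight = BPoly.from_derivatives(
        [t_to, t_to + t_stop, t_td - t_stop, t_td],
        [[th_to, thdot_to, thddot_to], [th_ext, 0.0, 0.0],
         [th_ext, 0.0, 0.0], [th_to, -thdot_to, thddot_to]])
    th_down = BPoly.from_derivatives(
        [t_td, t_td + 0.5 * (t_land - t_td), t_land, t_rec],
        [[th_to, -thdot_to, thddot_to],
         [0.5 * (th_to + th_land),
          0.8 * (th_land - th_to) / (t_land - t_td), 0.0],
         [th_land, 0.0, -15.0], [th_stand, 0.0, 0.0]])
    theta = np.empty(n)
    theta[contact_pre] = th_up(t[contact_pre])
    theta[flight] = th_flight(t[flight])
    theta[contact_post] = th_down(np.minimum(t[contact_post], t_rec))

    a_up = BPoly.from_derivatives(
        [0.0, t_dip, t_to],
        [[ankle_h, 0.0, 0.0], [ankle_h, 0.0, 0.0],
         [ankle_h + rise, v_a, a_accel_to]])
    a_down = BPoly.from_derivatives(
        [t_td, t_land, t_rec],
        [[ankle_h + rise, -v_a, a_accel_to], [ankle_h, 0.0, 0.0],
         [ankle_h, 0.0, 0.0]])
    ankle_y = np.empty(n)
    ankle_y[contact_pre] = a_up(t[contact_pre])
    ankle_y[contact_post] = a_down(np.minimum(t[contact_post], t_rec))
    ankle_y[flight] = 0.0   # placeholder; flight placement is CoM-driven

    poses_cfg = _configuration(theta, model)    # ankle at origin
    com_cfg = _body_com(poses_cfg, model)

    # --- assemble global placement -------------------------------------
    offset = np.zeros((n, 3))
    offset[:, 1] = ankle_y
    i_to = int(np.searchsorted(t, t_to, side="right")) - 1
    com_to = com_cfg[i_to] + offset[i_to]
    tau_all = t[flight] - t_to
    com_target = (com_to[None, :] + v_com[None, :] * tau_all[:, None]
                  - 0.5 * G * tau_all[:, None] ** 2 * np.array([0.0, 1.0, 0.0]))
    offset[flight] = com_target - com_cfg[flight]
    # horizontal offset after flight: resume from the flight-end position and
    # velocity (the tuck leaves a residual horizontal rate), settle by t_land
    thdot_td = float(th_flight(t_td, 1))
    v_in = np.array([v_com[0], 0.0, v_com[2]]) - dcom_dth * thdot_td
    drift = np.array([v_com[0], 0.0, v_com[2]]) * tf
    for ax in (0, 2):
        ramp = BPoly.from_derivatives(
            [t_td, t_land],
            [[drift[ax], v_in[ax]],
             [drift[ax] + 0.5 * v_in[ax] * (t_land - t_td), 0.0]])
        vals = ramp(np.minimum(t[contact_post], t_land))
        vals[t[contact_post] > t_land] = ramp(t_land)
        offset[contact_post, ax] += vals

    poses = {}
    for seg, (q, org) in poses_cfg.items():
        poses[seg] = UnitQuaternionSeries(q=q, origin=org + offset, dt=dt)

    com = _body_com({seg: (p.q, p.origin) for seg, p in poses.items()}, model)
    acc = np.gradient(np.gradient(com, dt, axis=0), dt, axis=0)
    # right plate of a bilateral jump: half the whole-body inertial force
    grf = 0.5 * subject.mass * (acc + np.array([0.0, G, 0.0]))
    grf[flight] = 0.0
    ankle_pos = poses["foot"].origin
    heel_lift = np.clip(ankle_pos[:, 1] - ankle_h, 0.0, None)
    cop = np.column_stack([
        ankle_pos[:, 0] + COP_BASE_OFFSET * s + COP_TRAVEL_GAIN * heel_lift,
        np.zeros(n), ankle_pos[:, 2]])
    free_moment = FREE_MOMENT_ARM * grf[:, 1]
    gr = GroundReaction(grf=grf, cop=cop, rate=rate, free_moment=free_moment)

    rng = np.random.default_rng(params.seed)
    noise = {
        seg: {lab: rng.normal(0.0, params.noise_sd, size=(n, 3))
              if params.noise_sd > 0 else np.zeros((n, 3))
              for lab in model.marker_clouds[seg]}
        for seg in model.marker_clouds
    }
    i_td = int(np.searchsorted(t, t_td, side="left"))
    # flight-boundary truth = the instants the plate un/re-loads (the plate
    # force tapers smoothly through the 10 N floor around the ballistic knots)
    thresh = 10.0
    low = grf[:, 1] < thresh
    i_unload = int(np.flatnonzero(low & (t <= t_to + 2 * dt))[0])
    after = np.flatnonzero(~low & (t >= t_td - 2 * dt))
    i_reload = int(after[0])
    truth = {
        "poses": poses,
        "knee_flexion": theta,
        "com": com,
        "v_takeoff": float(v_com[1]),
        "takeoff_frame": i_unload,
        "touchdown_frame": i_reload,
        "ballistic_interval": (i_to + 1, i_td),
        "dip_pre_frame": int(np.argmin(np.abs(t - t_dip))),
        "dip_post_frame": int(np.argmin(np.abs(t - t_land))),
        "flight_time": tf,
        "artifact": np.zeros(n),
    }
    markers = _markers_from_poses(poses, model, noise, rate)
    return SyntheticTrial(markers=markers, ground_reaction=gr, truth=truth,
                          params=params, model=model, noise=noise)


def _markers_from_poses(poses, model, noise, rate,
                        shank_extra_rotation=None) -> MarkerSet:
    trajs = {}
    for seg, cloud in model.marker_clouds.items():
        R = to_matrix(poses[seg].q)
        org = poses[seg].origin
        trajs[seg] = {}
        for lab, local in cloud.items():
            pt = local
            if seg == "shank" and shank_extra_rotation is not None:
                pt = np.einsum("nij,j->ni", shank_extra_rotation, local)
                glob = org + np.einsum("nij,nj->ni", R, pt)
            else:
                glob = org + np.einsum("nij,j->ni", R, pt)
            trajs[seg][lab] = glob + noise[seg][lab]
    return MarkerSet(trajs, rate)


def inject_axial_artifact(trial: SyntheticTrial, amp: float,
                          profile: str = "constant") -> SyntheticTrial:
    """Rotate the shank markers about the shank long axis (soft-tissue artifact).

    ``constant``: fixed angle every frame; ``flexion_coupled``: amp scaled by
    the normalised knee flexion (zero artifact at zero flexion). Positive amp
    reads as internal rotation to the reconstruction. Marker noise draws are
    reused so the artifact is the only change.
    """
    if abs(amp) > 0.15:
        raise ValueError("artifact amplitude beyond 0.15 rad is implausible")
    if profile not in ("constant", "flexion_coupled"):
        raise ValueError(f"unknown artifact profile {profile!r}")
    theta = trial.truth["knee_flexion"]
    if profile == "constant":
        ang = np.full(len(theta), float(amp))
    else:
        ang = float(amp) * theta / np.max(theta)
    rot = to_matrix(_quat_axis(ang, 1))
    markers = _markers_from_poses(trial.truth["poses"], trial.model,
                                  trial.noise, trial.markers.rate,
                                  shank_extra_rotation=rot)
    truth = dict(trial.truth)
    truth["artifact"] = ang
    return replace(trial, markers=markers, truth=truth)


def draw_subjects(n: int, seed: int = 0,
                  mass_mean: float = 83.5, mass_sd: float = 10.9,
                  height_mean: float = 1.79, height_sd: float = 0.07):
    """Sample a cohort of subject anthropometries (athletic male population)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(SubjectAnthro(
            mass=float(np.clip(rng.normal(mass_mean, mass_sd), 50.0, 120.0)),
            height=float(np.clip(rng.normal(height_mean, height_sd), 1.55, 2.05)),
            id=f"S{i + 1:02d}"))
    return out
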