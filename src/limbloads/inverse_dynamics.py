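"""Intersegmental joint wrenches by quaternion/wrench inverse dynamics.

The limb is a foot-shank-thigh chain with ball joints at the ankle, knee and
hip; the only external actions are gravity and the ground reaction at the
centre of pressure. Per frame, all three joint wrenches are obtained in one
step as the solution of a single 18x18 linear system assembling every
segment's Newton-Euler balance (mathematically identical to the distal-to-
proximal recursion, which the test suite keeps as an independent oracle).

Each joint wrench is the action of the proximal segment on the distal one,
expressed at the instantaneous joint centre (a fixed point of the proximal
segment's frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import UnitQuaternionSeries
from .model import JOINTS, SegmentInertia

GRAVITY = np.array([0.0, -9.81, 0.0])

__all__ = ["Wrench", "WrenchSeries", "GroundReaction",
           "segment_inertial_wrench", "solve_chain", "com_kinematics"]


def _skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


@dataclass
class Wrench:
    """Force/moment pair acting at a stated global point."""

    force: np.ndarray
    moment: np.ndarray
    point: np.ndarray
    frame: str = "global"

    def transported_to(self, new_point) -> "Wrench":
        """Express the same action at another point (moment transport rule)."""
        new_point = np.asarray(new_point, float)
        d = np.asarray(self.point, float) - new_point
        return Wrench(force=np.asarray(self.force, float),
                      moment=np.asarray(self.moment, float) + np.cross(d, self.force),
                      point=new_point, frame=self.frame)


@dataclass
class WrenchSeries:
    force: np.ndarray    # (n, 3) N
    moment: np.ndarray   # (n, 3) N m, at `point`
    point: np.ndarray    # (n, 3) m global

    def __getitem__(self, i: int) -> Wrench:
        return Wrench(self.force[i], self.moment[i], self.point[i])


@dataclass
class GroundReaction:
    """Force-plate series: GRF vector, centre of pressure, free moment."""

    grf: np.ndarray          # (n, 3) N
    cop: np.ndarray          # (n, 3) m global
    rate: float
    free_moment: np.ndarray | None = None  # (n,) N m about the vertical

    def __post_init__(self):
        self.grf = np.asarray(self.grf, float)
        self.cop = np.asarray(self.cop, float)
        if self.free_moment is None:
            self.free_moment = np.zeros(len(self.grf))
        if len(self.grf) != len(self.cop):
            raise ValueError("grf and cop lengths differ")
        loaded = self.grf[:, 1] > 10.0
        if not np.all(np.isfinite(self.cop[loaded])):
            raise ValueError("non-finite CoP on loaded frames")

    @property
    def n_frames(self) -> int:
        return len(self.grf)

    def airborne_mask(self, threshold: float = 10.0) -> np.ndarray:
        return self.grf[:, 1] < threshold


def com_kinematics(series: UnitQuaternionSeries, inertia: SegmentInertia):
    """CoM global trajectory and its finite-difference acceleration."""
    com = series.point_trajectory(inertia.com_offset)
    dt = series.dt
    acc = np.gradient(np.gradient(com, dt, axis=0), dt, axis=0)
    return com, acc


def segment_inertial_wrench(inertia: SegmentInertia, rotation: np.ndarray,
                            com_acc, omega, alpha,
                            gravity=GRAVITY, point=None) -> Wrench:
    """Net external wrench a segment's motion requires, at its CoM.

    force = m (a_com - g); moment about the CoM = I_g alpha + omega x I_g
    omega with I_g = R I_local R^T. ``point`` is only a label for where the
    CoM is in space (defaults to the origin).
    """
    R = np.asarray(rotation, float)
    I_g = R @ inertia.inertia_tensor @ R.T
    f = inertia.mass * (np.asarray(com_acc, float) - np.asarray(gravity, float))
    m = I_g @ np.asarray(alpha, float) + np.cross(omega, I_g @ np.asarray(omega, float))
    return Wrench(force=f, moment=m,
                  point=np.zeros(3) if point is None else np.asarray(point, float))


def solve_chain(kin: dict, gr: GroundReaction, inertias: dict,
                joint_centres: dict, gravity=GRAVITY) -> dict:
    """Joint wrench series at the ankle, knee and hip.

    kin: segment -> UnitQuaternionSeries with derivatives attached (foot,
    shank, thigh required). joint_centres: joint -> (segment, local point).
    Returns joint -> WrenchSeries, each wrench the proximal-on-distal action
    at the instantaneous joint centre.
    """
    required = ("foot", "shank", "thigh")
    n = {seg: kin[seg].n_frames for seg in required}
    if len(set(n.values())) != 1 or next(iter(n.values())) != gr.n_frames:
        raise ValueError(f"frame-count mismatch: kinematics {n}, "
                         f"force plate {gr.n_frames}")
    nf = gr.n_frames
    for seg in required:
        if kin[seg].omega is None:
            raise ValueError(f"segment {seg!r} has no derivatives; call "
                             "differentiate_quaternions first")
    rot = {seg: kin[seg].rotation_matrices() for seg in required}
    com, acc = {}, {}
    for seg in required:
        com[seg], acc[seg] = com_kinematics(kin[seg], inertias[seg])
        bad = ~np.all(np.isfinite(acc[seg]), axis=1)
        if np.any(bad):
            raise ValueError(f"NaN in {seg} kinematics at frame "
                             f"{int(np.flatnonzero(bad)[0])}")
    if not np.all(np.isfinite(gr.grf)):
        raise ValueError("NaN in ground reaction input at frame "
                         f"{int(np.flatnonzero(~np.all(np.isfinite(gr.grf), axis=1))[0])}")
    # joint centre definition: fixed point in the proximal segment's frame
    centres = {}
    for j in JOINTS:
        segname, local = joint_centres[j]
        if segname in kin:
            centres[j] = kin[segname].point_trajectory(local)
        elif j == "hip":
            # no pelvis kinematics: use the proximal end of the thigh
            centres[j] = kin["thigh"].origin
        else:
            raise KeyError(f"no kinematics for joint-centre segment {segname!r}")

    chain = (("foot", None, "ankle"), ("shank", "ankle", "knee"),
             ("thigh", "knee", "hip"))
    sl = {j: slice(6 * i, 6 * i + 6) for i, j in enumerate(JOINTS)}
    out = {j: WrenchSeries(np.zeros((nf, 3)), np.zeros((nf, 3)), centres[j])
           for j in JOINTS}
    I3 = np.eye(3)
    for i in range(nf):
        A = np.zeros((18, 18))
        b = np.zeros(18)
        for seg, distal, proximal in chain:
            inert = inertias[seg]
            iw = segment_inertial_wrench(
                inert, rot[seg][i], acc[seg][i], kin[seg].omega[i],
                kin[seg].alpha[i], gravity)
            row = sl[proximal].start  # one 6-row block per segment
            c_p = centres[proximal][i]
            cm = com[seg][i]
            A[row:row + 3, sl[proximal]][:, :3] = I3
            A[row + 3:row + 6, sl[proximal].start:sl[proximal].start + 3] = _skew(c_p - cm)
            A[row + 3:row + 6, sl[proximal].start + 3:sl[proximal].start + 6] = I3
            b[row:row + 3] = iw.force
            b[row + 3:row + 6] = iw.moment
            if distal is None:
                # external ground reaction on the foot
                b[row:row + 3] -= gr.grf[i]
                b[row + 3:row + 6] -= np.cross(gr.cop[i] - cm, gr.grf[i])
                b[row + 3:row + 6] -= gr.free_moment[i] * np.array([0.0, 1.0, 0.0])
            else:
                c_d = centres[distal][i]
                A[row:row + 3, sl[distal].start:sl[distal].start + 3] = -I3
                A[row + 3:row + 6, sl[distal].start:sl[distal].start + 3] = -_skew(c_d - cm)
                A[row + 3:row + 6, sl[distal].start + 3:sl[distal].start + 6] = -I3
        w = np.linalg.solve(A, b)
        for j in JOINTS:
            out[j].force[i] = w[sl[j].start:sl[j].start + 3]
            out[j].moment[i] = w[sl[j].start + 3:sl[j].start + 6]
    return out
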