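"""Muscle lines of action and joint moment arms.

Muscle paths are straight polylines through fixed via points (no wrapping
surfaces). For every joint a muscle is declared to cross, the strand whose
endpoints lie on segments on opposite sides of that joint provides the line
of action; the moment arm column is (p - c) x u with c the joint centre, p a
point on the strand and u the unit pull on the distal side (toward the
proximal attachment). Geometrically this equals minus the derivative of
muscle length with respect to the joint angle (tendon excursion), which the
test suite checks by finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._quat import to_matrix
from .model import JOINTS, MuscleSet

#: chain level of each segment; a joint sits between adjacent levels
_LEVEL = {"foot": 0, "shank": 1, "thigh": 2, "pelvis": 3}
_JOINT_LEVEL = {"ankle": 0.5, "knee": 1.5, "hip": 2.5}

__all__ = ["MusclePathFrame", "compute_paths", "moment_arms",
           "MuscleGeometrySeries", "muscle_geometry_series"]


@dataclass
class MusclePathFrame:
    """One muscle's global polyline at one frame plus per-joint action lines."""

    muscle: str
    polyline: np.ndarray     # (P, 3) global, origin first
    length: float
    #: joint -> (unit pull on the distal side, application point on the strand)
    action: dict


def _strand_for_joint(segments, joint):
    """Index i such that strand (i, i+1) crosses the joint, by segment level."""
    jl = _JOINT_LEVEL[joint]
    for i in range(len(segments) - 1):
        lo, hi = sorted((_LEVEL[segments[i]], _LEVEL[segments[i + 1]]))
        if lo < jl < hi:
            return i
    raise ValueError(f"no path strand crosses joint {joint!r} "
                     f"(segments {segments})")


def compute_paths(muscles: MuscleSet, poses: dict) -> list:
    """Map attachment points to the global frame for one pose frame.

    ``poses[segment] = (q, origin)`` with q scalar-first LCS->GCS. Raises on a
    missing segment pose or a zero-length path.
    """
    rot = {seg: to_matrix(q) for seg, (q, _) in poses.items()}
    org = {seg: np.asarray(o, float) for seg, (_, o) in poses.items()}
    frames = []
    for e in muscles:
        pts, segs = [], []
        for seg, local in e.path_points:
            if seg not in poses:
                raise KeyError(f"{e.name}: no pose for segment {seg!r}")
            pts.append(org[seg] + rot[seg] @ local)
            segs.append(seg)
        poly = np.array(pts)
        seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        if np.any(seglen < 1e-9):
            raise ValueError(f"{e.name}: zero-length path strand")
        action = {}
        for joint in e.crosses:
            i = _strand_for_joint(segs, joint)
            # pull on the distal side points toward the proximal (origin) end
            u = (poly[i] - poly[i + 1]) / seglen[i]
            action[joint] = (u, poly[i + 1])
        frames.append(MusclePathFrame(muscle=e.name, polyline=poly,
                                      length=float(seglen.sum()), action=action))
    return frames


def moment_arms(paths: list, joint_centres: dict) -> np.ndarray:
    """9 x N moment-arm matrix (rows: ankle, knee, hip x global x,y,z).

    Entry block for joint j, muscle i is (p - c_j) x u_i in metres (moment in
    N m per newton of muscle force); exactly zero for joints the muscle does
    not cross.
    """
    R = np.zeros((9, len(paths)))
    for col, pf in enumerate(paths):
        for joint, (u, p) in pf.action.items():
            c = np.asarray(joint_centres[joint], float)
            if not np.all(np.isfinite(c)):
                raise ValueError(f"non-finite centre for joint {joint!r}")
            R[3 * JOINTS.index(joint):3 * JOINTS.index(joint) + 3, col] = \
                np.cross(p - c, u)
    return R


@dataclass
class MuscleGeometrySeries:
    """Vectorized muscle geometry over a whole trial.

    arms: (n, 9, N) moment-arm matrices; lengths: (n, N) path lengths;
    knee_pull: (n, 3, N) unit pull on the shank side for knee-crossing
    muscles (zero columns otherwise); knee_crossing: (N,) bool mask.
    """

    names: list
    arms: np.ndarray
    lengths: np.ndarray
    knee_pull: np.ndarray
    knee_crossing: np.ndarray


def muscle_geometry_series(muscles: MuscleSet, pose_series: dict,
                           joint_centre_series: dict) -> MuscleGeometrySeries:
    """Moment arms and action lines for every frame at once.

    ``pose_series[segment]`` is a UnitQuaternionSeries; ``joint_centre_series``
    maps joint -> (n, 3) global centres.
    """
    rot = {seg: s.rotation_matrices() for seg, s in pose_series.items()}
    org = {seg: s.origin for seg, s in pose_series.items()}
    n = next(iter(org.values())).shape[0]
    N = len(muscles)
    arms = np.zeros((n, 9, N))
    lengths = np.zeros((n, N))
    knee_pull = np.zeros((n, 3, N))
    knee_crossing = np.zeros(N, dtype=bool)
    for col, e in enumerate(muscles):
        pts = []
        segs = []
        for seg, local in e.path_points:
            pts.append(org[seg] + np.einsum("nij,j->ni", rot[seg], local))
            segs.append(seg)
        poly = np.stack(pts, axis=1)                       # (n, P, 3)
        d = np.diff(poly, axis=1)
        seglen = np.linalg.norm(d, axis=2)                 # (n, P-1)
        if np.any(seglen < 1e-9):
            raise ValueError(f"{e.name}: zero-length path strand")
        lengths[:, col] = seglen.sum(axis=1)
        for joint in e.crosses:
            i = _strand_for_joint(segs, joint)
            u = -d[:, i, :] / seglen[:, i, None]
            p = poly[:, i + 1, :]
            c = joint_centre_series[joint]
            j0 = 3 * JOINTS.index(joint)
            arms[:, j0:j0 + 3, col] = np.cross(p - c, u)
            if joint == "knee":
                knee_pull[:, :, col] = u
                knee_crossing[col] = True
    return MuscleGeometrySeries(names=list(muscles.names), arms=arms,
                                lengths=lengths, knee_pull=knee_pull,
                                knee_crossing=knee_crossing)
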