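"""Segment kinematics from skin markers.

Pipeline: per-frame least-squares rigid pose (Horn's closed-form quaternion
method), low-pass filtering matched to a quintic-spline (Woltring-style)
frequency response, sign-continuous quaternion series with finite-difference
velocities/accelerations, and the axial-rotation perturbation used by the
soft-tissue-artifact sensitivity experiment.

Conventions: global frame has Y up (X anterior, Z to the subject's right);
quaternions are scalar-first LCS->GCS; right-multiplying a series by a fixed
quaternion is a rotation about a *local* segment axis. The shank longitudinal
axis is local +y and internal rotation of the (right) shank is positive about
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
from scipy.signal import butter, filtfilt

from ._quat import canonicalize, from_axis_angle, qconj, qmul, qnormalize, to_matrix

AXIAL_WARN_THRESHOLD = 0.15  # rad; above reported soft-tissue-artifact errors

__all__ = [
    "MarkerSet", "UnitQuaternionSeries", "absolute_orientation", "filter_series",
    "differentiate_quaternions", "apply_axial_rotation", "reconstruct_poses",
    "relative_orientation", "joint_angles_zxy",
]


@dataclass
class MarkerSet:
    """Labelled global marker trajectories grouped by segment.

    ``trajectories[segment][label]`` is an (n_frames, 3) array in metres.
    """

    trajectories: dict
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        lengths = {
            arr.shape[0]
            for seg in self.trajectories.values()
            for arr in seg.values()
        }
        if len(lengths) > 1:
            raise ValueError(f"marker trajectories have mixed lengths: {sorted(lengths)}")
        for seg, markers in self.trajectories.items():
            if len(markers) < 3:
                raise ValueError(f"segment {seg!r} has fewer than 3 markers")

    @property
    def n_frames(self) -> int:
        for seg in self.trajectories.values():
            for arr in seg.values():
                return arr.shape[0]
        return 0

    @property
    def segments(self):
        return list(self.trajectories)

    def filtered(self, cutoff: float, mode: str = "woltring") -> "MarkerSet":
        """Low-pass every trajectory component; see :func:`filter_series`."""
        out = {
            seg: {
                name: filter_series(arr, cutoff, self.rate, mode=mode)
                for name, arr in markers.items()
            }
            for seg, markers in self.trajectories.items()
        }
        return MarkerSet(out, self.rate)


@dataclass
class UnitQuaternionSeries:
    """Time series of one segment's pose (orientation + origin) and derivatives."""

    q: np.ndarray          # (n, 4) scalar-first, LCS->GCS
    origin: np.ndarray     # (n, 3) m, global position of the segment origin
    dt: float
    qdot: np.ndarray | None = None
    qddot: np.ndarray | None = None
    omega: np.ndarray | None = None   # (n, 3) rad/s, global frame
    alpha: np.ndarray | None = None   # (n, 3) rad/s^2, global frame

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        norms = np.linalg.norm(self.q, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("quaternion series is not unit-norm to 1e-9")

    @property
    def n_frames(self) -> int:
        return self.q.shape[0]

    def is_sign_continuous(self) -> bool:
        return bool(np.all(np.sum(self.q[1:] * self.q[:-1], axis=-1) >= 0))

    def rotation_matrices(self) -> np.ndarray:
        return to_matrix(self.q)

    def point_trajectory(self, local_point) -> np.ndarray:
        """Global trajectory of a point fixed in the segment frame."""
        return self.origin + np.einsum(
            "nij,j->ni", to_matrix(self.q), np.asarray(local_point, dtype=float))


def absolute_orientation(ref_cloud, obs_cloud, require_noncollinear: bool = True):
    """Least-squares rigid transform mapping ref_cloud onto obs_cloud.

    Horn's closed-form solution: the optimal rotation is the eigenvector of a
    4x4 symmetric matrix built from the cross-covariance of the centred
    clouds, the translation follows from the centroids. Returns ``(q, t)``
    with ``obs ≈ R(q) @ ref + t`` and q canonicalised to w >= 0.
    """
    ref = np.asarray(ref_cloud, dtype=float)
    obs = np.asarray(obs_cloud, dtype=float)
    if ref.shape != obs.shape:
        raise ValueError(f"point counts differ: {ref.shape} vs {obs.shape}")
    if ref.shape[0] < 3 or ref.shape[1] != 3:
        raise ValueError("need at least 3 corresponding 3-D points")
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)
    if require_noncollinear:
        s = np.linalg.svd(ref_c, compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1e-30) or s[0] == 0.0:
            raise ValueError("reference cloud is collinear or degenerate; "
                             "the rotation about the line is unobservable")
    M = ref_c.T @ obs_c  # 3x3 cross-covariance (ref -> obs)
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    N = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(N)
    q = canonicalize(qnormalize(vecs[:, -1]))
    t = obs.mean(axis=0) - to_matrix(q) @ ref.mean(axis=0)
    return q, t


def _third_difference(n: int) -> scipy.sparse.csr_matrix:
    data = np.tile([-1.0, 3.0, -3.0, 1.0], (n - 3, 1))
    offsets = np.arange(n - 3)[:, None] + np.arange(4)[None, :]
    rows = np.repeat(np.arange(n - 3), 4)
    return scipy.sparse.csr_matrix(
        (data.ravel(), (rows, offsets.ravel())), shape=(n - 3, n))


def filter_series(x, cutoff: float, rate: float, mode: str = "woltring"):
    """Zero-phase low-pass filter of a uniformly sampled series.

    ``mode="woltring"`` (default) solves the discrete quintic-smoothing-spline
    problem min Σ(y-x)^2 + c Σ(Δ³y)^2, whose frequency response
    1/(1 + c(2 sin(ωh/2))^6) is matched to a -3 dB amplitude point at
    ``cutoff``. Constant through quadratic trends pass unchanged (the penalty
    annihilates them), which keeps endpoints undistorted.
    ``mode="butterworth"`` is a dual-pass 5th-order Butterworth alternative.

    x may be (n,) or (n, k); filtering runs along axis 0.
    """
    x = np.asarray(x, dtype=float)
    if rate <= 2.0 * cutoff:
        raise ValueError(f"rate ({rate} Hz) must exceed twice the cutoff ({cutoff} Hz)")
    n = x.shape[0]
    if n < 12:
        raise ValueError(f"series of length {n} is shorter than the filter warm-up (12)")
    if mode == "woltring":
        h = 1.0 / rate
        omega_c = 2.0 * np.pi * cutoff
        # amplitude 1/sqrt(2) at omega_c:  1 + lam*omega_c^6 = sqrt(2)
        lam = (np.sqrt(2.0) - 1.0) / omega_c**6
        c = lam / h**6
        D3 = _third_difference(n)
        A = scipy.sparse.eye(n, format="csc") + c * (D3.T @ D3).tocsc()
        solve = scipy.sparse.linalg.factorized(A)
        flat = x.reshape(n, -1)
        out = np.column_stack([solve(flat[:, j]) for j in range(flat.shape[1])])
        return out.reshape(x.shape)
    if mode == "butterworth":
        b, a = butter(5, cutoff / (0.5 * rate))
        return filtfilt(b, a, x, axis=0)
    raise ValueError(f"unknown filter mode {mode!r}")


def differentiate_quaternions(series: UnitQuaternionSeries) -> UnitQuaternionSeries:
    """Attach q̇, q̈ and global angular velocity/acceleration.

    Central differences in the interior, one-sided at the endpoints. The
    angular velocity is the vector part of 2 q̇ ⊗ q* (global frame, since q
    maps LCS->GCS); the angular acceleration is its time derivative.
    """
    if series.n_frames < 5:
        raise ValueError("need at least 5 frames to differentiate")
    if not series.is_sign_continuous():
        raise ValueError("quaternion series is sign-discontinuous; "
                         "canonicalize it (enforce q[i]·q[i-1] >= 0) first")
    dt = series.dt
    qdot = np.gradient(series.q, dt, axis=0)
    qddot = np.gradient(qdot, dt, axis=0)
    omega = 2.0 * qmul(qdot, qconj(series.q))[:, 1:]
    alpha = np.gradient(omega, dt, axis=0)
    if not np.all(np.isfinite(omega)):
        raise ValueError("non-finite angular velocity")
    return replace(series, qdot=qdot, qddot=qddot, omega=omega, alpha=alpha)


def apply_axial_rotation(series: UnitQuaternionSeries, angle: float,
                         axis=(0.0, 1.0, 0.0)) -> UnitQuaternionSeries:
    """Rotate every frame by a fixed angle about a local segment axis.

    Default axis is local +y, the shank longitudinal axis; positive angle is
    internal rotation of a right shank. Right-multiplication makes this a
    local-frame operation: origins are untouched, and derivatives are
    recomputed (the global angular velocity is in fact unchanged by a
    time-constant local offset).
    """
    angle = float(angle)
    if not np.isfinite(angle):
        raise ValueError("offset angle must be finite")
    if abs(angle) > AXIAL_WARN_THRESHOLD:
        warnings.warn(
            f"axial offset {angle:+.3f} rad exceeds {AXIAL_WARN_THRESHOLD} rad, "
            "beyond reported soft-tissue-artifact magnitudes", stacklevel=2)
    if angle == 0.0:
        return series
    r = from_axis_angle(axis, angle)
    q = canonicalize(qmul(series.q, r))
    out = UnitQuaternionSeries(q=qnormalize(q), origin=series.origin, dt=series.dt)
    if series.qdot is not None:
        out = differentiate_quaternions(out)
    return out


def reconstruct_poses(markers: MarkerSet, reference_clouds: dict) -> dict:
    """Per-segment pose series from global markers via Horn's method.

    ``reference_clouds[segment][label]`` gives each marker's fixed position in
    the segment local frame; the recovered translation is therefore the global
    position of the segment origin.
    """
    dt = 1.0 / markers.rate
    poses = {}
    for seg, trajs in markers.trajectories.items():
        if seg not in reference_clouds:
            raise KeyError(f"no reference marker cloud for segment {seg!r}")
        labels = [lab for lab in trajs if lab in reference_clouds[seg]]
        if len(labels) < 3:
            raise ValueError(f"segment {seg!r}: fewer than 3 markers shared "
                             "with the reference cloud")
        ref = np.array([reference_clouds[seg][lab] for lab in labels])
        obs = np.stack([trajs[lab] for lab in labels], axis=1)  # (n, m, 3)
        qs = np.empty((obs.shape[0], 4))
        ts = np.empty((obs.shape[0], 3))
        for i in range(obs.shape[0]):
            qs[i], ts[i] = absolute_orientation(ref, obs[i])
        poses[seg] = UnitQuaternionSeries(q=canonicalize(qs), origin=ts, dt=dt)
    return poses


def relative_orientation(proximal: UnitQuaternionSeries,
                         distal: UnitQuaternionSeries) -> np.ndarray:
    """Orientation of the distal segment in the proximal frame, sign-continuous."""
    return canonicalize(qmul(qconj(proximal.q), distal.q))


def joint_angles_zxy(q_rel: np.ndarray) -> dict:
    """Intrinsic Z-X-Y decomposition of a relative orientation series.

    Returns flexion (= -z angle, so knee flexion is positive), abduction-
    adduction (x) and internal-external rotation (y, internal positive for a
    right limb). With y innermost, a local +y offset adds exactly to the
    rotation channel.
    """
    from scipy.spatial.transform import Rotation

    q_rel = np.atleast_2d(q_rel)
    r = Rotation.from_quat(q_rel[:, [1, 2, 3, 0]])  # to scalar-last
    z, x, y = r.as_euler("ZXY").T
    return {"flexion": -z, "adduction": x, "rotation": y}
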