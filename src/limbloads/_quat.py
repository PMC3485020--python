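"""Minimal scalar-first unit-quaternion helpers.

Convention: q = (w, x, y, z) represents an active rotation from the segment
local frame (LCS) to the global frame (GCS); rotating a local vector v is
``rotate(q, v) = R(q) @ v``. Composition ``qmul(a, b)`` applies b first.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "qmul", "qconj", "qnormalize", "rotate", "to_matrix", "from_axis_angle",
    "canonicalize",
]


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b; inputs broadcast over leading axes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ], axis=-1)


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (…,3,3) of unit quaternion(s) (…,4)."""
    w, x, y, z = np.moveaxis(np.asarray(q, dtype=float), -1, 0)
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
    ], axis=-2)


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v (…,3) by quaternion(s) q (…,4)."""
    return np.einsum("...ij,...j->...i", to_matrix(q), np.asarray(v, dtype=float))


def from_axis_angle(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * float(angle)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Enforce w >= 0 on the first frame and sign continuity thereafter."""
    q = np.array(q, dtype=float)
    if q.ndim == 1:
        return -q if q[0] < 0 else q
    if q[0, 0] < 0:
        q[0] = -q[0]
    for i in range(1, len(q)):
        if np.dot(q[i], q[i - 1]) < 0:
            q[i] = -q[i]
    return q
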