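"""Independent reference implementations used only by the test suite.

Each oracle deliberately re-derives its quantity along a different route
than the package: the inverse-dynamics oracle is an explicit distal-to-
proximal Newton-Euler recursion (the package assembles one linear system);
the force-sharing oracle is a direct grid search; moment arms are checked by
tendon excursion (finite-difference length derivatives); the repeated-
measures ANOVA is a literal sum-of-squares decomposition.
"""

from __future__ import annotations

import numpy as np

from limbloads._quat import from_axis_angle, qmul, to_matrix
from limbloads.inverse_dynamics import com_kinematics
from limbloads.kinematics import UnitQuaternionSeries
from limbloads.muscle_mechanics import compute_paths


def newton_euler_recursion(kin, gr, inertias, joint_centres, frame):
    """Joint wrenches at one frame by explicit bottom-up recursion.

    Returns {joint: (force, moment_at_centre)} computed foot -> shank ->
    thigh, transporting the distal reaction by hand at each step.
    """
    g = np.array([0.0, -9.81, 0.0])
    rot = {s: to_matrix(kin[s].q[frame]) for s in ("foot", "shank", "thigh")}
    com, acc = {}, {}
    for s in ("foot", "shank", "thigh"):
        c, a = com_kinematics(kin[s], inertias[s])
        com[s], acc[s] = c[frame], a[frame]
    centres = {}
    for j, (segname, local) in joint_centres.items():
        src = kin[segname] if segname in kin else kin["thigh"]
        if segname in kin:
            centres[j] = src.origin[frame] + to_matrix(src.q[frame]) @ local
        else:
            centres[j] = kin["thigh"].origin[frame]
    out = {}
    # distal external action on the current segment, expressed at a point
    f_d = gr.grf[frame]
    m_d = np.cross(gr.cop[frame] - com["foot"], gr.grf[frame]) \
        + gr.free_moment[frame] * np.array([0.0, 1.0, 0.0])
    p_d_is_com = True
    chain = (("foot", "ankle"), ("shank", "knee"), ("thigh", "hip"))
    for seg, joint in chain:
        inert = inertias[seg]
        I_g = rot[seg] @ inert.inertia_tensor @ rot[seg].T
        omega = kin[seg].omega[frame]
        alpha = kin[seg].alpha[frame]
        f_inertial = inert.mass * (acc[seg] - g)
        m_inertial = I_g @ alpha + np.cross(omega, I_g @ omega)
        f_p = f_inertial - f_d
        # moments about the segment CoM
        if not p_d_is_com:
            m_d = m_d + np.cross(p_d - com[seg], f_d)
        c = centres[joint]
        m_p = m_inertial - m_d - np.cross(c - com[seg], f_p)
        out[joint] = (f_p, m_p)
        # reaction on the next segment up acts at this joint centre
        f_d, m_d, p_d, p_d_is_com = -f_p, -m_p, c, False
    return out


def brute_force_1dof(arms, pcsa, sigma_max, demand, n=30, resolution=4001):
    """Exhaustive 1-DOF force sharing for exactly two muscles.

    Scans F1 over its admissible interval (F2 determined by equilibrium),
    then refines around the best point. Returns the optimal force pair.
    """
    a1, a2 = arms
    f1max, f2max = pcsa[0] * sigma_max, pcsa[1] * sigma_max

    def objective(f1):
        f2 = (demand - a1 * f1) / a2
        bad = (f2 < 0) | (f2 > f2max)
        val = (f1 / pcsa[0]) ** n + (f2 / pcsa[1]) ** n
        return np.where(bad, np.inf, val), f2

    lo, hi = 0.0, f1max
    best = None
    for _ in range(4):
        f1 = np.linspace(lo, hi, resolution)
        val, f2 = objective(f1)
        i = int(np.argmin(val))
        best = (f1[i], f2[i], val[i])
        span = (hi - lo) / resolution * 4
        lo, hi = max(0.0, f1[i] - span), min(f1max, f1[i] + span)
    return best


def tendon_excursion_arms(muscles, poses, joint_centres, joint, axis,
                          dtheta=1e-6):
    """-dL/dtheta for a small rotation of the distal chain about one axis.

    ``poses`` maps segment -> (q, origin) for one frame. Rotates every
    segment distal to ``joint`` rigidly about the joint centre and returns
    the per-muscle central-difference length derivative (a vector over the
    muscle set; zero for muscles whose length is unaffected).
    """
    distal = {"ankle": ("foot",), "knee": ("shank", "foot"),
              "hip": ("thigh", "shank", "foot")}[joint]
    c = np.asarray(joint_centres[joint], float)
    e = np.zeros(3)
    e[axis] = 1.0

    def lengths(sign):
        r = from_axis_angle(e, sign * dtheta)
        R = to_matrix(r)
        moved = {}
        for seg, (q, org) in poses.items():
            if seg in distal:
                moved[seg] = (qmul(r, q), c + R @ (np.asarray(org) - c))
            else:
                moved[seg] = (q, org)
        return np.array([p.length for p in compute_paths(muscles, moved)])

    return -(lengths(+1.0) - lengths(-1.0)) / (2.0 * dtheta)


def rm_anova_sums_of_squares(data):
    """Literal one-way repeated-measures decomposition (subjects x conds)."""
    data = np.asarray(data, float)
    n_s, n_c = data.shape
    grand = data.mean()
    ss_cond = n_s * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = n_c * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_err = np.sum((data - grand) ** 2) - ss_cond - ss_subj
    f = (ss_cond / (n_c - 1)) / (ss_err / ((n_s - 1) * (n_c - 1)))
    return ss_cond, ss_subj, ss_err, f


def random_smooth_chain(rng, n=64, dt=0.005):
    """Smooth random foot/shank/thigh/pelvis pose series + plate series.

    Sum-of-sinusoid joint-ish motions; not physically meaningful, but smooth
    enough that finite-difference derivatives are well behaved, which is all
    the inverse-dynamics comparison needs.
    """
    t = np.arange(n) * dt

    def smooth_signal(scale):
        out = np.zeros(n)
        for _ in range(3):
            f = rng.uniform(0.5, 4.0)
            out += rng.normal(0, scale) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        return out

    def series(base):
        ang_z = smooth_signal(0.4)
        ang_y = smooth_signal(0.15)
        q = qmul(
            np.stack([np.cos(ang_z / 2), np.zeros(n), np.zeros(n), np.sin(ang_z / 2)], axis=1),
            np.stack([np.cos(ang_y / 2), np.zeros(n), np.sin(ang_y / 2), np.zeros(n)], axis=1))
        org = np.stack([base[0] + smooth_signal(0.05),
                        base[1] + smooth_signal(0.05),
                        base[2] + smooth_signal(0.02)], axis=1)
        return UnitQuaternionSeries(q=q, origin=org, dt=dt)

    kin = {"foot": series((0.0, 0.07, 0.0)), "shank": series((0.0, 0.5, 0.0)),
           "thigh": series((0.0, 0.9, 0.0)), "pelvis": series((0.0, 0.9, 0.0))}
    grf = np.stack([smooth_signal(30.0), 500.0 + smooth_signal(100.0),
                    smooth_signal(20.0)], axis=1)
    cop = np.stack([0.05 + smooth_signal(0.01), np.zeros(n),
                    smooth_signal(0.01)], axis=1)
    return kin, grf, cop
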