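"""Per-frame muscle force sharing.

Minimises the sum of muscle stresses raised to the power n (default 30)
subject to joint-moment equilibrium R F = m and bounds 0 <= F_i <= PCSA_i *
sigma_max. As n grows the solution approaches the min-max (lowest peak
stress) force sharing while remaining unique and smooth; n = 30 is the
working value.

Numerics: the problem is solved in normalised stress variables
x_i = F_i / (PCSA_i sigma_max) in [0, 1], where the objective sum x_i^n is
convex and bounded, with an SLSQP exponent-continuation schedule warm-started
frame to frame. Feasibility is certified first with an exact LP (HiGHS); a
frame is "unsolved" when the equilibrium system admits no force vector within
bounds (or the solver cannot reach the residual tolerance after fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize

__all__ = ["ForceShareProblem", "FrameSolution", "solve_frame", "solve_trial",
           "minmax_peak_stress"]

_CONTINUATION = (2, 6, 14, 30)


@dataclass
class ForceShareProblem:
    """One frame's equilibrium system and bounds.

    arms: (k, N) moment-arm matrix rows in N m per N (k = 9 for full
    ankle/knee/hip equilibrium); m_target: (k,) joint moments to balance;
    pcsa in cm^2; sigma_max in N/cm^2.
    """

    arms: np.ndarray
    m_target: np.ndarray
    pcsa: np.ndarray
    sigma_max: float | np.ndarray
    n_exponent: int = 30

    def __post_init__(self):
        self.arms = np.atleast_2d(np.asarray(self.arms, float))
        self.m_target = np.atleast_1d(np.asarray(self.m_target, float))
        self.pcsa = np.atleast_1d(np.asarray(self.pcsa, float))
        if self.arms.shape != (len(self.m_target), len(self.pcsa)):
            raise ValueError("inconsistent problem dimensions")
        if np.any(self.pcsa <= 0) or np.any(np.asarray(self.sigma_max) <= 0):
            raise ValueError("pcsa and sigma_max must be positive")
        if self.n_exponent < 2:
            raise ValueError("n_exponent must be >= 2")
        if not np.all(np.isfinite(self.arms)):
            raise ValueError("non-finite moment arms")

    @property
    def max_forces(self) -> np.ndarray:
        return self.pcsa * np.asarray(self.sigma_max)

    @property
    def scaled_arms(self) -> np.ndarray:
        """Equilibrium matrix in normalised stress variables x in [0,1]."""
        return self.arms * self.max_forces[None, :]


@dataclass
class FrameSolution:
    """Solved muscle forces for one frame (empty when unsolved)."""

    forces: np.ndarray
    solved: bool
    residual: float
    objective: float = np.nan
    status: str = "ok"
    x: np.ndarray = field(default=None, repr=False)  # normalised stresses


def _feasible_point(p: ForceShareProblem, tol_abs: float):
    """LP phase 1: minimal equilibrium violation over the bound box."""
    A = p.scaled_arms
    k, N = A.shape
    # variables [x, s+, s-]; A x + s+ - s- = m, minimise 1'(s+ + s-)
    c = np.concatenate([np.zeros(N), np.ones(2 * k)])
    A_eq = np.hstack([A, np.eye(k), -np.eye(k)])
    bounds = [(0.0, 1.0)] * N + [(0.0, None)] * (2 * k)
    res = linprog(c, A_eq=A_eq, b_eq=p.m_target, bounds=bounds, method="highs")
    if not res.success:
        return None, np.inf
    return res.x[:N], float(res.fun)


def solve_frame(p: ForceShareProblem, x0: np.ndarray | None = None,
                tol: float = 1e-6) -> FrameSolution:
    """Minimise sum (F_i / pcsa_i)^n subject to equilibrium and bounds.

    Residual tolerance is ``tol * max(1, |m|_inf)``. ``x0`` warm-starts the
    NLP (normalised stresses of a neighbouring frame); the strictly convex
    objective makes the minimiser unique, so warm starting changes nothing
    beyond tolerance.
    """
    A = p.scaled_arms
    m = p.m_target
    tol_abs = tol * max(1.0, np.max(np.abs(m)))
    xf, violation = _feasible_point(p, tol_abs)
    if xf is None or violation > tol_abs:
        return FrameSolution(forces=np.empty(0), solved=False,
                             residual=float(violation), status="infeasible")
    N = A.shape[1]
    # rescale by the min-max peak stress so the optimum sits near y = 1:
    # x^30 is numerically flat for small x, which stalls gradient methods
    t_star = minmax_peak_stress(p)
    if t_star is None or t_star < 1e-12:
        x = np.zeros(N)
        resid = float(np.max(np.abs(A @ x - m)))
        if resid <= tol_abs:
            return FrameSolution(forces=x * p.max_forces, solved=True,
                                 residual=resid, objective=0.0, x=x)
        t_star = max(float(np.max(xf)), 1e-9)
    sigma = t_star
    As = A * sigma
    y_hi = 1.0 / sigma
    cons = {"type": "eq", "fun": lambda y: As @ y - m, "jac": lambda y: As}
    bounds = [(0.0, y_hi)] * N

    def _solve_from(y_start, exponents):
        y = np.clip(np.asarray(y_start, float), 0.0, y_hi)
        for n in exponents:
            fun = lambda y, n=n: float(np.sum(y**n))
            jac = lambda y, n=n: n * y**(n - 1)
            res = minimize(fun, y, jac=jac, bounds=bounds, constraints=[cons],
                           method="SLSQP",
                           options={"maxiter": 300, "ftol": 1e-14})
            if np.all(np.isfinite(res.x)):
                y = np.clip(res.x, 0.0, y_hi)
        return y

    schedule = tuple(n for n in _CONTINUATION if n < p.n_exponent) + (p.n_exponent,)
    if x0 is not None and len(x0) == N:
        y = _solve_from(np.asarray(x0, float) / sigma, (p.n_exponent,))
        if np.max(np.abs(As @ y - m)) > tol_abs:
            y = _solve_from(xf / sigma, schedule)
    else:
        y = _solve_from(xf / sigma, schedule)
    resid = float(np.max(np.abs(As @ y - m)))
    if resid > tol_abs:
        return FrameSolution(forces=np.empty(0), solved=False, residual=resid,
                             status="no_convergence")
    x = y * sigma
    return FrameSolution(forces=x * p.max_forces, solved=True, residual=resid,
                         objective=float(np.sum(x**p.n_exponent)), x=x)


def solve_trial(problems, tol: float = 1e-6, warm_start: bool = True):
    """Independent per-frame solves, warm-started from the previous frame.

    Returns (solutions, unsolved_indices); unsolved frames are excluded from
    all downstream summaries.
    """
    problems = list(problems)
    if not problems:
        raise ValueError("empty problem list")
    solutions, unsolved = [], []
    x_prev = None
    for i, p in enumerate(problems):
        sol = solve_frame(p, x0=x_prev if warm_start else None, tol=tol)
        solutions.append(sol)
        if sol.solved:
            x_prev = sol.x
        else:
            unsolved.append(i)
    return solutions, unsolved


def minmax_peak_stress(p: ForceShareProblem) -> float | None:
    """Exact minimum achievable peak normalised stress (LP).

    Solves min t s.t. A x = m, 0 <= x_i <= t <= 1. Returns None when the
    equilibrium is infeasible within bounds. This is the n -> infinity limit
    the power-n criterion approaches.
    """
    A = p.scaled_arms
    k, N = A.shape
    c = np.concatenate([np.zeros(N), [1.0]])
    A_eq = np.hstack([A, np.zeros((k, 1))])
    A_ub = np.hstack([np.eye(N), -np.ones((N, 1))])  # x_i - t <= 0
    bounds = [(0.0, 1.0)] * N + [(0.0, 1.0)]
    res = linprog(c, A_eq=A_eq, b_eq=p.m_target, A_ub=A_ub,
                  b_ub=np.zeros(N), bounds=bounds, method="highs")
    if not res.success:
        return None
    return float(res.x[-1])
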