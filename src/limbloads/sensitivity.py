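"""The two sensitivity experiments, end to end.

A battery runs the full pipeline (pose reconstruction -> inverse dynamics ->
muscle force sharing -> knee loads -> phase summaries) once per condition:

* rotation conditions perturb only the shank orientation stream by a fixed
  axial offset (default -0.1, -0.05, 0, +0.05, +0.1 rad, internal positive);
* the bounds condition doubles only the PCSA of the five knee rotators
  (gracilis, plantaris, popliteus, sartorius, TFL).

Everything else is bit-identical across conditions. Because the shank tensor
is axisymmetric about its long axis, the rotation conditions leave every
joint wrench unchanged; only the muscle attachment geometry (hence moment
arms, muscle forces and knee loads) responds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inverse_dynamics import GroundReaction, solve_chain
from .joint_loads import knee_load_frame
from .kinematics import (MarkerSet, apply_axial_rotation,
                         differentiate_quaternions, filter_series,
                         joint_angles_zxy, reconstruct_poses,
                         relative_orientation)
from .model import (KNEE_ROTATORS, QUADRICEPS, ScaledModel, SubjectAnthro,
                    build_model, double_pcsa)
from .muscle_mechanics import muscle_geometry_series
from .optimizer import ForceShareProblem, solve_trial
from .pipeline_stats import PHASE_NAMES, JumpPhases, segment_phases, summarize_phase

__all__ = ["Condition", "ConditionResult", "default_battery", "run_battery",
           "run_condition", "compare_to_original"]

DEFAULT_OFFSETS = (-0.1, -0.05, 0.0, 0.05, 0.1)


@dataclass(frozen=True)
class Condition:
    """One model condition: an axial-rotation offset or a bound multiplier."""

    kind: str                       # "rotation" | "bounds"
    rotation_offset: float = 0.0    # rad, internal positive
    bound_multiplier: float = 1.0   # applied to the five knee rotators
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("rotation", "bounds"):
            raise ValueError(f"unknown condition kind {self.kind!r}")

    @property
    def is_original(self) -> bool:
        return (self.kind == "rotation" and self.rotation_offset == 0.0)


def default_battery(offsets=DEFAULT_OFFSETS, include_bounds: bool = True):
    """The study's condition battery: five rotations plus doubled bounds."""
    conds = [Condition(kind="rotation", rotation_offset=o,
                       label="original" if o == 0.0 else f"rot{o:+.2f}")
             for o in offsets]
    if sum(c.is_original for c in conds) != 1:
        raise ValueError("battery must contain the original (0 rad) exactly once")
    if include_bounds:
        conds.append(Condition(kind="bounds", bound_multiplier=2.0,
                               label="double_bound"))
    return conds


@dataclass
class ConditionResult:
    condition: Condition
    loads: dict = None             # quantity -> (n,) smoothed series
    muscle_forces: pd.DataFrame = None   # n x five knee rotators, smoothed
    all_forces: np.ndarray = None  # (n, N) raw solved forces (NaN unsolved)
    solved: np.ndarray = None      # (n,) bool
    residuals: np.ndarray = None   # (n,) equilibrium residual, N m
    m_targets: np.ndarray = None   # (n, 9) joint-moment demands
    unsolved_pct: float = np.nan
    phases: JumpPhases = None
    summary: object = None         # PhaseSummary
    wrenches: dict = None          # joint -> WrenchSeries
    flexion: np.ndarray = None
    bodyweight: float = np.nan
    error: str | None = None


def _prepare_kinematics(markers: MarkerSet, model: ScaledModel, config):
    """Filter markers, reconstruct segment poses, attach derivatives."""
    filtered = markers.filtered(config.cutoff, mode=config.filter_mode)
    poses = reconstruct_poses(filtered, model.marker_clouds)
    return {seg: differentiate_quaternions(s) for seg, s in poses.items()}


def run_condition(poses: dict, gr: GroundReaction, model: ScaledModel,
                  config, condition: Condition) -> ConditionResult:
    """Run the model once for a single condition.

    ``poses`` must contain foot/shank/thigh/pelvis series with derivatives;
    only the intended stream (shank orientation or knee-rotator PCSA) is
    modified here.
    """
    kin = dict(poses)
    muscles = model.muscles
    if condition.kind == "rotation" and condition.rotation_offset != 0.0:
        kin["shank"] = apply_axial_rotation(kin["shank"], condition.rotation_offset)
    if condition.kind == "bounds" and condition.bound_multiplier != 1.0:
        if condition.bound_multiplier != 2.0:
            mult = condition.bound_multiplier
            raise ValueError(f"only x2 bound multipliers are supported, got {mult}")
        muscles = double_pcsa(muscles, KNEE_ROTATORS)

    wrenches = solve_chain(kin, gr, model.inertias, model.joint_centres)
    centres = {}
    for joint, (seg, local) in model.joint_centres.items():
        src = kin[seg] if seg in kin else kin["thigh"]
        centres[joint] = src.point_trajectory(local) if seg in kin else kin["thigh"].origin
    geom = muscle_geometry_series(muscles, kin, centres)
    n = gr.n_frames
    m_target = np.hstack([wrenches[j].moment for j in ("ankle", "knee", "hip")])
    pcsa = muscles.pcsas
    sigma = muscles[muscles.names[0]].sigma_max
    problems = [ForceShareProblem(arms=geom.arms[i], m_target=m_target[i],
                                  pcsa=pcsa, sigma_max=sigma,
                                  n_exponent=config.n_exponent)
                for i in range(n)]
    solutions, unsolved = solve_trial(problems, tol=config.solver_tol)
    solved = np.array([s.solved for s in solutions])
    residuals = np.array([s.residual for s in solutions])
    N = len(muscles)
    forces = np.full((n, N), np.nan)
    for i, s in enumerate(solutions):
        if s.solved:
            forces[i] = s.forces

    angles = joint_angles_zxy(relative_orientation(kin["thigh"], kin["shank"]))
    flexion = angles["flexion"]
    quad_idx = [muscles.names.index(q) for q in QUADRICEPS]
    R_shank = kin["shank"].rotation_matrices()
    load_keys = ("shear_ap", "shear_ml", "tfj", "pfj")
    loads_raw = {k: np.full(n, np.nan) for k in load_keys}
    for i in range(n):
        if not solved[i]:
            continue
        lf = knee_load_frame(wrenches["knee"].force[i], forces[i],
                             geom.knee_pull[i], R_shank[i],
                             float(np.sum(forces[i, quad_idx])), flexion[i])
        loads_raw["shear_ap"][i] = lf.shear_ap
        loads_raw["shear_ml"][i] = lf.shear_ml
        loads_raw["tfj"][i] = lf.tfj_magnitude
        loads_raw["pfj"][i] = lf.pfj_contact

    # unsolved frames are removed, the remaining series smoothed; summaries
    # only ever read solved frames
    loads = {k: _smooth_masked(v, solved, gr.rate, config)
             for k, v in loads_raw.items()}
    rot_forces = {m: _smooth_masked(forces[:, muscles.names.index(m)],
                                    solved, gr.rate, config)
                  for m in KNEE_ROTATORS}
    phases = segment_phases(flexion, gr.grf[:, 1], gr.rate,
                            threshold=config.flight_threshold)
    summary = summarize_phase(loads, rot_forces, phases,
                              model.anthro.bodyweight, solved_mask=solved)
    return ConditionResult(
        condition=condition, loads=loads,
        muscle_forces=pd.DataFrame(rot_forces), all_forces=forces,
        solved=solved, unsolved_pct=100.0 * len(unsolved) / n,
        residuals=residuals, m_targets=m_target,
        phases=phases, summary=summary, wrenches=wrenches, flexion=flexion,
        bodyweight=model.anthro.bodyweight)


def _smooth_masked(x: np.ndarray, solved: np.ndarray, rate: float, config):
    """Interpolate across unsolved frames, then low-pass like any model output."""
    y = np.asarray(x, float).copy()
    if not solved.all():
        idx = np.arange(len(y))
        y = np.interp(idx, idx[solved], y[solved])
    return filter_series(y, config.cutoff, rate, mode=config.filter_mode)


def run_battery(markers: MarkerSet, gr: GroundReaction, anthro: SubjectAnthro,
                config, conditions=None, model: ScaledModel | None = None):
    """Run every condition on one trial; per-condition failures do not abort."""
    if model is None:
        model = build_model(anthro, sigma_max=config.sigma_max)
    if conditions is None:
        conditions = default_battery(tuple(config.rotation_offsets))
    poses = _prepare_kinematics(markers, model, config)
    results = []
    for cond in conditions:
        try:
            results.append(run_condition(poses, gr, model, config, cond))
        except Exception as exc:  # noqa: BLE001 - battery must keep going
            results.append(ConditionResult(condition=cond, error=str(exc)))
    return results


def compare_to_original(results, own_peak: bool = False) -> dict:
    """Percentage-change tables (quantity x phase) for each altered condition.

    Changes are 100 (altered - original) / original, computed on frames
    solved in *both* conditions ("corresponding frames"). ``own_peak=True``
    instead compares each condition's own peaks over its own solved frames.
    An original value of zero yields NaN (undefined), never infinity.
    """
    orig = [r for r in results if r.error is None and r.condition.is_original]
    if len(orig) != 1:
        raise ValueError("results must contain exactly one original condition")
    orig = orig[0]
    tables = {}
    for r in results:
        if r is orig or r.error is not None:
            continue
        if own_peak:
            so, sa = orig.summary, r.summary
        else:
            common = orig.solved & r.solved
            so = summarize_phase(orig.loads, {m: orig.muscle_forces[m].to_numpy()
                                              for m in orig.muscle_forces},
                                 orig.phases, orig.bodyweight, solved_mask=common)
            sa = summarize_phase(r.loads, {m: r.muscle_forces[m].to_numpy()
                                           for m in r.muscle_forces},
                                 orig.phases, orig.bodyweight, solved_mask=common)
        rows = {}
        for qty in so.peaks.columns:
            rows[qty] = _pct(sa.peaks[qty], so.peaks[qty])
        for m in so.aucs.columns:
            rows[m] = _pct(sa.aucs[m], so.aucs[m])
        tables[r.condition.label] = pd.DataFrame(rows).T[list(PHASE_NAMES)]
    return tables


def _pct(altered: pd.Series, original: pd.Series) -> pd.Series:
    out = 100.0 * (altered - original) / original
    return out.where(original != 0.0, np.nan)
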