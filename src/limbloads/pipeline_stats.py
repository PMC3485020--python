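"""Jump-phase segmentation, phase summaries, and the statistical battery.

The counter-movement jump is segmented into four phases: (1) counter
movement and (2) take-off, separated by the instant of deepest knee flexion
before flight; the airborne interval; then (3) landing and (4) recovery,
separated by the deepest flexion after flight. Per phase the peak knee loads
(bodyweight-normalised) and per-muscle force-time integrals (normalised by
bodyweight x airborne duration) are summarised, and conditions are compared
across subjects with repeated-measures ANOVA (Bonferroni post hoc) or paired
t-tests at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

PHASE_NAMES = ("counter_movement", "take_off", "landing", "recovery")
DEFAULT_FLIGHT_THRESHOLD = 10.0  # N vertical GRF

__all__ = ["JumpPhases", "PhaseSummary", "StatsOutcome", "segment_phases",
           "summarize_phase", "rm_anova_with_posthoc", "paired_t",
           "PHASE_NAMES"]


@dataclass
class JumpPhases:
    """Frame ranges [start, stop) of the four phases and the flight interval."""

    boundaries: dict          # phase name -> (start, stop)
    airborne: tuple           # (start, stop) frames with no ground contact
    airborne_duration: float  # s
    rate: float

    def __post_init__(self):
        b = self.boundaries
        order = [b[p] for p in PHASE_NAMES]
        flat = [order[0][0], order[0][1], order[1][0], order[1][1],
                self.airborne[0], self.airborne[1],
                order[2][0], order[2][1], order[3][0], order[3][1]]
        if any(flat[i] > flat[i + 1] for i in range(len(flat) - 1)):
            raise ValueError("phases must be ordered and non-overlapping, "
                             "with flight between take-off and landing")

    def frames(self, phase: str) -> np.ndarray:
        a, b = self.boundaries[phase]
        return np.arange(a, b)


def segment_phases(knee_flexion, grf_vertical, rate: float,
                   threshold: float = DEFAULT_FLIGHT_THRESHOLD) -> JumpPhases:
    """Locate the four phases from knee flexion and vertical GRF.

    The airborne interval is the contiguous run of frames with vertical GRF
    below ``threshold``; exactly one such run (not touching the trial edges)
    must exist. Phase boundaries 1/2 and 3/4 are the knee-flexion maxima of
    the pre-flight and post-flight contact intervals (first frame on a
    plateau).
    """
    knee_flexion = np.asarray(knee_flexion, float)
    grf_vertical = np.asarray(grf_vertical, float)
    if knee_flexion.shape != grf_vertical.shape:
        raise ValueError("series must be synchronized (equal length)")
    low = grf_vertical < threshold
    edges = np.flatnonzero(np.diff(low.astype(int)))
    runs = []
    start = 0 if low[0] else None
    for e in edges:
        if low[e + 1] and start is None:
            start = e + 1
        elif not low[e + 1] and start is not None:
            runs.append((start, e + 1))
            start = None
    if start is not None:
        runs.append((start, len(low)))
    if len(runs) != 1:
        raise ValueError(f"expected exactly one flight interval, found {len(runs)}")
    a0, a1 = runs[0]
    if a0 == 0 or a1 == len(low):
        raise ValueError("flight interval touches the trial boundary")
    dip_pre = int(np.argmax(knee_flexion[:a0]))
    dip_post = a1 + int(np.argmax(knee_flexion[a1:]))
    return JumpPhases(
        boundaries={
            "counter_movement": (0, dip_pre),
            "take_off": (dip_pre, a0),
            "landing": (a1, dip_post),
            "recovery": (dip_post, len(low)),
        },
        airborne=(a0, a1),
        airborne_duration=(a1 - a0) / rate,
        rate=rate,
    )


@dataclass
class PhaseSummary:
    """Per-phase peak loads (bodyweight units) and muscle AUCs (dimensionless)."""

    peaks: pd.DataFrame   # index: phase, columns: load quantity
    aucs: pd.DataFrame    # index: phase, columns: muscle


def _signed_extremum(x: np.ndarray) -> float:
    """Signed value of largest magnitude (ties -> earliest)."""
    if x.size == 0:
        return np.nan
    return float(x[np.argmax(np.abs(x))])


def summarize_phase(loads: dict, muscle_forces: dict, phases: JumpPhases,
                    bodyweight: float, solved_mask=None) -> PhaseSummary:
    """Phase-wise peaks and force-time integrals.

    loads: quantity -> (n,) series (``shear_ap`` uses the signed extremum of
    largest magnitude, others the maximum); muscle_forces: muscle -> (n,)
    newtons. Peaks are in bodyweight units; AUCs are trapezoidal integrals
    over the solved frames of each phase divided by bodyweight x airborne
    duration. Unsolved frames are excluded.
    """
    if bodyweight <= 0:
        raise ValueError("bodyweight must be positive")
    n = len(next(iter(loads.values())))
    solved = np.ones(n, bool) if solved_mask is None else np.asarray(solved_mask, bool)
    t = np.arange(n) / phases.rate
    peaks, aucs = {}, {}
    for phase in PHASE_NAMES:
        idx = phases.frames(phase)
        idx = idx[solved[idx]]
        row = {}
        for qty, series in loads.items():
            seg = np.asarray(series, float)[idx]
            val = _signed_extremum(seg) if qty == "shear_ap" else \
                (np.nan if seg.size == 0 else float(np.max(seg)))
            row[qty] = val / bodyweight
        peaks[phase] = row
        aucs[phase] = {
            m: (0.0 if idx.size < 2 else float(
                np.trapezoid(np.asarray(f, float)[idx], t[idx])))
            / (bodyweight * phases.airborne_duration)
            for m, f in muscle_forces.items()
        }
    return PhaseSummary(peaks=pd.DataFrame(peaks).T.loc[list(PHASE_NAMES)],
                        aucs=pd.DataFrame(aucs).T.loc[list(PHASE_NAMES)])


@dataclass
class StatsOutcome:
    test: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def rm_anova_with_posthoc(values: pd.DataFrame, baseline: str) -> StatsOutcome:
    """One-way repeated-measures ANOVA across conditions, Bonferroni post hoc.

    values: subjects x conditions (no missing cells; incomplete subjects are
    dropped). Post hoc: paired t of every other condition against
    ``baseline``, p adjusted as min(1, k * p).
    """
    values = values.dropna(axis=0)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    data = values.to_numpy(float)
    n_s, n_c = data.shape
    grand = data.mean()
    ss_cond = n_s * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = n_c * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = n_c - 1
    df_err = (n_s - 1) * (n_c - 1)
    scale = max(ss_tot, 1.0)
    if ss_cond / scale < 1e-14:
        f_stat, p = 0.0, 1.0
    elif ss_err / scale < 1e-14:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_cond / df_cond) / (ss_err / df_err)
        p = float(_sps.f.sf(f_stat, df_cond, df_err))
    others = [c for c in values.columns if c != baseline]
    rows = []
    for c in others:
        t_out = paired_t(values[c].to_numpy(), values[baseline].to_numpy())
        rows.append({"condition": c, "t": t_out.statistic,
                     "p_raw": t_out.p_value,
                     "p_adj": min(1.0, len(others) * t_out.p_value)})
    return StatsOutcome(test="rm_anova", statistic=float(f_stat), p_value=float(p),
                        posthoc=pd.DataFrame(rows))


def paired_t(a, b) -> StatsOutcome:
    """Two-sided paired t-test with a degenerate-difference sentinel.

    A constant nonzero difference has zero variance: the statistic is
    reported as +/-inf with p = 0; an all-zero difference gives t = 0, p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return StatsOutcome(test="paired_t", statistic=0.0, p_value=1.0)
        return StatsOutcome(test="paired_t",
                            statistic=float(np.sign(d[0]) * np.inf), p_value=0.0)
    t, p = _sps.ttest_rel(a, b)
    return StatsOutcome(test="paired_t", statistic=float(t), p_value=float(p))
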