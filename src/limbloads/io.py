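"""File formats and run configuration.

Canonical interchange is plain delimited text: a TRC-style tab-delimited
marker file (mm, converted to metres on read; marker labels encode the
segment as ``segment:label``), a CSV marker dialect, and a CSV force-plate
file (time, GRF vector, CoP, optional vertical free moment). Configuration
is a flat YAML mapping.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inverse_dynamics import GroundReaction
from .kinematics import MarkerSet
from .model import KNEE_ROTATORS

__all__ = ["RunConfig", "read_markers", "write_markers", "read_forceplate",
           "write_forceplate"]


@dataclass
class RunConfig:
    """Run parameters; the defaults reproduce the standard battery."""

    cutoff: float = 10.0            # Hz, low-pass cutoff for inputs & outputs
    rate: float = 200.0             # Hz, expected sample rate
    n_exponent: int = 30            # stress-power of the force-sharing cost
    sigma_max: float = 61.0         # N/cm^2, maximum permitted muscle stress
    rotation_offsets: tuple = (-0.1, -0.05, 0.0, 0.05, 0.1)  # rad
    knee_rotators: tuple = KNEE_ROTATORS
    flight_threshold: float = 10.0  # N, vertical GRF below which airborne
    solver_tol: float = 1e-6        # scaled equilibrium residual tolerance
    filter_mode: str = "woltring"   # or "butterworth"
    seed: int = 0
    out_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key in ("rotation_offsets", "knee_rotators"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["rotation_offsets"] = list(self.rotation_offsets)
        data["knee_rotators"] = list(self.knee_rotators)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _columns(markers: MarkerSet):
    return [(seg, lab) for seg in markers.trajectories
            for lab in markers.trajectories[seg]]


def write_markers(path, markers: MarkerSet, dialect: str = "trc") -> None:
    path = Path(path)
    cols = _columns(markers)
    n = markers.n_frames
    t = np.arange(n) / markers.rate
    if dialect == "trc":
        with open(path, "w") as fh:
            fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
            fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                     "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
            fh.write(f"{markers.rate:g}\t{markers.rate:g}\t{n}\t{len(cols)}\t"
                     f"mm\t{markers.rate:g}\t1\t{n}\n")
            fh.write("Frame#\tTime\t" +
                     "\t\t\t".join(f"{s}:{l}" for s, l in cols) + "\t\t\n")
            fh.write("\t\t" + "\t".join(
                f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(cols))) + "\n")
            for i in range(n):
                row = [str(i + 1), f"{t[i]:.6f}"]
                for s, l in cols:
                    row.extend(f"{v * 1000.0:.8f}"
                               for v in markers.trajectories[s][l][i])
                fh.write("\t".join(row) + "\n")
    elif dialect == "csv":
        data = {"time": t}
        for s, l in cols:
            for k, ax in enumerate("xyz"):
                data[f"{s}:{l}_{ax}"] = markers.trajectories[s][l][:, k]
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_markers(path, dialect: str | None = None) -> MarkerSet:
    """Read a marker file (TRC-like or CSV dialect; inferred from suffix)."""
    path = Path(path)
    if dialect is None:
        dialect = "trc" if path.suffix.lower() == ".trc" else "csv"
    if dialect == "trc":
        with open(path) as fh:
            lines = fh.read().splitlines()
        meta = lines[2].split("\t")
        rate, n, n_mark = float(meta[0]), int(meta[2]), int(meta[3])
        unit = meta[4]
        scale = {"mm": 1e-3, "m": 1.0}[unit]
        labels = [c for c in lines[3].split("\t")[2:] if c]
        if len(labels) != n_mark:
            raise ValueError("marker count disagrees with header")
        raw = np.full((n, 3 * n_mark), np.nan)
        for i, line in enumerate(lines[5:5 + n]):
            vals = line.split("\t")[2:]
            for j, v in enumerate(vals[:3 * n_mark]):
                if v.strip():
                    raw[i, j] = float(v)
        trajs: dict = {}
        for j, name in enumerate(labels):
            seg, lab = name.split(":")
            block = raw[:, 3 * j:3 * j + 3] * scale
            bad = np.flatnonzero(~np.all(np.isfinite(block), axis=1))
            if bad.size:
                raise ValueError(f"missing sample for marker {name!r} "
                                 f"at frame {int(bad[0])}")
            trajs.setdefault(seg, {})[lab] = block
        return MarkerSet(trajs, rate)
    if dialect == "csv":
        df = pd.read_csv(path)
        t = df["time"].to_numpy()
        rate = 1.0 / np.mean(np.diff(t))
        trajs = {}
        names = sorted({c.rsplit("_", 1)[0] for c in df.columns if c != "time"})
        for name in names:
            seg, lab = name.split(":")
            block = df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy()
            bad = np.flatnonzero(~np.all(np.isfinite(block), axis=1))
            if bad.size:
                raise ValueError(f"missing sample for marker {name!r} "
                                 f"at frame {int(bad[0])}")
            trajs.setdefault(seg, {})[lab] = block
        return MarkerSet(trajs, float(np.round(rate, 6)))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_forceplate(path, gr: GroundReaction) -> None:
    t = np.arange(gr.n_frames) / gr.rate
    df = pd.DataFrame({
        "time": t,
        "fx": gr.grf[:, 0], "fy": gr.grf[:, 1], "fz": gr.grf[:, 2],
        "copx": gr.cop[:, 0], "copy": gr.cop[:, 1], "copz": gr.cop[:, 2],
        "tz": gr.free_moment,
    })
    df.to_csv(path, index=False, float_format="%.10g")


def read_forceplate(path, expected_rate: float | None = None,
                    rotation=None) -> GroundReaction:
    """Read a force-plate CSV; optional 3x3 plate-to-global rotation."""
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    rate = float(np.round(1.0 / np.mean(np.diff(t)), 6))
    if expected_rate is not None and abs(rate - expected_rate) > 1e-3:
        raise ValueError(f"force-plate rate {rate} Hz does not match the "
                         f"expected {expected_rate} Hz")
    grf = df[["fx", "fy", "fz"]].to_numpy()
    cop = df[["copx", "copy", "copz"]].to_numpy()
    if rotation is not None:
        R = np.asarray(rotation, float)
        grf = grf @ R.T
        cop = cop @ R.T
    tz = df["tz"].to_numpy() if "tz" in df else None
    return GroundReaction(grf=grf, cop=cop, rate=rate, free_moment=tz)
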