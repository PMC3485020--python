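"""Subject scaling and the packaged musculoskeletal dataset.

Four rigid segments (foot, shank, thigh, pelvis) joined by 3-DOF ball joints
at the ankle, knee and hip. Inertial parameters scale with body mass and
stature through a packaged coefficient table; muscle attachment geometry is a
reduced 24-element set scaled linearly from a 1.79 m reference skeleton.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SEGMENTS = ("foot", "shank", "thigh", "pelvis")
JOINTS = ("ankle", "knee", "hip")
#: joint centre = fixed point in the *proximal* segment's frame
JOINT_CENTRE_SEGMENT = {"ankle": "shank", "knee": "thigh", "hip": "pelvis"}
KNEE_ROTATORS = ("gracilis", "plantaris", "popliteus", "sartorius", "tfl")
QUADRICEPS = ("vas_lat", "vas_med", "vas_int", "rect_fem")
REFERENCE_HEIGHT = 1.79  # m, stature of the packaged reference geometry
DEFAULT_SIGMA_MAX = 61.0  # N/cm^2, maximum permitted muscle stress
#: mass fraction of head + arms + trunk above the pelvis segment
HAT_MASS_FRAC = 0.4911
HAT_COM_PELVIS = np.array([-0.02, 0.26, -0.09])  # m at reference stature


def _data(name: str) -> "importlib.resources.abc.Traversable":
    return importlib.resources.files("limbloads.data").joinpath(name)


def load_table(name: str) -> pd.DataFrame:
    with importlib.resources.as_file(_data(name)) as path:
        return pd.read_csv(path, comment="#")


@dataclass(frozen=True)
class SubjectAnthro:
    """Subject mass (kg), stature (m) and an identifying label."""

    mass: float
    height: float
    id: str = "subject"

    def __post_init__(self):
        if self.mass < 0 or self.height <= 0:
            raise ValueError("mass must be >= 0 and height > 0")

    @property
    def bodyweight(self) -> float:
        """Weight in newtons (g = 9.81 m/s^2)."""
        return self.mass * 9.81


@dataclass(frozen=True)
class SegmentInertia:
    segment: str
    mass: float
    com_offset: np.ndarray       # m, in the segment frame
    inertia_tensor: np.ndarray   # kg m^2, about the CoM, segment frame
    length: float = 0.0          # m, segment length (bookkeeping)

    def __post_init__(self):
        object.__setattr__(self, "com_offset", np.asarray(self.com_offset, float))
        object.__setattr__(self, "inertia_tensor",
                           np.asarray(self.inertia_tensor, float))
        I = self.inertia_tensor
        if self.mass < 0:
            raise ValueError("segment mass must be non-negative")
        if not np.allclose(I, I.T, atol=1e-12):
            raise ValueError("inertia tensor must be symmetric")
        if np.any(np.linalg.eigvalsh(I) < -1e-12):
            raise ValueError("inertia tensor must be positive semi-definite")


def scale_inertia(anthro: SubjectAnthro, segment: str,
                  coeffs: pd.DataFrame | None = None) -> SegmentInertia:
    """Inertial parameters of one segment from mass/stature scaling.

    Segment mass is a fixed fraction of body mass; segment length scales with
    stature; the CoM offset and the radii of gyration scale with segment
    length; the tensor is diagonal in the segment frame, I_aa = m (r_a L)^2.
    """
    if coeffs is None:
        coeffs = load_table("de_leva.csv")
    row = coeffs[coeffs["segment"] == segment]
    if row.empty:
        raise KeyError(
            f"unknown segment {segment!r}; valid: {sorted(coeffs['segment'])}")
    row = row.iloc[0]
    L = row["length_frac"] * anthro.height
    m = row["mass_frac"] * anthro.mass
    com = np.array([row["com_x"], row["com_y"], row["com_z"]]) * L
    radii = np.array([row["r_x"], row["r_y"], row["r_z"]]) * L
    return SegmentInertia(segment=segment, mass=m, com_offset=com,
                          inertia_tensor=np.diag(m * radii**2), length=L)


@dataclass(frozen=True)
class MuscleElement:
    """One muscle line element: path geometry, PCSA and maximum stress.

    ``origin``/``insertion`` are (segment, xyz-in-segment-frame) pairs;
    ``via_points`` is an ordered list of the same. ``crosses`` declares which
    of ankle/knee/hip the element spans. The upper force bound is
    pcsa * sigma_max (PCSA in cm^2, sigma_max in N/cm^2).
    """

    name: str
    origin: tuple
    insertion: tuple
    pcsa: float
    sigma_max: float = DEFAULT_SIGMA_MAX
    via_points: tuple = ()
    crosses: tuple = ()

    def __post_init__(self):
        if self.pcsa <= 0 or self.sigma_max <= 0:
            raise ValueError(f"{self.name}: pcsa and sigma_max must be positive")
        if not self.crosses:
            raise ValueError(f"{self.name}: must cross at least one joint")
        if self.origin[0] == self.insertion[0] and not self.via_points:
            raise ValueError(f"{self.name}: origin and insertion on the same "
                             "segment without via points spans no joint")

    @property
    def max_force(self) -> float:
        return self.pcsa * self.sigma_max

    @property
    def path_points(self) -> tuple:
        return (self.origin, *self.via_points, self.insertion)


@dataclass(frozen=True)
class MuscleSet:
    elements: tuple

    def __post_init__(self):
        names = [e.name for e in self.elements]
        if len(set(names)) != len(names):
            raise ValueError("muscle names must be unique")
        missing = set(KNEE_ROTATORS) - set(names)
        if missing:
            raise ValueError(f"knee rotators missing from the set: {sorted(missing)}")

    @property
    def names(self) -> list:
        return [e.name for e in self.elements]

    def __len__(self):
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, name: str) -> MuscleElement:
        for e in self.elements:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def max_forces(self) -> np.ndarray:
        return np.array([e.max_force for e in self.elements])

    @property
    def pcsas(self) -> np.ndarray:
        return np.array([e.pcsa for e in self.elements])


def load_reference_muscles(sigma_max: float = DEFAULT_SIGMA_MAX) -> MuscleSet:
    """The packaged 24-element reference muscle set (1.79 m skeleton)."""
    meta = load_table("muscles.csv")
    pts = load_table("muscle_points.csv")
    elements = []
    for _, row in meta.iterrows():
        sub = pts[pts["name"] == row["name"]].sort_values("idx")
        path = [(r["segment"], np.array([r["x"], r["y"], r["z"]]))
                for _, r in sub.iterrows()]
        elements.append(MuscleElement(
            name=row["name"], origin=path[0], insertion=path[-1],
            via_points=tuple(path[1:-1]), pcsa=float(row["pcsa_cm2"]),
            sigma_max=sigma_max, crosses=tuple(row["crosses"].split(";"))))
    return MuscleSet(tuple(elements))


def scale_geometry(muscles: MuscleSet, anthro: SubjectAnthro,
                   reference_height: float = REFERENCE_HEIGHT,
                   factors=None) -> MuscleSet:
    """Linearly scale attachment coordinates to the subject.

    By default a single uniform factor height/reference_height is applied to
    all three axes; ``factors`` overrides with per-axis values. PCSA is
    unchanged.
    """
    if factors is None:
        factors = np.full(3, anthro.height / reference_height)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError(f"scale factors must be positive, got {factors}")

    def _scale(point):
        seg, xyz = point
        return (seg, xyz * factors)

    out = []
    for e in muscles:
        out.append(replace(e, origin=_scale(e.origin), insertion=_scale(e.insertion),
                           via_points=tuple(_scale(p) for p in e.via_points)))
    return MuscleSet(tuple(out))


def double_pcsa(muscles: MuscleSet, targets) -> MuscleSet:
    """Return a set with the targets' PCSA (hence force bound) exactly x2.

    Multiplicative: applying twice yields x4. All other fields untouched.
    """
    targets = list(targets)
    unknown = sorted(set(targets) - set(muscles.names))
    if unknown:
        raise KeyError(f"unknown muscle names: {unknown}")
    out = tuple(replace(e, pcsa=2.0 * e.pcsa) if e.name in targets else e
                for e in muscles)
    return MuscleSet(out)


def load_reference_marker_clouds() -> dict:
    """Per-segment marker local coordinates of the reference skeleton."""
    df = load_table("markers.csv")
    clouds: dict = {}
    for _, row in df.iterrows():
        clouds.setdefault(row["segment"], {})[row["label"]] = np.array(
            [row["x"], row["y"], row["z"]])
    return clouds


@dataclass(frozen=True)
class ScaledModel:
    """Everything subject-specific the pipeline needs, built once per subject."""

    anthro: SubjectAnthro
    inertias: dict            # segment -> SegmentInertia
    muscles: MuscleSet
    segment_lengths: dict     # segment -> m
    joint_centres: dict       # joint -> (segment, local point)
    marker_clouds: dict       # segment -> {label: local point}

    def with_muscles(self, muscles: MuscleSet) -> "ScaledModel":
        return replace(self, muscles=muscles)


def build_model(anthro: SubjectAnthro,
                sigma_max: float = DEFAULT_SIGMA_MAX) -> ScaledModel:
    coeffs = load_table("de_leva.csv")
    inertias = {seg: scale_inertia(anthro, seg, coeffs) for seg in SEGMENTS}
    lengths = {seg: inertias[seg].length for seg in SEGMENTS}
    muscles = scale_geometry(load_reference_muscles(sigma_max), anthro)
    s = anthro.height / REFERENCE_HEIGHT
    joint_centres = {
        "ankle": ("shank", np.array([0.0, -lengths["shank"], 0.0])),
        "knee": ("thigh", np.array([0.0, -lengths["thigh"], 0.0])),
        "hip": ("pelvis", np.zeros(3)),
    }
    clouds = {
        seg: {lab: xyz * s for lab, xyz in cloud.items()}
        for seg, cloud in load_reference_marker_clouds().items()
    }
    return ScaledModel(anthro=anthro, inertias=inertias, muscles=muscles,
                       segment_lengths=lengths, joint_centres=joint_centres,
                       marker_clouds=clouds)
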