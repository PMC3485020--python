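"""Knee joint loads computed after the muscle forces are known.

Tibiofemoral contact closes the force balance of the shank at the knee;
patellofemoral contact follows a frictionless-pulley patella with packaged
flexion-dependent tendon-ratio and tendon-angle tables; anterior-posterior
shear is attributed to the cruciate ligaments (anterior -> ACL, posterior ->
PCL) with a flexion-dependent effectiveness factor. Ligaments carry no load
inside the equilibrium; recruitment only labels and scales the reported
resisted force.

Sign conventions (shank anatomical frame at the knee): local x anterior, y
along the tibial long axis, z lateral (right side). Reported AP shear is
negative anterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import load_table

__all__ = ["KneeLoadFrame", "tibiofemoral_contact", "patellofemoral_contact",
           "shear_decompose", "pf_tables", "ligament_tables"]

_PF = None
_LIG = None


def pf_tables():
    global _PF
    if _PF is None:
        df = load_table("patellofemoral.csv")
        _PF = (df["flexion_rad"].to_numpy(), df["tendon_ratio"].to_numpy(),
               np.deg2rad(df["included_deg"].to_numpy()))
    return _PF


def ligament_tables():
    global _LIG
    if _LIG is None:
        df = load_table("ligament_effectiveness.csv")
        _LIG = (df["flexion_rad"].to_numpy(), df["acl_factor"].to_numpy(),
                df["pcl_factor"].to_numpy())
    return _LIG


@dataclass
class KneeLoadFrame:
    """Knee loads at one solved frame."""

    tfj_contact: np.ndarray   # (3,) N, shank anatomical frame
    tfj_magnitude: float
    pfj_contact: float        # N
    patellar_tendon_force: float
    shear_ap: float           # N, anterior negative
    shear_ml: float           # N, lateral positive
    flexion_angle: float      # rad
    ligament: str             # "ACL" | "PCL" | "none"
    resisted: float           # N carried by the recruited ligament


def tibiofemoral_contact(knee_force_global, muscle_forces, knee_pull,
                         shank_rotation) -> np.ndarray:
    """Tibiofemoral contact force in the shank anatomical frame.

    The intersegmental knee force from inverse dynamics is the total action
    of the thigh side on the shank; subtracting the pulls of every
    knee-crossing muscle on the shank leaves the bone-on-bone contact:
    contact = F_knee - sum_j F_j u_j, rotated into the shank frame.

    knee_pull: (3, N) unit pulls on the shank for knee-crossing muscles
    (zero columns for the rest); muscle_forces: (N,) newtons.
    """
    f = np.asarray(knee_force_global, float) - \
        np.asarray(knee_pull, float) @ np.asarray(muscle_forces, float)
    return np.asarray(shank_rotation, float).T @ f


def patellofemoral_contact(quad_force: float, flexion: float):
    """(patellar tendon force, PF contact magnitude) from total quad force.

    The patella is a frictionless pulley: the patellar-tendon force is the
    quadriceps-tendon force times a flexion-dependent ratio rho, and the
    contact force is the magnitude of the vector sum of the two tendon pulls
    at the tabulated included angle (law of cosines). At full extension the
    pulls are nearly collinear and opposing, so contact tends to zero.
    """
    if quad_force < 0:
        raise ValueError("quadriceps force must be non-negative")
    grid, rho, theta = pf_tables()
    if not (grid[0] - 1e-9 <= flexion <= grid[-1] + 1e-9):
        raise ValueError(f"flexion {flexion:.3f} rad outside the table range "
                         f"[{grid[0]}, {grid[-1]}]")
    r = float(np.interp(flexion, grid, rho))
    ang = float(np.interp(flexion, grid, theta))
    pt = r * quad_force
    contact = float(np.sqrt(quad_force**2 + pt**2 +
                            2.0 * quad_force * pt * np.cos(ang)))
    return pt, contact


def shear_decompose(contact_local, flexion: float):
    """(shear_ap, shear_ml, ligament, resisted) from a shank-frame contact.

    shear_ap is the AP component with anterior negative; anterior shear is
    attributed to the ACL and posterior to the PCL, the resisted magnitude
    scaled by the flexion-dependent effectiveness factor.
    """
    c = np.asarray(contact_local, float)
    shear_ap = -float(c[0])          # local x is anterior; anterior reported negative
    shear_ml = float(c[2])
    grid, acl, pcl = ligament_tables()
    if shear_ap == 0.0:
        return shear_ap, shear_ml, "none", 0.0
    if shear_ap < 0.0:
        factor = float(np.interp(flexion, grid, acl))
        return shear_ap, shear_ml, "ACL", abs(shear_ap) * factor
    factor = float(np.interp(flexion, grid, pcl))
    return shear_ap, shear_ml, "PCL", abs(shear_ap) * factor


def knee_load_frame(knee_force_global, muscle_forces, knee_pull,
                    shank_rotation, quad_force: float,
                    flexion: float) -> KneeLoadFrame:
    """Assemble every knee-load quantity for one solved frame."""
    contact = tibiofemoral_contact(knee_force_global, muscle_forces,
                                   knee_pull, shank_rotation)
    pt, pfj = patellofemoral_contact(quad_force, np.clip(flexion, 0.0, 2.1))
    ap, ml, lig, resisted = shear_decompose(contact, flexion)
    return KneeLoadFrame(tfj_contact=contact,
                         tfj_magnitude=float(np.linalg.norm(contact)),
                         pfj_contact=pfj, patellar_tendon_force=pt,
                         shear_ap=ap, shear_ml=ml, flexion_angle=float(flexion),
                         ligament=lig, resisted=resisted)
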