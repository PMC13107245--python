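"""Geometry and metal-coordination analysis.

Distances, angles and torsions of the catalytic-site geometry, the
Gaussian-smoothed coordination number of the Mn centre, and the
screened effective charge of the metal ion.

The coordination count of a metal centre with ligand distances ``Ri`` is

    N_coord = sum_i exp(-(Ri - R0)^2 / (2 sigma^2))

with ideal bond length ``R0`` (2.08 Å for Mn–O) and spread ``sigma``
(0.05 Å): each ligand contributes 1 at the ideal length and decays as a
Gaussian as the bond stretches or compresses.

The effective charge of the metal centre is a screened Coulomb sum over
the partial charges ``Zi`` of the coordinating atoms,

    Q_eff = k_e * sum_i Zi * exp(-k * ri) / ri

with attenuation coefficient ``k`` (1.2 Å⁻¹) and the Coulomb constant
``k_e`` of the package unit system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .system import ToySystem
from .units import COULOMB

__all__ = [
    "CoordinationModel",
    "DegenerateGeometryError",
    "distance",
    "bond_angle",
    "dihedral",
    "coordination_number",
    "effective_charge",
]


class DegenerateGeometryError(ValueError):
    """Zero-length vector or collinear points where an angle is undefined."""


@dataclass
class CoordinationModel:
    """Metal-coordination parameters: centre atom, ligand atoms, R0, sigma, attenuation k."""

    center_index: int
    ligand_indices: list[int]
    ideal_length: float = 2.08   # Å, ideal Mn-O bond length
    spread: float = 0.05         # Å, bond-length spread
    attenuation: float = 1.2     # Å^-1, charge screening coefficient

    def __post_init__(self) -> None:
        if self.ideal_length <= 0:
            raise ValueError("ideal_length must be positive")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.attenuation < 0:
            raise ValueError("attenuation must be non-negative")


def distance(a, b) -> float:
    """Euclidean distance between two points, Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def bond_angle(v1_tail, apex, v2_tail) -> float:
    """Angle at ``apex`` between the directions to the two tail points, degrees in [0, 180]."""
    u = np.asarray(v1_tail, dtype=float) - np.asarray(apex, dtype=float)
    v = np.asarray(v2_tail, dtype=float) - np.asarray(apex, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length vector at angle apex")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4, degrees in (-180, 180], right-handed.

    0° is the planar cis arrangement, 180° planar trans.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(np.linalg.norm(b1) * nb2, 1e-30) or \
       np.linalg.norm(n2) < 1e-10 * max(np.linalg.norm(b3) * nb2, 1e-30):
        raise DegenerateGeometryError("three consecutive points are collinear")
    phi = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))
    # map -180 -> +180 to keep the half-open convention
    return 180.0 if phi <= -180.0 + 1e-12 else phi


def coordination_number(system: ToySystem, model: CoordinationModel) -> float:
    """Gaussian-smoothed ligand count around the metal centre (dimensionless)."""
    pos = system.positions
    center = pos[model.center_index]
    total = 0.0
    for idx in model.ligand_indices:
        ri = float(np.linalg.norm(pos[idx] - center))
        total += math.exp(-((ri - model.ideal_length) ** 2) / (2.0 * model.spread**2))
    return total


def effective_charge(system: ToySystem, model: CoordinationModel) -> float:
    """Screened effective charge of the metal centre from ligand partial charges."""
    pos = system.positions
    center = pos[model.center_index]
    total = 0.0
    for idx in model.ligand_indices:
        ri = float(np.linalg.norm(pos[idx] - center))
        if ri <= 0.0:
            raise DegenerateGeometryError(
                f"ligand {idx} coincides with the metal centre"
            )
        total += system.atoms[idx].charge * math.exp(-model.attenuation * ri) / ri
    return COULOMB * total
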