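"""Toy molecular-mechanics energetics and interaction-energy bookkeeping.

The force-field energy of a parameterized :class:`~mncat.system.ToySystem` is

    E_MM = sum_bonds Kb (r - r0)^2
         + sum_angles Ktheta (theta - theta0)^2
         + sum_dihedrals Kphi (1 + cos(n phi - delta))
         + sum_pairs (Aij / r^12 - Bij / r^6)   [+ Coulomb]

Harmonic terms carry **no** 1/2 factor (CHARMM convention); force constants
supplied to this module must not be double-counted.  Nonbonded pairs exclude
1-2 and 1-3 neighbours; 1-4 pairs interact at full strength (configurable).
Point-charge electrostatics over the same included pairs use Coulomb's law
with the package constant.

Alongside the force field the module books the continuum-solvation and
interaction-energy identities used by the catalysis analysis:

* Born solvation of a charge ``q`` in a spherical cavity of radius ``Rcav``
  inside a dielectric ``eps``: ``dG = -1/2 (1 - 1/eps) q^2 k_e / Rcav``
  (always stabilizing).
* Solvation decomposition ``G_solv = G_elec + G_cav + G_disp + G_rep``.
* Binding energy ``E_bind = E_complex - (E_enzyme + E_substrate)``.
* Synergy energy ``E_syn = E_EMS - E_ES - E_MS + E_S`` — the three-body
  stabilization of the enzyme–Mn–substrate complex beyond pairwise sums;
  exactly zero for any pairwise-additive energy model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .system import ToySystem
from .units import COULOMB

__all__ = [
    "BondParam",
    "AngleParam",
    "DihedralParam",
    "PairParam",
    "SolvationParameters",
    "ForceFieldParameters",
    "EnergyBreakdown",
    "ParameterizationError",
    "mm_total_energy",
    "mm_forces",
    "numerical_forces",
    "born_solvation",
    "solvation_decomposition",
    "binding_energy",
    "synergy_energy",
]


class ParameterizationError(KeyError):
    """A topology entry has no force-field parameters; message names the entry."""


@dataclass
class BondParam:
    k: float      # kcal/(mol Å^2)
    r0: float     # Å

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("bond force constant must be non-negative")


@dataclass
class AngleParam:
    k: float        # kcal/(mol rad^2)
    theta0: float   # rad

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("angle force constant must be non-negative")


@dataclass
class DihedralParam:
    k: float       # kcal/mol
    n: int         # multiplicity >= 1
    delta: float   # rad phase

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("dihedral multiplicity must be >= 1")


@dataclass
class PairParam:
    a: float   # kcal Å^12 / mol
    b: float   # kcal Å^6 / mol

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("Lennard-Jones A, B must be non-negative")

    @property
    def r_min(self) -> float:
        """Separation of the LJ minimum, (2A/B)^(1/6)."""
        return (2.0 * self.a / self.b) ** (1.0 / 6.0)

    @property
    def e_min(self) -> float:
        """LJ well depth at r_min: -B^2/(4A)."""
        return -self.b**2 / (4.0 * self.a)


@dataclass
class SolvationParameters:
    """Dielectric constant, cavity radius (Å) and solute charge (e) for Born solvation."""

    dielectric: float = 78.39   # water at 300 K
    cavity_radius: float = 2.0
    solute_charge: float = 0.0

    def __post_init__(self):
        if self.dielectric < 1:
            raise ValueError("dielectric constant must be >= 1")
        if self.cavity_radius <= 0:
            raise ValueError("cavity radius must be positive")


def _bond_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def _angle_key(i: int, j: int, k: int) -> tuple[int, int, int]:
    return (i, j, k) if i < k else (k, j, i)


def _dihedral_key(t: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    return t if t <= t[::-1] else t[::-1]


@dataclass
class ForceFieldParameters:
    """Per-entry force-field parameters.

    ``bonds``/``angles``/``dihedrals`` are keyed by (canonicalized) atom-index
    tuples; ``pairs`` by sorted element-symbol tuples, with ``("*", "*")`` as
    an optional default.  ``excluded_orders`` lists the bonded separations
    (in bonds) removed from the nonbonded sum; the default (1, 2) excludes
    1-2 and 1-3 pairs and keeps 1-4 at full strength.
    """

    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    dihedrals: dict = field(default_factory=dict)
    pairs: dict = field(default_factory=dict)
    include_electrostatics: bool = True
    excluded_orders: tuple[int, ...] = (1, 2)

    def bond(self, i: int, j: int) -> BondParam:
        try:
            return self.bonds[_bond_key(i, j)]
        except KeyError:
            raise ParameterizationError(f"no bond parameters for bond ({i}, {j})") from None

    def angle(self, i: int, j: int, k: int) -> AngleParam:
        try:
            return self.angles[_angle_key(i, j, k)]
        except KeyError:
            raise ParameterizationError(f"no angle parameters for angle ({i}, {j}, {k})") from None

    def dihedral(self, t: tuple[int, int, int, int]) -> DihedralParam:
        try:
            return self.dihedrals[_dihedral_key(tuple(t))]
        except KeyError:
            raise ParameterizationError(f"no dihedral parameters for dihedral {tuple(t)}") from None

    def pair(self, el_i: str, el_j: str) -> PairParam | None:
        key = tuple(sorted((el_i, el_j)))
        if key in self.pairs:
            return self.pairs[key]
        return self.pairs.get(("*", "*"))


@dataclass
class EnergyBreakdown:
    """Energy components in kcal/mol; ``total`` is always their sum."""

    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    lennard_jones: float = 0.0
    electrostatic: float = 0.0
    hydrogen_bond: float = 0.0
    van_der_waals: float = 0.0
    solvation: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.bond + self.angle + self.dihedral + self.lennard_jones
            + self.electrostatic + self.hydrogen_bond + self.van_der_waals
            + self.solvation
        )

    def as_dict(self) -> dict[str, float]:
        d = {
            "bond": self.bond, "angle": self.angle, "dihedral": self.dihedral,
            "lennard_jones": self.lennard_jones, "electrostatic": self.electrostatic,
            "hydrogen_bond": self.hydrogen_bond, "van_der_waals": self.van_der_waals,
            "solvation": self.solvation,
        }
        d["total"] = self.total
        return d


# ---------------------------------------------------------------------------
# Nonbonded exclusions
# ---------------------------------------------------------------------------

def _excluded_pairs(system: ToySystem, orders: tuple[int, ...]) -> set[tuple[int, int]]:
    """Pairs within the given bonded separations (1 = directly bonded, 2 = 1-3...)."""
    n = system.n_atoms
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in system.bonds:
        adj[i].add(j)
        adj[j].add(i)
    excluded: set[tuple[int, int]] = set()
    max_order = max(orders, default=0)
    for start in range(n):
        # BFS out to max_order bonds
        dist = {start: 0}
        frontier = [start]
        for d in range(1, max_order + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if v != start and d in orders:
                excluded.add(_bond_key(start, v))
    return excluded


def _nonbonded_pairs(system: ToySystem, params: ForceFieldParameters):
    excl = _excluded_pairs(system, params.excluded_orders)
    n = system.n_atoms
    return [(i, j) for i in range(n) for j in range(i + 1, n) if (i, j) not in excl]


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def mm_total_energy(system: ToySystem, params: ForceFieldParameters) -> EnergyBreakdown:
    """Force-field energy of the system, reported component by component."""
    pos = system.positions
    out = EnergyBreakdown()

    for i, j in system.bonds:
        p = params.bond(i, j)
        r = float(np.linalg.norm(pos[i] - pos[j]))
        out.bond += p.k * (r - p.r0) ** 2

    for i, j, k in system.angles:
        p = params.angle(i, j, k)
        theta = _angle_rad(pos[i], pos[j], pos[k])
        out.angle += p.k * (theta - p.theta0) ** 2

    for quad in system.dihedrals:
        p = params.dihedral(quad)
        phi = _dihedral_rad(*(pos[q] for q in quad))
        out.dihedral += p.k * (1.0 + math.cos(p.n * phi - p.delta))

    elements = system.elements
    charges = system.charges
    do_elec = params.include_electrostatics and np.any(charges != 0.0)
    for i, j in _nonbonded_pairs(system, params):
        r = float(np.linalg.norm(pos[i] - pos[j]))
        pp = params.pair(elements[i], elements[j])
        if pp is not None:
            out.lennard_jones += pp.a / r**12 - pp.b / r**6
        if do_elec:
            out.electrostatic += COULOMB * charges[i] * charges[j] / r
    return out


# ---------------------------------------------------------------------------
# Analytic forces
# ---------------------------------------------------------------------------

def _angle_rad(pi, pj, pk) -> float:
    u, v = pi - pj, pk - pj
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(min(1.0, max(-1.0, c)))


def _dihedral_rad(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    return math.atan2(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)), np.dot(n1, n2))


def mm_forces(system: ToySystem, params: ForceFieldParameters) -> np.ndarray:
    """Analytic forces -dE/dr, kcal/(mol·Å), shape (N, 3)."""
    pos = system.positions
    forces = np.zeros_like(pos)

    for i, j in system.bonds:
        p = params.bond(i, j)
        dij = pos[i] - pos[j]
        r = float(np.linalg.norm(dij))
        dEdr = 2.0 * p.k * (r - p.r0)
        f = -dEdr * dij / r
        forces[i] += f
        forces[j] -= f

    for i, j, k in system.angles:
        p = params.angle(i, j, k)
        u, v = pos[i] - pos[j], pos[k] - pos[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        uh, vh = u / nu, v / nv
        c = min(1.0, max(-1.0, float(np.dot(uh, vh))))
        s = math.sqrt(max(1.0 - c * c, 1e-14))
        theta = math.acos(c)
        dEdtheta = 2.0 * p.k * (theta - p.theta0)
        dthe_di = (c * uh - vh) / (nu * s)
        dthe_dk = (c * vh - uh) / (nv * s)
        forces[i] -= dEdtheta * dthe_di
        forces[k] -= dEdtheta * dthe_dk
        forces[j] += dEdtheta * (dthe_di + dthe_dk)

    for quad in system.dihedrals:
        p = params.dihedral(quad)
        i1, i2, i3, i4 = quad
        b1, b2, b3 = pos[i2] - pos[i1], pos[i3] - pos[i2], pos[i4] - pos[i3]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        nb2 = float(np.linalg.norm(b2))
        phi = math.atan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2))
        dEdphi = -p.k * p.n * math.sin(p.n * phi - p.delta)
        # torsion gradient: end-atom terms via the plane normals, interior
        # atoms from translation/rotation invariance (validated against
        # central differences in the test suite)
        dphi_d1 = -nb2 / float(np.dot(n1, n1)) * n1
        dphi_d4 = nb2 / float(np.dot(n2, n2)) * n2
        c12 = float(np.dot(b1, b2)) / nb2**2
        c32 = float(np.dot(b3, b2)) / nb2**2
        dphi_d2 = -(1.0 + c12) * dphi_d1 + c32 * dphi_d4
        dphi_d3 = c12 * dphi_d1 - (1.0 + c32) * dphi_d4
        forces[i1] -= dEdphi * dphi_d1
        forces[i2] -= dEdphi * dphi_d2
        forces[i3] -= dEdphi * dphi_d3
        forces[i4] -= dEdphi * dphi_d4

    elements = system.elements
    charges = system.charges
    do_elec = params.include_electrostatics and np.any(charges != 0.0)
    for i, j in _nonbonded_pairs(system, params):
        dij = pos[i] - pos[j]
        r = float(np.linalg.norm(dij))
        dEdr = 0.0
        pp = params.pair(elements[i], elements[j])
        if pp is not None:
            dEdr += -12.0 * pp.a / r**13 + 6.0 * pp.b / r**7
        if do_elec:
            dEdr += -COULOMB * charges[i] * charges[j] / r**2
        f = -dEdr * dij / r
        forces[i] += f
        forces[j] -= f
    return forces


def numerical_forces(
    system: ToySystem, params: ForceFieldParameters, h: float = 1e-5
) -> np.ndarray:
    """Central-finite-difference forces; the independent fallback/oracle for mm_forces."""
    work = system.copy()
    base = work.positions
    forces = np.zeros_like(base)
    for i in range(work.n_atoms):
        for d in range(3):
            for sign in (+1.0, -1.0):
                coords = base.copy()
                coords[i, d] += sign * h
                work.positions = coords
                e = mm_total_energy(work, params).total
                forces[i, d] -= sign * e / (2.0 * h)
    return forces


# ---------------------------------------------------------------------------
# Solvation and interaction-energy bookkeeping
# ---------------------------------------------------------------------------

def born_solvation(params: SolvationParameters) -> float:
    """Born continuum solvation free energy, kcal/mol (<= 0, stabilizing)."""
    eps = params.dielectric
    return (
        -0.5 * (1.0 - 1.0 / eps) * params.solute_charge**2 * COULOMB
        / params.cavity_radius
    )


def solvation_decomposition(
    elec: float, cav: float, disp: float, rep: float
) -> EnergyBreakdown:
    """Book the four continuum-solvation components; total goes to ``solvation``."""
    for v in (elec, cav, disp, rep):
        if not math.isfinite(v):
            raise ValueError("solvation components must be finite")
    out = EnergyBreakdown(solvation=elec + cav + disp + rep)
    out.solvation_components = {  # type: ignore[attr-defined]
        "electrostatic": elec, "cavity": cav, "dispersion": disp, "repulsion": rep,
    }
    return out


def binding_energy(e_complex: float, e_enzyme: float, e_substrate: float) -> float:
    """Substrate–catalyst binding energy: E_complex - (E_enzyme + E_substrate)."""
    return e_complex - (e_enzyme + e_substrate)


def synergy_energy(e_ems: float, e_es: float, e_ms: float, e_s: float) -> float:
    """Three-body synergy of the enzyme–Mn–substrate complex.

    ``E(enzyme-Mn-substrate) - E(enzyme-substrate) - E(Mn-substrate) + E(substrate)``;
    negative values mean synergistic stabilization.  Identically zero when the
    underlying energies are pairwise additive.
    """
    return e_ems - e_es - e_ms + e_s
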