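"""YAML configuration for topology, coordination and force-field parameters.

One structured text file can carry three sections:

``topology``
    ``bonds`` / ``angles`` / ``dihedrals`` as lists of 0-based index tuples,
    applied to a system read from XYZ/PDB (which carry no topology).
``coordination``
    ``center``, ``ligands``, ``R0`` (Å), ``sigma`` (Å), ``k`` (Å⁻¹).
``forcefield``
    ``bonds``: [{atoms, k, r0}], ``angles``: [{atoms, k, theta0_deg}],
    ``dihedrals``: [{atoms, k, n, delta_deg}], ``pairs``: [{elements, a, b}]
    (elements ``["*", "*"]`` is the default pair), ``exclusions`` (bonded
    orders removed from the nonbonded sum) and ``electrostatics`` (bool).
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .energetics import (
    AngleParam, BondParam, DihedralParam, ForceFieldParameters, PairParam,
    _angle_key, _bond_key, _dihedral_key,
)
from .geometry import CoordinationModel
from .system import ToySystem

__all__ = ["load_config", "apply_topology", "coordination_from_config",
           "forcefield_from_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def apply_topology(system: ToySystem, config: dict) -> ToySystem:
    """Attach the ``topology`` section's bonds/angles/dihedrals to a system."""
    topo = config.get("topology", {})
    system.bonds = [tuple(b) for b in topo.get("bonds", [])]
    system.angles = [tuple(a) for a in topo.get("angles", [])]
    system.dihedrals = [tuple(d) for d in topo.get("dihedrals", [])]
    system.validate()
    return system


def coordination_from_config(config: dict) -> CoordinationModel:
    c = config["coordination"]
    return CoordinationModel(
        center_index=int(c["center"]),
        ligand_indices=[int(i) for i in c["ligands"]],
        ideal_length=float(c.get("R0", 2.08)),
        spread=float(c.get("sigma", 0.05)),
        attenuation=float(c.get("k", 1.2)),
    )


def forcefield_from_config(config: dict) -> ForceFieldParameters:
    ff = config.get("forcefield", {})
    params = ForceFieldParameters(
        include_electrostatics=bool(ff.get("electrostatics", True)),
        excluded_orders=tuple(ff.get("exclusions", (1, 2))),
    )
    for entry in ff.get("bonds", []):
        i, j = entry["atoms"]
        params.bonds[_bond_key(i, j)] = BondParam(float(entry["k"]), float(entry["r0"]))
    for entry in ff.get("angles", []):
        i, j, k = entry["atoms"]
        params.angles[_angle_key(i, j, k)] = AngleParam(
            float(entry["k"]), math.radians(float(entry["theta0_deg"]))
        )
    for entry in ff.get("dihedrals", []):
        params.dihedrals[_dihedral_key(tuple(entry["atoms"]))] = DihedralParam(
            float(entry["k"]), int(entry["n"]),
            math.radians(float(entry.get("delta_deg", 0.0))),
        )
    for entry in ff.get("pairs", []):
        key = tuple(sorted(entry["elements"]))
        params.pairs[key] = PairParam(float(entry["a"]), float(entry["b"]))
    return params
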