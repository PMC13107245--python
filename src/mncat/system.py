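"""Molecular system container and coordinate file I/O.

A :class:`ToySystem` is the universal input object of the package: an ordered
list of atoms (element, position, mass, partial charge) plus bonded topology
(bonds, angles, dihedrals) and an optional cubic box.  Coordinates are in Å,
masses in amu, charges in elementary charges; indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "ToySystem",
    "element_mass",
    "read_xyz",
    "write_xyz",
    "write_xyz_frames",
    "read_pdb_coords",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed coordinate file; message names the offending line."""


# Standard atomic weights (amu) for the elements a toy catalytic model uses.
_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546,
    "Zn": 65.38, "Br": 79.904, "I": 126.904, "Se": 78.971,
}


def element_mass(element: str) -> float:
    """Atomic mass in amu from the built-in element table.

    Raises ``KeyError`` for unknown symbols rather than defaulting silently.
    """
    try:
        return _MASSES[element.capitalize() if len(element) > 1 else element.upper()]
    except KeyError:
        raise KeyError(f"unknown element symbol {element!r}") from None


@dataclass
class AtomSite:
    """One atom: element symbol, Cartesian position (Å), mass (amu), partial charge (e)."""

    element: str
    position: np.ndarray
    mass: float = 0.0
    charge: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a Cartesian triple")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.mass == 0.0:
            self.mass = element_mass(self.element)
        if self.mass <= 0:
            raise ValueError("mass must be positive")


@dataclass
class ToySystem:
    """Atoms plus bonded topology; the enzyme–metal–substrate model object.

    ``bonds`` are index pairs, ``angles`` index triples (apex in the middle),
    ``dihedrals`` index quadruples.  ``box_length`` is the cubic box edge in Å,
    or ``None`` for a non-periodic system.
    """

    atoms: list[AtomSite] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    box_length: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        for tup in (*self.bonds, *self.angles, *self.dihedrals):
            if any(i < 0 or i >= n for i in tup):
                raise ValueError(f"topology entry {tup} out of range for {n} atoms")
            if len(set(tup)) != len(tup):
                raise ValueError(f"topology entry {tup} repeats an atom index")
        seen = set()
        for i, j in self.bonds:
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    # -- array views ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @positions.setter
    def positions(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def copy(self) -> "ToySystem":
        return ToySystem(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            angles=list(self.angles),
            dihedrals=list(self.dihedrals),
            box_length=self.box_length,
        )


# ---------------------------------------------------------------------------
# XYZ format
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> ToySystem:
    """Read a standard XYZ file (count line, comment line, element x y z records)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file, expected an atom-count line")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: malformed atom count {lines[0]!r}") from None
    atoms: list[AtomSite] = []
    for k in range(count):
        lineno = k + 3
        try:
            fields = lines[k + 2].split()
        except IndexError:
            raise ParseError(f"{path}: line {lineno}: expected {count} atom records") from None
        if len(fields) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 'element x y z'")
        try:
            xyz = [float(v) for v in fields[1:4]]
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric coordinate") from None
        atoms.append(AtomSite(element=fields[0], position=np.array(xyz)))
    return ToySystem(atoms=atoms)


def write_xyz(system: ToySystem, path: str | Path, comment: str = "") -> None:
    """Write a standard XYZ file with 6-decimal coordinates."""
    with open(path, "w") as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for atom in system.atoms:
            x, y, z = atom.position
            fh.write(f"{atom.element:<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def write_xyz_frames(
    elements: Sequence[str], frames: Iterable[np.ndarray], path: str | Path
) -> None:
    """Write a multi-frame (trajectory) XYZ file."""
    with open(path, "w") as fh:
        for k, coords in enumerate(frames):
            fh.write(f"{len(elements)}\nframe {k}\n")
            for el, (x, y, z) in zip(elements, coords):
                fh.write(f"{el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# ---------------------------------------------------------------------------
# Minimal PDB coordinate reading (ATOM/HETATM records only, via gemmi)
# ---------------------------------------------------------------------------

def read_pdb_coords(path: str | Path) -> ToySystem:
    """Read only elements and coordinates from ATOM/HETATM records of a PDB file.

    Element symbols come from the element column when present, otherwise they
    are inferred from the atom-name field.  All other record types are ignored.
    An input with no coordinate records yields an empty system (with a warning),
    not an error.
    """
    structure = gemmi.read_pdb(str(path))
    atoms: list[AtomSite] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    el = atom.element.name
                    if el in ("X", ""):  # element truly unknown
                        el = atom.name.strip()[0]
                    atoms.append(
                        AtomSite(
                            element=el,
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            label=f"{residue.name}{residue.seqid.num}:{atom.name}",
                        )
                    )
        break  # first model only
    if not atoms:
        import warnings

        warnings.warn(f"{path}: no ATOM/HETATM records found; returning empty system")
    return ToySystem(atoms=atoms)
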