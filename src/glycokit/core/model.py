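"""Lightweight molecular data model shared by every other module.

A :class:`MolecularModel` is an ordered list of :class:`AtomRecord` plus an
explicit bond list (atom-index pairs, each stored once).  Coordinates are in
Ångström everywhere inside the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class AtomRecord:
    """One atom of a PDB-style structure.

    ``b_factor`` may carry a pLDDT confidence for predicted models; the
    package never interprets it, only preserves it.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    coordinates: np.ndarray
    insertion_code: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,):
            raise ValueError("coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom serial {self.serial}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the atom within one model: (chain, resnum, icode, name)."""
        return (self.chain, self.residue_number, self.insertion_code, self.name)

    def copy(self) -> "AtomRecord":
        return replace(self, coordinates=self.coordinates.copy())


@dataclass
class MolecularModel:
    """An ordered atom list with bonds (each unordered pair stored once)."""

    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) float array of atom positions, Å. A copy; use set_coordinates."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        for atom, xyz in zip(self.atoms, coords):
            atom.coordinates = xyz.copy()

    def copy(self) -> "MolecularModel":
        return MolecularModel(
            atoms=[a.copy() for a in self.atoms],
            bonds=list(self.bonds),
            model_id=self.model_id,
        )

    # ---- lookup helpers -------------------------------------------------
    def atom_index(
        self,
        name: str,
        residue_number: int | None = None,
        chain: str | None = None,
        insertion_code: str | None = None,
    ) -> int:
        """Index of the first atom matching the given fields.

        Raises ``KeyError`` naming the atom if nothing matches.
        """
        for i, a in enumerate(self.atoms):
            if a.name != name:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if chain is not None and a.chain != chain:
                continue
            if insertion_code is not None and a.insertion_code != insertion_code:
                continue
            return i
        where = f" in residue {chain or '?'}:{residue_number}" if residue_number else ""
        raise KeyError(f"atom {name!r} not found{where}")

    def residue_atoms(
        self, chain: str, residue_number: int, insertion_code: str = ""
    ) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain == chain
            and a.residue_number == residue_number
            and a.insertion_code == insertion_code
        ]

    def residues(self) -> list[tuple[str, int, str, str]]:
        """Residues in file order as (chain, residue_number, icode, residue_name)."""
        seen: list[tuple[str, int, str, str]] = []
        last = None
        for a in self.atoms:
            key = (a.chain, a.residue_number, a.insertion_code, a.residue_name)
            if key != last:
                seen.append(key)
                last = key
        return seen

    def strip_hydrogens(self) -> "MolecularModel":
        """New model without H/D atoms; bonds re-indexed."""
        keep = [i for i, a in enumerate(self.atoms) if a.element not in ("H", "D")]
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [self.atoms[i].copy() for i in keep]
        bonds = [
            (remap[i], remap[j])
            for i, j in self.bonds
            if i in remap and j in remap
        ]
        return MolecularModel(atoms=atoms, bonds=bonds, model_id=self.model_id)

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("cannot bond an atom to itself")
        if not (0 <= i < len(self.atoms) and 0 <= j < len(self.atoms)):
            raise IndexError(f"bond ({i}, {j}) out of range")
        pair = (min(i, j), max(i, j))
        if pair not in self.bonds:
            self.bonds.append(pair)


def merge_models(
    a: MolecularModel, b: MolecularModel, extra_bonds: list[tuple[int, int]] = ()
) -> MolecularModel:
    """Concatenate two models; ``extra_bonds`` index (a_atom, b_atom) pairs."""
    offset = len(a.atoms)
    merged = MolecularModel(
        atoms=[at.copy() for at in a.atoms] + [at.copy() for at in b.atoms],
        bonds=list(a.bonds) + [(i + offset, j + offset) for i, j in b.bonds],
        model_id=a.model_id,
    )
    for i, j in extra_bonds:
        merged.add_bond(i, j + offset)
    return merged
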