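"""Linkage geometry configuration: which atoms define the protein-glycan
phi/psi torsions for each glycosylation chemistry, and over what ranges the
optimizer may search.

The shipped table (``glycokit/data/linkage_table.yaml``) is a convention
layer, not a result: edit it or pass an alternative file to override any
entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

SUPPORTED_GLYCO_TYPES = frozenset(
    {"N-GlcNAc", "O-GalNAc", "O-GlcNAc", "O-Fuc", "O-Man", "O-Glc", "O-Xyl", "C-Man"}
)


@dataclass(frozen=True)
class TorsionRange:
    """Degree interval in (-180, 180]; ``lo > hi`` wraps through 180."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        for v in (self.lo, self.hi):
            if not (-180.0 <= v <= 180.0):
                raise ValueError(f"range endpoint {v} outside [-180, 180]")

    @property
    def wraps(self) -> bool:
        return self.lo > self.hi

    @property
    def width(self) -> float:
        return (self.hi - self.lo) % 360.0 if self.wraps else self.hi - self.lo

    @property
    def midpoint(self) -> float:
        mid = self.lo + self.width / 2.0
        return wrap_angle(mid)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        u = rng.uniform(0.0, self.width, size=size)
        return wrap_angle(self.lo + u)

    def contains(self, angle: float, tol: float = 1e-9) -> bool:
        a = wrap_angle(angle)
        if self.wraps:
            return a >= self.lo - tol or a <= self.hi + tol
        return self.lo - tol <= a <= self.hi + tol


def wrap_angle(angle):
    """Map degrees onto (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class LinkageSpec:
    """Geometry of one glycosylation chemistry.

    ``phi`` is the dihedral over atoms a-b-c-d and ``psi`` over b-c-d-e,
    where a (glycan ring oxygen) and b (anomeric carbon) belong to the
    glycan, and c, d, e are sidechain atoms of the acceptor residue.
    """

    glyco_type: str
    glycan_a: str
    glycan_b: str
    protein_atoms: dict[str, dict[str, str]]  # residue_name -> {c, d, e}
    phi_range: TorsionRange
    psi_range: TorsionRange
    bond_length: float  # b-c, Å
    bond_angle: float  # b-c-d, degrees

    def __post_init__(self) -> None:
        if self.glyco_type not in SUPPORTED_GLYCO_TYPES:
            raise ValueError(
                f"unsupported glycosylation type {self.glyco_type!r}; "
                f"supported: {sorted(SUPPORTED_GLYCO_TYPES)}"
            )

    def sidechain_atoms(self, residue_name: str) -> dict[str, str]:
        try:
            return self.protein_atoms[residue_name]
        except KeyError:
            raise KeyError(
                f"{self.glyco_type} linkage has no atom mapping for residue "
                f"{residue_name!r} (acceptors: {sorted(self.protein_atoms)})"
            ) from None

    def phi_atom_names(self, residue_name: str) -> tuple[str, str, str, str]:
        pa = self.sidechain_atoms(residue_name)
        return (self.glycan_a, self.glycan_b, pa["c"], pa["d"])

    def psi_atom_names(self, residue_name: str) -> tuple[str, str, str, str]:
        pa = self.sidechain_atoms(residue_name)
        return (self.glycan_b, pa["c"], pa["d"], pa["e"])


def load_linkage_table(path: str | Path | None = None) -> dict[str, LinkageSpec]:
    """Load the linkage table; ``path=None`` loads the packaged defaults."""
    if path is None:
        source = resources.files("glycokit").joinpath("data/linkage_table.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    table: dict[str, LinkageSpec] = {}
    for glyco_type, entry in raw.items():
        table[glyco_type] = LinkageSpec(
            glyco_type=glyco_type,
            glycan_a=entry["glycan_atoms"]["a"],
            glycan_b=entry["glycan_atoms"]["b"],
            protein_atoms={k: dict(v) for k, v in entry["protein_atoms"].items()},
            phi_range=TorsionRange(*entry["phi_range"]),
            psi_range=TorsionRange(*entry["psi_range"]),
            bond_length=float(entry["bond_length"]),
            bond_angle=float(entry["bond_angle"]),
        )
    return table
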