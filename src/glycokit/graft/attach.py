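"""Placing a glycan's reducing end onto a protein sidechain and steering
the two linkage torsions.

A :class:`GraftPose` couples a fixed protein with a mobile glycan copy.
The glycan is positioned so that its anomeric carbon (atom *b* of the
linkage) sits at the configured bond length and angle from the sidechain
attachment atom (*c*), and the linkage dihedrals

    phi = a-b-c-d        psi = b-c-d-e

can then be set exactly by rigid rotation of the whole glycan about the
b-c and c-d axes respectively (protein atoms never move).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from glycokit.core.geometry import (
    dihedral_from_points,
    place_atom,
    rotate_subset,
)
from glycokit.core.graph import build_graph, perceive_bonds
from glycokit.core.linkage import LinkageSpec, wrap_angle
from glycokit.core.model import MolecularModel, merge_models
from glycokit.graft.fitness import CLASH_THRESHOLD, steric_fitness
from glycokit.graft.torsions import TorsionQuartet, detect_torsion_pairs

ANOMERIC_ANGLE = 109.5  # a-b-c angle at the anomeric carbon, degrees


class AttachmentError(ValueError):
    """A linkage atom could not be resolved at the requested site."""


@dataclass(frozen=True)
class SiteRef:
    """A residue reference in author numbering."""

    chain: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.residue_number}{self.insertion_code}"


def parse_site(text: str | SiteRef) -> SiteRef:
    """Parse ``"A:45"`` / ``"A:N45"`` / ``"A:45A"`` into a SiteRef."""
    if isinstance(text, SiteRef):
        return text
    chain, _, rest = text.partition(":")
    if not rest:
        raise ValueError(f"cannot parse site reference {text!r} (expected CHAIN:NUM)")
    rest = rest.strip()
    if rest and rest[0].isalpha():  # optional residue-type letter, e.g. N45
        rest = rest[1:]
    icode = ""
    if rest and rest[-1].isalpha():
        icode = rest[-1]
        rest = rest[:-1]
    return SiteRef(chain=chain.strip(), residue_number=int(rest), insertion_code=icode)


@dataclass
class GraftPose:
    """A glycan positioned in the protein frame, with its linkage handles."""

    protein: MolecularModel
    glycan: MolecularModel
    linkage: LinkageSpec
    site: SiteRef
    a_g: int  # glycan ring oxygen index (atom a)
    b_g: int  # glycan anomeric carbon index (atom b)
    c_p: int  # protein attachment atom index (atom c)
    d_p: int
    e_p: int
    cluster_id: int = -1
    exclusions: frozenset[int] = field(default_factory=frozenset)
    _quartets: list[TorsionQuartet] | None = field(default=None, repr=False)

    # ---- geometry ------------------------------------------------------
    def _points(self) -> tuple[np.ndarray, ...]:
        return (
            self.glycan.atoms[self.a_g].coordinates,
            self.glycan.atoms[self.b_g].coordinates,
            self.protein.atoms[self.c_p].coordinates,
            self.protein.atoms[self.d_p].coordinates,
            self.protein.atoms[self.e_p].coordinates,
        )

    @property
    def phi(self) -> float:
        a, b, c, d, _ = self._points()
        return dihedral_from_points(a, b, c, d)

    @property
    def psi(self) -> float:
        _, b, c, d, e = self._points()
        return dihedral_from_points(b, c, d, e)

    def set_torsions(self, phi: float | None = None, psi: float | None = None) -> "GraftPose":
        """Rotate the whole glycan so the linkage dihedrals take the
        requested values exactly; glycan-internal geometry is untouched."""
        all_glycan = list(range(len(self.glycan.atoms)))
        if phi is not None:
            a, b, c, d, _ = self._points()
            delta = wrap_angle(self.phi - phi)
            rotate_subset(self.glycan, all_glycan, b, c - b, delta)
        if psi is not None:
            _, b, c, d, e = self._points()
            delta = wrap_angle(self.psi - psi)
            rotate_subset(self.glycan, all_glycan, c, d - c, delta)
        return self

    def internal_quartets(self) -> list[TorsionQuartet]:
        """Rotatable torsions inside the glycan (cached)."""
        if self._quartets is None:
            graph = build_graph(self.glycan)
            self._quartets = detect_torsion_pairs(graph)
        return self._quartets

    def rotate_internal(self, quartet: TorsionQuartet, delta: float) -> None:
        """Rotate a glycan-internal torsion by ``delta`` degrees, keeping the
        side that carries the anomeric anchor fixed."""
        j, k = quartet.atoms[1], quartet.atoms[2]
        moving = set(quartet.rotating_set)
        if self.b_g in moving:
            moving = set(range(len(self.glycan.atoms))) - moving
            j, k = k, j  # flip axis so the handedness of delta is preserved
        pj = self.glycan.atoms[j].coordinates
        pk = self.glycan.atoms[k].coordinates
        rotate_subset(self.glycan, sorted(moving), pj, pk - pj, delta)

    # ---- scoring -------------------------------------------------------
    def fitness(
        self,
        protein_coords: np.ndarray | None = None,
        protein_tree: cKDTree | None = None,
        threshold: float = CLASH_THRESHOLD,
    ) -> tuple[float, list[tuple[int, int, float]]]:
        """Steric loss of the current pose (0 means clash-free)."""
        if protein_coords is None:
            protein_coords = self.protein.coordinates
        return steric_fitness(
            protein_coords,
            self.glycan.coordinates,
            threshold=threshold,
            exclusions=self.exclusions,
            protein_tree=protein_tree,
        )

    def copy(self) -> "GraftPose":
        return GraftPose(
            protein=self.protein,
            glycan=self.glycan.copy(),
            linkage=self.linkage,
            site=self.site,
            a_g=self.a_g,
            b_g=self.b_g,
            c_p=self.c_p,
            d_p=self.d_p,
            e_p=self.e_p,
            cluster_id=self.cluster_id,
            exclusions=self.exclusions,
            _quartets=self._quartets,
        )

    def complex_model(self) -> MolecularModel:
        """Protein + glycan merged, with the linkage emitted as a bond."""
        return merge_models(self.protein, self.glycan,
                            extra_bonds=[(self.c_p, self.b_g)])


def attach_reducing_end(
    protein: MolecularModel,
    site: SiteRef | str,
    glycan: MolecularModel,
    linkage: LinkageSpec,
    cluster_id: int = -1,
) -> GraftPose:
    """Bond a glycan conformer to a protein sidechain.

    The anomeric carbon is placed at the configured bond length/angle from
    the sidechain attachment atom, the anomeric configuration of the input
    conformer is preserved (the glycan moves rigidly), and the linkage
    torsions start at their range midpoints.  An anomeric hydroxyl (O1 and
    its hydrogen), if present, is removed: the linkage replaces it.
    """
    site = parse_site(site)
    res_atoms = protein.residue_atoms(site.chain, site.residue_number,
                                      site.insertion_code)
    if not res_atoms:
        raise AttachmentError(f"site {site}: no residue found")
    residue_name = protein.atoms[res_atoms[0]].residue_name
    names = linkage.sidechain_atoms(residue_name)
    indices = {}
    for role in ("c", "d", "e"):
        wanted = names[role]
        match = [i for i in res_atoms if protein.atoms[i].name == wanted]
        if not match:
            raise AttachmentError(
                f"site {site} ({residue_name}): sidechain atom {wanted!r} is "
                "missing; check the residue's rotamer or use the amide swap "
                "tool if an Asn OD1/ND2 assignment is suspect"
            )
        indices[role] = match[0]

    glycan = glycan.copy()
    glycan = _strip_anomeric_hydroxyl(glycan, linkage.glycan_b)
    if not glycan.bonds:
        glycan.bonds = perceive_bonds(glycan)
    try:
        a_g = glycan.atom_index(linkage.glycan_a)
        b_g = glycan.atom_index(linkage.glycan_b)
    except KeyError as exc:
        raise AttachmentError(f"glycan lacks a linkage atom: {exc}") from exc

    c = protein.atoms[indices["c"]].coordinates
    d = protein.atoms[indices["d"]].coordinates
    e = protein.atoms[indices["e"]].coordinates
    phi0 = linkage.phi_range.midpoint
    psi0 = linkage.psi_range.midpoint
    # psi = b-c-d-e == e-d-c-b, so b is built off (e, d, c)
    target_b = place_atom(e, d, c, linkage.bond_length, linkage.bond_angle, psi0)
    ab_length = float(
        np.linalg.norm(glycan.atoms[a_g].coordinates - glycan.atoms[b_g].coordinates)
    )
    # phi = a-b-c-d == d-c-b-a, so a is built off (d, c, target_b)
    target_a = place_atom(d, c, target_b, ab_length, ANOMERIC_ANGLE, phi0)

    _rigid_two_point_align(glycan, b_g, a_g, target_b, target_a)
    pose = GraftPose(
        protein=protein,
        glycan=glycan,
        linkage=linkage,
        site=site,
        a_g=a_g,
        b_g=b_g,
        c_p=indices["c"],
        d_p=indices["d"],
        e_p=indices["e"],
        cluster_id=cluster_id,
        exclusions=frozenset({b_g}),
    )
    pose.set_torsions(phi=phi0, psi=psi0)
    return pose


def _strip_anomeric_hydroxyl(glycan: MolecularModel, anomeric_name: str) -> MolecularModel:
    drop = {i for i, a in enumerate(glycan.atoms) if a.name in ("O1", "HO1", "H1O")}
    if not drop:
        return glycan
    keep = [i for i in range(len(glycan.atoms)) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    return MolecularModel(
        atoms=[glycan.atoms[i] for i in keep],
        bonds=[(remap[i], remap[j]) for i, j in glycan.bonds
               if i in remap and j in remap],
        model_id=glycan.model_id,
    )


def _rigid_two_point_align(
    model: MolecularModel, b: int, a: int,
    target_b: np.ndarray, target_a: np.ndarray,
) -> None:
    """Move the model rigidly so atom b lands on target_b and atom a lies
    along the target_b -> target_a direction (roll about that axis is left
    as-is; the linkage torsions fix the remaining orientation)."""
    coords = model.coordinates
    coords = coords - coords[b] + target_b
    v1 = coords[a] - target_b
    v2 = np.asarray(target_a, float) - target_b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 > 1e-12 and n2 > 1e-12:
        u1, u2 = v1 / n1, v2 / n2
        axis = np.cross(u1, u2)
        s = np.linalg.norm(axis)
        cth = float(np.clip(np.dot(u1, u2), -1.0, 1.0))
        if s > 1e-12:
            angle = np.degrees(np.arctan2(s, cth))
            from glycokit.core.geometry import rotation_about_axis

            coords = rotation_about_axis(target_b, axis, angle)(coords)
        elif cth < 0:  # anti-parallel: rotate 180 deg about any perpendicular
            perp = np.cross(u1, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(u1, [0.0, 1.0, 0.0])
            from glycokit.core.geometry import rotation_about_axis

            coords = rotation_about_axis(target_b, perp, 180.0)(coords)
    model.set_coordinates(coords)
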