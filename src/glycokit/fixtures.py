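"""Deterministic synthetic-input generators.

Everything the other modules consume — glycan conformer trajectories with
planted cluster structure, pocket proteins with an analytically known
clearance, extended-chain sequon proteins — is generated here as a pure
function of its parameters and seed.  Geometry is idealized (no force
field): rings are regular, substituents are placed by internal
coordinates, and pocket walls are rigid carbon pseudo-atom shells, which
keeps steric feasibility exactly computable from the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from glycokit.core.geometry import place_atom, set_dihedral
from glycokit.core.graph import build_graph
from glycokit.core.model import AtomRecord, MolecularModel
from glycokit.conformers.ensemble import ConformationEnsemble

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class FixtureSpec:
    """Declarative fixture request (CLI surface for the generators)."""

    kind: str  # planted_ensemble | pocket_protein | toy_glycan | sequon_protein
    parameters: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# toy glycan
# ---------------------------------------------------------------------------

def make_toy_glycan() -> MolecularModel:
    """An idealized GlcNAc-like monosaccharide (synthetic geometry).

    A planar six-membered pyranose-like ring (C1, C2, C3, C4, C5, O5) with
    an N-acetyl arm on C2 (N2-C7(=O7)-C8), hydroxyls on C3/C4, and the
    exocyclic C6-O6 arm on C5.  The topology supports >= 3 rotatable
    torsion quartets and provides the O5/C1 linkage atoms a grafting
    linkage expects.  Deterministic; heavy atoms only.
    """
    ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    coords: dict[str, np.ndarray] = {}
    for i, name in enumerate(ring_names):
        angle = np.radians(60.0 * i)
        coords[name] = np.array([1.5 * np.cos(angle), 1.5 * np.sin(angle), 0.0])
    coords["N2"] = place_atom(coords["O5"], coords["C1"], coords["C2"], 1.45, 112.0, 120.0)
    coords["C7"] = place_atom(coords["C1"], coords["C2"], coords["N2"], 1.35, 120.0, 180.0)
    coords["O7"] = place_atom(coords["C2"], coords["N2"], coords["C7"], 1.23, 121.0, 10.0)
    coords["C8"] = place_atom(coords["C2"], coords["N2"], coords["C7"], 1.50, 116.0, -170.0)
    coords["O3"] = place_atom(coords["C1"], coords["C2"], coords["C3"], 1.43, 110.0, -120.0)
    coords["O4"] = place_atom(coords["C2"], coords["C3"], coords["C4"], 1.43, 110.0, 120.0)
    coords["C6"] = place_atom(coords["C3"], coords["C4"], coords["C5"], 1.52, 112.0, 120.0)
    coords["O6"] = place_atom(coords["C4"], coords["C5"], coords["C6"], 1.43, 110.0, 60.0)
    order = ring_names + ["N2", "C7", "O7", "C8", "O3", "O4", "C6", "O6"]
    atoms = [
        AtomRecord(
            serial=i + 1, name=name, element=name[0], residue_name="NAG",
            residue_number=1, chain="X", coordinates=coords[name], het=True,
        )
        for i, name in enumerate(order)
    ]
    idx = {name: i for i, name in enumerate(order)}
    bonds = [(idx[a], idx[b]) for a, b in [
        ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
        ("C5", "O5"), ("O5", "C1"),
        ("C2", "N2"), ("N2", "C7"), ("C7", "O7"), ("C7", "C8"),
        ("C3", "O3"), ("C4", "O4"), ("C5", "C6"), ("C6", "O6"),
    ]]
    return MolecularModel(atoms=atoms, bonds=sorted(tuple(sorted(b)) for b in bonds))


def reference_glcnac() -> MolecularModel:
    """The single-GlcNAc probe used by occupancy scanning (idealized)."""
    return make_toy_glycan()


# torsions varied by the planted-ensemble generator, as atom-name quartets
PLANTED_TORSIONS = [
    ("C1", "C2", "N2", "C7"),   # sidechain rotation about C2-N2
    ("C2", "N2", "C7", "C8"),   # amide rotation about N2-C7
    ("C4", "C5", "C6", "O6"),   # exocyclic omega-like arm
]


def make_planted_ensemble(
    k: int = 3,
    centers: np.ndarray | None = None,
    spread: float = 8.0,
    proportions: np.ndarray | None = None,
    n_frames: int = 1000,
    seed: int = 0,
) -> tuple[ConformationEnsemble, np.ndarray, np.ndarray]:
    """Frames of the toy glycan with torsions planted around k cluster centers.

    Each frame draws a cluster by ``proportions`` and sets the three
    rotatable torsions to that cluster's center plus Gaussian noise of the
    given spread (degrees).  Returns (ensemble, true labels, centers).
    Default centers are pairwise far apart relative to the default spread
    ("well separated": gaps > 6x spread).
    """
    rng = np.random.default_rng(seed)
    if centers is None:
        base = np.array([
            [60.0, 60.0, 170.0],
            [-65.0, 170.0, -60.0],
            [175.0, -60.0, 55.0],
            [-170.0, -175.0, 175.0],
            [55.0, -170.0, -65.0],
        ])
        if k > len(base):
            raise ValueError(f"supply explicit centers for k > {len(base)}")
        centers = base[:k]
    centers = np.asarray(centers, float)
    if centers.shape != (k, len(PLANTED_TORSIONS)):
        raise ValueError(f"centers must have shape ({k}, {len(PLANTED_TORSIONS)})")
    if proportions is None:
        proportions = np.full(k, 1.0 / k)
    proportions = np.asarray(proportions, float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")

    base_model = make_toy_glycan()
    graph = build_graph(base_model)
    idx = {a.name: i for i, a in enumerate(base_model.atoms)}
    quartets = []
    for names in PLANTED_TORSIONS:
        q = tuple(idx[n] for n in names)
        moving = graph.rotating_set(q[1], q[2])
        quartets.append((q, frozenset(moving)))

    labels = rng.choice(k, size=n_frames, p=proportions)
    frames = np.empty((n_frames, len(base_model.atoms), 3))
    for f in range(n_frames):
        model = base_model.copy()
        values = centers[labels[f]] + rng.normal(0.0, spread, size=len(quartets))
        for (q, moving), value in zip(quartets, values):
            set_dihedral(model, q, moving, float(value))
        frames[f] = model.coordinates
    ensemble = ConformationEnsemble(frames=frames, template=base_model)
    return ensemble, labels, centers


# ---------------------------------------------------------------------------
# sequon proteins
# ---------------------------------------------------------------------------

_SIDECHAIN_OFFSETS: dict[str, list[tuple[str, np.ndarray]]] = {
    "ASN": [
        ("CB", np.array([0.0, 1.2, 0.8])),
        ("CG", np.array([0.0, 2.2, 1.8])),
        ("OD1", np.array([-1.0, 2.7, 2.3])),
        ("ND2", np.array([0.95, 2.9, 2.5])),
    ],
    "SER": [("CB", np.array([0.0, 1.2, 0.8])), ("OG", np.array([0.0, 2.2, 1.8]))],
    "THR": [
        ("CB", np.array([0.0, 1.2, 0.8])),
        ("OG1", np.array([0.0, 2.2, 1.8])),
        ("CG2", np.array([1.2, 1.8, 0.3])),
    ],
    "TRP": [
        ("CB", np.array([0.0, 1.2, 0.8])),
        ("CG", np.array([0.0, 2.2, 1.8])),
        ("CD1", np.array([1.1, 3.0, 2.1])),
    ],
    "PRO": [
        ("CB", np.array([0.0, 1.2, 0.8])),
        ("CG", np.array([-0.8, 2.0, 0.2])),
        ("CD", np.array([-1.4, 1.0, -0.6])),
    ],
}
_GENERIC_SIDECHAIN = [("CB", np.array([0.0, 1.2, 0.8]))]


def make_sequon_protein(
    sequence: str,
    numbering_offset: int = 0,
    chain: str = "A",
    seed: int = 0,
) -> MolecularModel:
    """Idealized extended chain with sidechain stubs for sequon detection
    and attachment; author numbering starts at ``1 + numbering_offset``."""
    atoms: list[AtomRecord] = []
    serial = 1
    for i, letter in enumerate(sequence.upper()):
        if letter not in _ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r} at position {i}")
        res = _ONE_TO_THREE[letter]
        origin = np.array([3.6 * i, 0.0, 0.0])
        backbone = [
            ("N", np.array([0.0, 0.0, 0.0]), "N"),
            ("CA", np.array([1.2, 1.0, 0.0]), "C"),
            ("C", np.array([2.4, 0.2, 0.0]), "C"),
            ("O", np.array([2.5, -1.0, 0.3]), "O"),
        ]
        placed = [(name, origin + off, el) for name, off, el in backbone]
        ca = origin + np.array([1.2, 1.0, 0.0])
        if res != "GLY":
            side = _SIDECHAIN_OFFSETS.get(res, _GENERIC_SIDECHAIN)
            for name, off in side:
                placed.append((name, ca + off, name.lstrip("0123456789")[0]))
        for name, xyz, element in placed:
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=element, residue_name=res,
                    residue_number=1 + numbering_offset + i, chain=chain,
                    coordinates=xyz,
                )
            )
            serial += 1
    return MolecularModel(atoms=atoms)


# ---------------------------------------------------------------------------
# pocket proteins
# ---------------------------------------------------------------------------

def _fibonacci_shell(center: np.ndarray, radius: float, spacing: float) -> list[np.ndarray]:
    n = max(6, int(np.ceil(4.0 * np.pi * radius**2 / spacing**2)))
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azimuth = np.pi * (1.0 + 5.0**0.5) * i
    dots = np.column_stack([
        np.sin(polar) * np.cos(azimuth),
        np.sin(polar) * np.sin(azimuth),
        np.cos(polar),
    ])
    return list(center + radius * dots)


def make_pocket_protein(
    clearance: float,
    site_kind: str = "N",
    seed: int = 0,
    wall_layers: int = 4,
    wall_spacing: float = 1.2,
) -> tuple[MolecularModel, "object"]:
    """A sequon caged inside a rigid spherical shell of inner radius
    ``clearance`` centered on the sidechain attachment atom (ND2).

    The cage is several concentric layers of carbon pseudo-atoms (1 Å
    layer spacing, dot spacing well under the 1.7 Å clash threshold, so
    nothing slips between dots).  Because neither linkage torsion changes
    any glycan atom's distance to the attachment atom, a single-GlcNAc fit
    is feasible iff the probe's maximal radial extent about that atom plus
    the 1.7 Å threshold fits inside ``clearance`` — the yes/no scan label
    is analytic and monotone in ``clearance``.

    Returns (model, site reference of the sequon's Asn).
    """
    from glycokit.graft.attach import SiteRef

    if clearance < 0:
        raise ValueError("clearance must be >= 0")
    protein = make_sequon_protein("GNAS", numbering_offset=0, seed=seed)
    site = SiteRef("A", 2)
    nd2 = protein.atoms[protein.atom_index("ND2", 2, "A")].coordinates
    wall_points: list[np.ndarray] = []
    for layer in range(wall_layers):
        radius = clearance + 1.0 * layer
        if radius < 0.3:
            wall_points.append(nd2.copy())
            continue
        wall_points.extend(_fibonacci_shell(nd2, radius, wall_spacing))
    serial = len(protein.atoms) + 1
    for xyz in wall_points:
        protein.atoms.append(
            AtomRecord(
                serial=serial, name="C", element="C", residue_name="WAL",
                residue_number=serial, chain="W", coordinates=xyz, het=True,
            )
        )
        serial += 1
    return protein, site


def make_windowed_cage(
    window_half_angle: float = 85.0,
    window_direction: np.ndarray | None = None,
    cage_radius: float = 7.0,
    wall_layers: int = 3,
    seed: int = 0,
) -> tuple[MolecularModel, "object"]:
    """A pocket cage with a conical opening: only linkage torsions that
    steer the glycan through the window are clash-free.

    The feasible (phi, psi) region shrinks with ``window_half_angle``
    (degrees about ``window_direction``, default +z of the attachment
    frame), giving a toy problem whose feasible set a brute-force torsion
    grid can map exactly.  Returns (model, site).
    """
    from glycokit.graft.attach import SiteRef

    protein = make_sequon_protein("GNAS", numbering_offset=0, seed=seed)
    site = SiteRef("A", 2)
    nd2 = protein.atoms[protein.atom_index("ND2", 2, "A")].coordinates
    cg = protein.atoms[protein.atom_index("CG", 2, "A")].coordinates
    if window_direction is None:
        window_direction = nd2 - cg
    w = np.asarray(window_direction, float)
    w = w / np.linalg.norm(w)
    cos_cut = np.cos(np.radians(window_half_angle))
    serial = len(protein.atoms) + 1
    for layer in range(wall_layers):
        radius = cage_radius + 1.0 * layer
        for xyz in _fibonacci_shell(nd2, radius, 1.2):
            direction = (xyz - nd2) / radius
            if np.dot(direction, w) >= cos_cut:
                continue  # inside the window: leave open
            protein.atoms.append(
                AtomRecord(
                    serial=serial, name="C", element="C", residue_name="WAL",
                    residue_number=serial, chain="W", coordinates=xyz, het=True,
                )
            )
            serial += 1
    return protein, site


def make_blocked_amide_protein(
    window_half_angle: float = 50.0,
    cage_radius: float = 7.0,
    wall_layers: int = 3,
    seed: int = 0,
) -> tuple[MolecularModel, "object"]:
    """A sequon whose Asn amide assignment blocks grafting until swapped.

    The cage around the Asn sidechain is open only toward the direction the
    OD1 oxygen points: grafting at the authored ND2 fails (false negative),
    while exchanging the OD1/ND2 coordinates re-aims the attachment vector
    through the opening and the graft succeeds — the situation the amide
    swap tool exists for.  Returns (model, site).
    """
    from glycokit.graft.attach import SiteRef

    protein = make_sequon_protein("GNAS", numbering_offset=0, seed=seed)
    site = SiteRef("A", 2)
    cg = protein.atoms[protein.atom_index("CG", 2, "A")].coordinates
    nd2 = protein.atoms[protein.atom_index("ND2", 2, "A")].coordinates
    od1 = protein.atoms[protein.atom_index("OD1", 2, "A")].coordinates
    w = od1 - cg
    w /= np.linalg.norm(w)
    cos_cut = np.cos(np.radians(window_half_angle))
    serial = len(protein.atoms) + 1
    for layer in range(wall_layers):
        radius = cage_radius + 1.0 * layer
        for xyz in _fibonacci_shell(nd2, radius, 1.2):
            if np.dot((xyz - nd2) / radius, w) >= cos_cut:
                continue
            protein.atoms.append(
                AtomRecord(
                    serial=serial, name="C", element="C", residue_name="WAL",
                    residue_number=serial, chain="W", coordinates=xyz, het=True,
                )
            )
            serial += 1
    return protein, site


def probe_envelope_radius(glycan: MolecularModel | None = None) -> float:
    """Maximal distance of any probe atom from its anomeric carbon, Å."""
    glycan = glycan if glycan is not None else reference_glcnac()
    b = glycan.atoms[glycan.atom_index("C1")].coordinates
    return float(max(np.linalg.norm(a.coordinates - b) for a in glycan.atoms))


def probe_radial_extent(glycan: MolecularModel | None = None) -> float:
    """Maximal distance of any clash-counted probe atom from the attachment
    atom once grafted, Å — the quantity the pocket cage radius is compared
    against (invariant under both linkage torsions)."""
    from glycokit.core.linkage import load_linkage_table
    from glycokit.graft.attach import attach_reducing_end

    glycan = glycan if glycan is not None else reference_glcnac()
    stub = make_sequon_protein("GNAS")
    linkage = load_linkage_table()["N-GlcNAc"]
    pose = attach_reducing_end(stub, "A:2", glycan, linkage)
    anchor = pose.protein.atoms[pose.c_p].coordinates
    return float(
        max(
            np.linalg.norm(a.coordinates - anchor)
            for i, a in enumerate(pose.glycan.atoms)
            if i not in pose.exclusions
        )
    )


def make_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator (CLI entry point)."""
    kind = spec.kind
    params = dict(spec.parameters)
    if kind == "toy_glycan":
        return make_toy_glycan()
    if kind == "planted_ensemble":
        return make_planted_ensemble(seed=spec.seed, **params)
    if kind == "pocket_protein":
        return make_pocket_protein(seed=spec.seed, **params)
    if kind == "sequon_protein":
        return make_sequon_protein(seed=spec.seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}")
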