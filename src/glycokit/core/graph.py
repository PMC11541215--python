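"""Molecular graph construction: bond perception, ring flags, degrees.

Ring membership drives rotatable-torsion detection downstream: only bonds
outside cycles can rotate without deforming the molecule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from glycokit.core.model import MolecularModel

# single-bond covalent radii, Å (Cordero et al. consensus values)
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Se": 1.20,
    "Na": 1.66, "Mg": 1.41, "Zn": 1.22, "Fe": 1.32, "Ca": 1.76, "Mn": 1.39,
}
_BOND_TOLERANCE = 1.3  # bonded if d < (r_i + r_j) * tolerance


@dataclass
class MolecularGraph:
    """Atom connectivity with per-node ring membership and degree."""

    graph: nx.Graph
    ring_membership: np.ndarray  # bool per node
    degrees: np.ndarray  # int per node

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def neighbors(self, i: int) -> list[int]:
        return sorted(self.graph.neighbors(i))

    def rotating_set(self, j: int, k: int) -> set[int]:
        """Atoms on the k side when bond j-k is cut (the moving set)."""
        g = self.graph.copy()
        if not g.has_edge(j, k):
            raise ValueError(f"no bond between atoms {j} and {k}")
        g.remove_edge(j, k)
        for comp in nx.connected_components(g):
            if k in comp:
                if j in comp:
                    raise ValueError(f"bond {j}-{k} lies on a cycle; cutting it does not split the graph")
                return set(comp)
        raise AssertionError("unreachable")


def perceive_bonds(model: MolecularModel) -> list[tuple[int, int]]:
    """Distance-based bond perception with element-pair covalent cutoffs."""
    n = len(model.atoms)
    if n < 2:
        return []
    coords = model.coordinates
    radii = np.array(
        [COVALENT_RADII.get(a.element, 0.77) for a in model.atoms]
    )
    max_cut = 2.0 * radii.max() * _BOND_TOLERANCE
    tree = cKDTree(coords)
    bonds = []
    for i, j in tree.query_pairs(max_cut):
        cut = (radii[i] + radii[j]) * _BOND_TOLERANCE
        d = np.linalg.norm(coords[i] - coords[j])
        if 0.4 < d < cut:
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def build_graph(model: MolecularModel) -> MolecularGraph:
    """Graph over all atoms; bonds from the model or perceived by distance.

    Atoms on at least one cycle are flagged; a disconnected molecule gets a
    warning and its components are treated independently downstream.
    """
    bonds = model.bonds if model.bonds else perceive_bonds(model)
    g = nx.Graph()
    g.add_nodes_from(range(len(model.atoms)))
    g.add_edges_from(bonds)
    if len(model.atoms) and nx.number_connected_components(g) > 1:
        warnings.warn(
            f"molecular graph has {nx.number_connected_components(g)} "
            "connected components; they are handled independently",
            stacklevel=2,
        )
    ring = np.zeros(len(model.atoms), dtype=bool)
    for cycle in nx.cycle_basis(g):
        ring[list(cycle)] = True
    degrees = np.array([g.degree(i) for i in range(len(model.atoms))], dtype=int)
    return MolecularGraph(graph=g, ring_membership=ring, degrees=degrees)
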