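"""Rotatable-torsion detection on the molecular graph.

Ring bonds cannot rotate without deforming the ring, so the search is
restricted to the acyclic parts: every non-ring atom with exactly two
bonds (degree two) marks a potential rotation axis through each of its
bonds.  For such an atom X with neighbours U and V, the bond X-U defines
the quartet (V, X, U, W) — W a further neighbour of U — and symmetrically
for X-V.  Quartets sharing a central bond are deduplicated, and each
quartet carries the atom set that moves when its central bond is cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from glycokit.core.graph import MolecularGraph


@dataclass(frozen=True)
class TorsionQuartet:
    """Four atom indices (i, j, k, l); the rotation axis is the j-k bond."""

    atoms: tuple[int, int, int, int]
    rotating_set: frozenset[int] = field(default_factory=frozenset)

    @property
    def central_bond(self) -> tuple[int, int]:
        j, k = self.atoms[1], self.atoms[2]
        return (min(j, k), max(j, k))


def detect_torsion_pairs(graph: MolecularGraph) -> list[TorsionQuartet]:
    """Enumerate rotatable torsion quartets (deterministic ordering).

    An empty list is valid (e.g. a bare ring has no rotatable torsions).
    The rotating set of a quartet (i, j, k, l) is the connected component
    containing k after the j-k bond is cut.
    """
    ring = graph.ring_membership
    quartets: dict[tuple[int, int], TorsionQuartet] = {}
    for x in graph.nodes:
        if ring[x] or graph.degrees[x] != 2:
            continue
        u, v = graph.neighbors(x)
        for near, far in ((u, v), (v, u)):
            # central bond x-near; need a fourth atom beyond `near`
            candidates = [w for w in graph.neighbors(near) if w != x]
            if not candidates:
                continue
            w = min(candidates)
            bond = (min(x, near), max(x, near))
            if bond in quartets:
                continue
            rotating = frozenset(graph.rotating_set(x, near))
            quartets[bond] = TorsionQuartet(atoms=(far, x, near, w),
                                            rotating_set=rotating)
    return [quartets[bond] for bond in sorted(quartets)]
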