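"""The steric loss.

For protein atom set P and (rotated) glycan atom set G', with D_ij the
Euclidean distance between glycan atom i and protein atom j,

    F = sum over pairs with D_ij < 1.7 of  200 * exp(D_ij^2)

The 1.7 Å threshold is the van der Waals radius of carbon; the inequality
is strict, so a pair at exactly 1.7 Å contributes nothing.  Reducing-end
glycan atoms (covalently bonded to the protein by construction) are
excluded from the sum.  F = 0 therefore means "no clash": it is the graft
success criterion throughout the package.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

CLASH_THRESHOLD = 1.7  # Å, van der Waals radius of a carbon atom
CLASH_PREFACTOR = 200.0


def steric_fitness(
    protein_coords: np.ndarray,
    glycan_coords: np.ndarray,
    threshold: float = CLASH_THRESHOLD,
    exclusions: set[int] | frozenset[int] | None = None,
    protein_tree: cKDTree | None = None,
) -> tuple[float, list[tuple[int, int, float]]]:
    """Evaluate the steric loss and enumerate the clashing pairs.

    Parameters
    ----------
    protein_coords, glycan_coords:
        (Np, 3) and (Ng, 3) arrays, Å.  Either may be empty (vacuous sum).
    exclusions:
        glycan atom indices excluded from the sum (the reducing end).
    protein_tree:
        optional pre-built KD-tree over ``protein_coords`` for repeated
        evaluation against a fixed protein.

    Returns
    -------
    (fitness, clashes) where clashes is a list of
    (protein_index, glycan_index, distance) pairs with distance < threshold.
    """
    protein_coords = np.asarray(protein_coords, float).reshape(-1, 3)
    glycan_coords = np.asarray(glycan_coords, float).reshape(-1, 3)
    if len(protein_coords) == 0 or len(glycan_coords) == 0:
        return 0.0, []
    if not (np.all(np.isfinite(protein_coords)) and np.all(np.isfinite(glycan_coords))):
        raise ValueError("non-finite coordinates in steric evaluation")
    exclusions = exclusions or frozenset()
    tree = protein_tree if protein_tree is not None else cKDTree(protein_coords)
    fitness = 0.0
    clashes: list[tuple[int, int, float]] = []
    neighbor_lists = tree.query_ball_point(glycan_coords, threshold)
    for gi, neighbors in enumerate(neighbor_lists):
        if gi in exclusions or not neighbors:
            continue
        for pj in neighbors:
            d = float(np.linalg.norm(glycan_coords[gi] - protein_coords[pj]))
            if d < threshold:  # query_ball_point includes the boundary
                fitness += CLASH_PREFACTOR * float(np.exp(d * d))
                clashes.append((pj, gi, d))
    return fitness, clashes
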