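"""The wiggle fallback: bounded random moves over all rotatable torsions.

When no conformer can be placed clash-free by the linkage-torsion search
alone, the lowest-loss pose is refined by perturbing every rotatable
torsion — the glycan-internal quartets plus the linkage phi/psi — with
independent uniform draws within ±10° (the low end of glycosidic-linkage
torsional fluctuation at room temperature), keeping the best pose found,
for up to 40 iterations or until the loss reaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from glycokit.graft.attach import GraftPose

WIGGLE_STEP_RANGE = 10.0  # degrees
WIGGLE_MAX_ITER = 40


@dataclass
class WiggleOutcome:
    pose: GraftPose
    fitness: float
    iterations_used: int
    success: bool
    moves: list[np.ndarray] = field(default_factory=list)


def wiggle_refine(
    pose: GraftPose,
    protein_coords: np.ndarray | None = None,
    protein_tree: cKDTree | None = None,
    max_iter: int = WIGGLE_MAX_ITER,
    step_range: float = WIGGLE_STEP_RANGE,
    step_mode: str = "half_width",
    rng: np.random.Generator | None = None,
    record_moves: bool = False,
) -> WiggleOutcome:
    """Stochastically refine ``pose``; returns the best pose found.

    ``step_mode="half_width"`` draws each move from ±step_range (default);
    ``"full_width"`` reads the range as a total width (±step_range/2).
    A clash-free input is returned unchanged with zero iterations.
    """
    if step_mode not in ("half_width", "full_width"):
        raise ValueError("step_mode must be 'half_width' or 'full_width'")
    half = step_range if step_mode == "half_width" else step_range / 2.0
    rng = rng if rng is not None else np.random.default_rng()
    if protein_coords is None:
        protein_coords = pose.protein.coordinates
    if protein_tree is None:
        protein_tree = cKDTree(protein_coords)

    best = pose.copy()
    best_f, _ = best.fitness(protein_coords, protein_tree)
    outcome = WiggleOutcome(pose=best, fitness=best_f, iterations_used=0,
                            success=best_f == 0.0)
    if best_f == 0.0:
        return outcome

    quartets = pose.internal_quartets()
    n_torsions = len(quartets) + 2  # + linkage phi, psi
    for iteration in range(1, max_iter + 1):
        candidate = best.copy()
        deltas = rng.uniform(-half, half, size=n_torsions)
        for q, quartet in enumerate(quartets):
            candidate.rotate_internal(quartet, deltas[q])
        candidate.set_torsions(
            phi=candidate.phi + deltas[-2], psi=candidate.psi + deltas[-1]
        )
        f, _ = candidate.fitness(protein_coords, protein_tree)
        if record_moves:
            outcome.moves.append(deltas)
        if f < best_f:
            best, best_f = candidate, f
        outcome.iterations_used = iteration
        if best_f == 0.0:
            break
    outcome.pose = best
    outcome.fitness = best_f
    outcome.success = best_f == 0.0
    return outcome
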