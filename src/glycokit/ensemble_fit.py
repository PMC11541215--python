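"""Multi-frame ensemble fitting and solvent-accessible surface area.

To estimate the volume a flexible glycan excludes around its site, frames
are drawn at random from the free-glycan trajectory, attached with linkage
torsions sampled uniformly from the configured ranges, and kept only if no
glycan atom comes within 1.7 Å of a protein atom.  The draw-and-test
block (200 frames) is repeated five times per site and the accepted poses
are aggregated into a multi-model complex whose SASA quantifies the
occluded surface.

SASA uses dot sampling (Shrake-Rupley with Fibonacci-lattice spheres);
the headline parameters mirror common practice for glycan shielding:
water probe radius 0.14 nm and 15 dots per sphere.  Results are nm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from glycokit.conformers.ensemble import ConformationEnsemble
from glycokit.core.linkage import LinkageSpec
from glycokit.core.model import MolecularModel
from glycokit.graft.attach import GraftPose, SiteRef, attach_reducing_end, parse_site
from glycokit.graft.fitness import CLASH_THRESHOLD

DEFAULT_N_FRAMES = 200
DEFAULT_REPEATS = 5
PROBE_RADIUS_NM = 0.14
DOTS_PER_SPHERE = 15

# vdW radii, Å (Bondi-style consensus); overridable per call
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Se": 1.90,
}


@dataclass
class EnsembleResult:
    """Accepted/rejected bookkeeping plus the accepted glycan poses."""

    accepted_frames: list[tuple[int, int, float, float]]  # (repeat, frame, phi, psi)
    rejected_count: int
    repeats: int
    n_frames: int
    poses: list[GraftPose] = field(default_factory=list)
    sasa_per_model: np.ndarray | None = None  # nm², filled by the caller
    parameters: dict = field(default_factory=dict)

    @property
    def accepted_count(self) -> int:
        return len(self.accepted_frames)

    @property
    def acceptance_fraction(self) -> float:
        total = self.accepted_count + self.rejected_count
        return self.accepted_count / total if total else 0.0

    def aggregated_models(self) -> list[MolecularModel]:
        """One protein+glycan complex per accepted pose (multi-model output)."""
        models = []
        for i, pose in enumerate(self.poses):
            m = pose.complex_model()
            m.model_id = i + 1
            models.append(m)
        return models


def ensemble_fit(
    protein: MolecularModel,
    site: SiteRef | str,
    trajectory: ConformationEnsemble,
    linkage: LinkageSpec,
    n_frames: int = DEFAULT_N_FRAMES,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    threshold: float = CLASH_THRESHOLD,
    clash_coords: np.ndarray | None = None,
) -> EnsembleResult:
    """Draw, attach and clash-test glycan frames at one site.

    Frames are drawn without replacement within a repeat (with replacement,
    plus a warning, if the trajectory is shorter than ``n_frames``) and
    independently across repeats.  A frame is accepted iff no non-reducing-
    end glycan atom lies strictly within ``threshold`` of any protein atom.
    ``clash_coords`` overrides the clash set P (by default the whole
    protein), e.g. to extend it with other glycans or restrict it.
    """
    site = parse_site(site)
    rng = np.random.default_rng(seed)
    protein_coords = (
        protein.coordinates if clash_coords is None
        else np.asarray(clash_coords, float).reshape(-1, 3)
    )
    tree = cKDTree(protein_coords) if len(protein_coords) else None
    replace = trajectory.n_frames < n_frames
    if replace:
        warnings.warn(
            f"trajectory has {trajectory.n_frames} < {n_frames} frames; "
            "drawing with replacement",
            stacklevel=2,
        )
    accepted: list[tuple[int, int, float, float]] = []
    poses: list[GraftPose] = []
    rejected = 0
    for repeat in range(repeats):
        frame_ids = rng.choice(trajectory.n_frames, size=n_frames, replace=replace)
        for frame in frame_ids:
            glycan = trajectory.frame_model(int(frame))
            pose = attach_reducing_end(protein, site, glycan, linkage)
            phi = linkage.phi_range.sample(rng)
            psi = linkage.psi_range.sample(rng)
            pose.set_torsions(phi=phi, psi=psi)
            fitness, _ = pose.fitness(protein_coords, tree, threshold=threshold)
            if fitness == 0.0:
                accepted.append((repeat, int(frame), float(phi), float(psi)))
                poses.append(pose)
            else:
                rejected += 1
    return EnsembleResult(
        accepted_frames=accepted,
        rejected_count=rejected,
        repeats=repeats,
        n_frames=n_frames,
        poses=poses,
        parameters={
            "seed": seed,
            "n_frames": n_frames,
            "repeats": repeats,
            "threshold": threshold,
            "site": str(site),
        },
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    dots_per_sphere: int = DOTS_PER_SPHERE,
) -> np.ndarray:
    """Per-atom accessible surface area, Å², by dot sampling.

    Each atom's sphere of radius r_i + probe carries ``dots_per_sphere``
    quasi-uniform dots; a dot is buried if it falls inside any neighbour's
    expanded sphere.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    expanded = radii + probe_radius
    dots = _fibonacci_sphere(dots_per_sphere)
    tree = cKDTree(coords)
    areas = np.zeros(n)
    max_reach = 2.0 * expanded.max()
    for i in range(n):
        sphere = coords[i] + expanded[i] * dots
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        exposed = np.ones(len(sphere), dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(sphere - coords[j], axis=1)
            exposed &= d >= expanded[j]
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return areas


def compute_sasa(
    models: MolecularModel | list[MolecularModel],
    probe_radius_nm: float = PROBE_RADIUS_NM,
    dots_per_sphere: int = DOTS_PER_SPHERE,
    radii_table: dict[str, float] | None = None,
    probe_mode: str = "radius",
    per_atom: bool = False,
) -> np.ndarray | list[np.ndarray]:
    """Solvent-accessible surface area per model, nm².

    ``probe_mode="radius"`` (default) treats 0.14 nm as the probe radius —
    the conventional water probe; ``"diameter"`` reads it literally as a
    diameter (probe radius 0.07 nm).  Unknown elements raise a ``KeyError``
    naming the element.  With ``per_atom=True`` the per-atom areas (nm²)
    are returned for each model instead of totals.
    """
    if probe_mode not in ("radius", "diameter"):
        raise ValueError("probe_mode must be 'radius' or 'diameter'")
    probe_angstrom = probe_radius_nm * 10.0
    if probe_mode == "diameter":
        probe_angstrom /= 2.0
    if isinstance(models, MolecularModel):
        models = [models]
    table = radii_table if radii_table is not None else VDW_RADII
    results = []
    for model in models:
        radii = []
        for atom in model.atoms:
            if atom.element not in table:
                raise KeyError(
                    f"no van der Waals radius for element {atom.element!r}"
                )
            radii.append(table[atom.element])
        areas = shrake_rupley(
            model.coordinates, np.array(radii), probe_angstrom, dots_per_sphere
        ) / 100.0  # Å² -> nm²
        results.append(areas if per_atom else areas.sum())
    if per_atom:
        return results
    return np.array(results)


def delta_sasa(
    protein: MolecularModel,
    complexes: list[MolecularModel],
    **sasa_kwargs,
) -> float:
    """Glycan occlusion: SASA(protein alone) minus the mean protein-part
    SASA over the complex models, nm²."""
    alone = float(np.sum(compute_sasa(protein, per_atom=True, **sasa_kwargs)[0]))
    if not complexes:
        return 0.0
    n_protein = len(protein.atoms)
    within = [
        float(np.sum(compute_sasa(c, per_atom=True, **sasa_kwargs)[0][:n_protein]))
        for c in complexes
    ]
    return alone - float(np.mean(within))
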