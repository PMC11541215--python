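"""Site-level and protein-level grafting orchestration.

For one site, conformers are tried in descending population order (the
cascade G0, G1, ...): each is attached and its linkage torsions optimized
by the genetic search.  The first conformer reaching zero steric loss
wins.  If none does, the lowest-loss conformer is handed to the wiggle
fallback.  For a whole protein, sites are processed in residue order and
every successfully placed glycan joins the protein atom set for later
sites, so glycans cannot overlap each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from glycokit.conformers.library import ConformerLibrary
from glycokit.core.linkage import LinkageSpec
from glycokit.core.model import MolecularModel, merge_models
from glycokit.graft.attach import AttachmentError, GraftPose, SiteRef, attach_reducing_end, parse_site
from glycokit.graft.ga import GAConfig, ga_optimize
from glycokit.graft.wiggle import WIGGLE_MAX_ITER, WIGGLE_STEP_RANGE, wiggle_refine

logger = logging.getLogger(__name__)


@dataclass
class GraftResult:
    """Outcome of grafting one site."""

    success: bool
    pose: GraftPose | None
    phase: str  # "ga" or "wiggle"
    site: SiteRef
    fitness: float
    clusters_tried: list[int] = field(default_factory=list)
    fitness_by_cluster: dict[int, float] = field(default_factory=dict)
    wiggle_iterations_used: int = 0
    error: str = ""

    def to_dict(self) -> dict:
        return {
            "site": str(self.site),
            "success": self.success,
            "phase": self.phase,
            "fitness": self.fitness,
            "phi": None if self.pose is None else round(self.pose.phi, 3),
            "psi": None if self.pose is None else round(self.pose.psi, 3),
            "cluster_used": None if self.pose is None else self.pose.cluster_id,
            "clusters_tried": self.clusters_tried,
            "fitness_by_cluster": {str(k): v for k, v in self.fitness_by_cluster.items()},
            "wiggle_iterations_used": self.wiggle_iterations_used,
            "error": self.error,
        }


def graft_site(
    protein: MolecularModel,
    site: SiteRef | str,
    library: ConformerLibrary,
    linkage: LinkageSpec,
    config: GAConfig | None = None,
    extra_protein_coords: np.ndarray | None = None,
    wiggle_max_iter: int = WIGGLE_MAX_ITER,
    wiggle_step_range: float = WIGGLE_STEP_RANGE,
) -> GraftResult:
    """Attach the best-fitting conformer from ``library`` at ``site``.

    ``extra_protein_coords`` extends the clash set P (e.g. with glycans
    already placed at other sites).  All randomness derives from
    ``config.seed`` via per-cluster sub-streams.
    """
    if len(library) == 0:
        raise ValueError("conformer library is empty")
    site = parse_site(site)
    config = config or GAConfig()
    protein_coords = protein.coordinates
    if extra_protein_coords is not None and len(extra_protein_coords):
        protein_coords = np.vstack([protein_coords, extra_protein_coords])
    tree = cKDTree(protein_coords)
    streams = np.random.SeedSequence(config.seed).spawn(len(library) + 1)

    clusters_tried: list[int] = []
    fitness_by_cluster: dict[int, float] = {}
    best_pose: GraftPose | None = None
    best_fitness = np.inf
    for rank, entry in enumerate(library.entries):
        try:
            pose = attach_reducing_end(
                protein, site, entry.structure, linkage, cluster_id=entry.cluster_id
            )
        except AttachmentError as exc:
            return GraftResult(
                success=False, pose=None, phase="ga", site=site,
                fitness=np.inf, clusters_tried=clusters_tried, error=str(exc),
            )
        clusters_tried.append(entry.cluster_id)

        def evaluate(phi: float, psi: float, pose: GraftPose = pose) -> float:
            pose.set_torsions(phi=phi, psi=psi)
            return pose.fitness(protein_coords, tree)[0]

        rng = np.random.default_rng(streams[rank])
        phi_b, psi_b, fit_b, _ = ga_optimize(
            evaluate, linkage.phi_range, linkage.psi_range, config, rng
        )
        fitness_by_cluster[entry.cluster_id] = fit_b
        if fit_b < best_fitness:
            pose.set_torsions(phi=phi_b, psi=psi_b)
            best_pose, best_fitness = pose.copy(), fit_b
        if fit_b == 0.0:
            logger.info("site %s: cluster %d clash-free after GA", site, entry.cluster_id)
            return GraftResult(
                success=True, pose=best_pose, phase="ga", site=site,
                fitness=0.0, clusters_tried=clusters_tried,
                fitness_by_cluster=fitness_by_cluster,
            )

    logger.info(
        "site %s: no conformer clash-free after GA (best %.1f from cluster %d); wiggling",
        site, best_fitness, best_pose.cluster_id,
    )
    outcome = wiggle_refine(
        best_pose,
        protein_coords=protein_coords,
        protein_tree=tree,
        max_iter=wiggle_max_iter,
        step_range=wiggle_step_range,
        rng=np.random.default_rng(streams[-1]),
    )
    return GraftResult(
        success=outcome.success,
        pose=outcome.pose,
        phase="wiggle",
        site=site,
        fitness=outcome.fitness,
        clusters_tried=clusters_tried,
        fitness_by_cluster=fitness_by_cluster,
        wiggle_iterations_used=outcome.iterations_used,
    )


def graft_protein(
    protein: MolecularModel,
    site_plan: dict,
    config: GAConfig | None = None,
    include_grafted_in_protein: bool = True,
) -> tuple[MolecularModel, list[GraftResult]]:
    """Graft every site in ``site_plan`` (site -> (library, linkage)).

    Sites are processed in (chain, residue number) order; failures at one
    site do not stop the others.  Returns the merged glycoprotein (protein
    plus every successful glycan, CONECT-linked) and per-site results.

    One-shot glycosylation is this call with the same (library, linkage)
    for every site.
    """
    config = config or GAConfig()
    sites = [parse_site(s) for s in site_plan]
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate sites in site plan")
    order = np.argsort(
        [f"{s.chain}|{s.residue_number:08d}|{s.insertion_code}" for s in sites],
        kind="stable",
    )
    plans = list(site_plan.items())
    streams = np.random.SeedSequence(config.seed).spawn(len(sites))
    results: list[GraftResult] = []
    extra_coords: list[np.ndarray] = []
    merged = protein.copy()
    for pos in order:
        site = sites[pos]
        library, linkage = plans[pos][1]
        site_config = GAConfig(
            population_size=config.population_size,
            generations=config.generations,
            parent_fraction=config.parent_fraction,
            mutation_rate=config.mutation_rate,
            seed=int(streams[pos].generate_state(1)[0] % (2**31)),
            early_exit_on_zero=config.early_exit_on_zero,
        )
        extra = (
            np.vstack(extra_coords) if (include_grafted_in_protein and extra_coords)
            else None
        )
        result = graft_site(
            protein, site, library, linkage, config=site_config,
            extra_protein_coords=extra,
        )
        results.append(result)
        if result.success and result.pose is not None:
            extra_coords.append(result.pose.glycan.coordinates)
            merged = merge_models(
                merged, result.pose.glycan,
                extra_bonds=[(result.pose.c_p, result.pose.b_g)],
            )
    return merged, results
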