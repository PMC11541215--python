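"""Conformer library assembly, torsion profiling, and library I/O.

A library entry couples an actually-sampled frame (the one nearest its
cluster's density peak) with the cluster's population weight.  Entries are
ordered by descending weight, so entry 0 is the dominant solution conformer
("G0" in the grafting cascade).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from glycokit.conformers.cluster import ClusterModel, select_cluster_count
from glycokit.conformers.density import DensityModel, find_density_peak
from glycokit.conformers.ensemble import ConformationEnsemble, merge_replicas
from glycokit.conformers.features import (
    ReducedEmbedding,
    flatten_distances,
    reduce_dimensionality,
)
from glycokit.core.geometry import measure_dihedral
from glycokit.core.model import MolecularModel
from glycokit.core.pdbio import read_structure, write_structure

HISTOGRAM_BIN_WIDTH = 5.0  # degrees


@dataclass
class LibraryEntry:
    structure: MolecularModel
    weight: float
    cluster_id: int
    frame_index: int = -1  # index into the merged ensemble, provenance
    replica_index: int = -1


@dataclass
class ConformerLibrary:
    """Ranked representative structures with normalized cluster weights."""

    entries: list[LibraryEntry]
    glycan_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(e.weight for e in self.entries)
        if self.entries and abs(total - 1.0) > 1e-9:
            raise ValueError(f"library weights sum to {total}, not 1")
        order = sorted(
            range(len(self.entries)),
            key=lambda i: (-self.entries[i].weight, self.entries[i].cluster_id),
        )
        self.entries = [self.entries[i] for i in order]
        compositions = {
            tuple(a.name for a in e.structure.atoms) for e in self.entries
        }
        if len(compositions) > 1:
            raise ValueError("library entries differ in atom composition")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.entries])

    def write(self, pdb_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Multi-model PDB (model i = rank-i conformer) + JSON sidecar."""
        models = []
        for rank, entry in enumerate(self.entries):
            m = entry.structure.copy()
            m.model_id = rank + 1
            models.append(m)
        write_structure(models, pdb_path)
        sidecar = Path(sidecar_path) if sidecar_path else Path(pdb_path).with_suffix(".json")
        payload = {
            "glycan_id": self.glycan_id,
            "entries": [
                {
                    "rank": rank,
                    "cluster_id": e.cluster_id,
                    "weight": e.weight,
                    "frame_index": e.frame_index,
                    "replica_index": e.replica_index,
                }
                for rank, e in enumerate(self.entries)
            ],
            "metadata": self.metadata,
        }
        sidecar.write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_single(cls, structure: MolecularModel, glycan_id: str = "") -> "ConformerLibrary":
        """A one-entry library (weight 1), e.g. the GlcNAc scanning probe."""
        return cls(entries=[LibraryEntry(structure=structure, weight=1.0, cluster_id=0)],
                   glycan_id=glycan_id)

    @classmethod
    def load(cls, pdb_path: str | Path, sidecar_path: str | Path | None = None) -> "ConformerLibrary":
        models = read_structure(Path(pdb_path))
        sidecar = Path(sidecar_path) if sidecar_path else Path(pdb_path).with_suffix(".json")
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            entries = [
                LibraryEntry(
                    structure=models[item["rank"]],
                    weight=item["weight"],
                    cluster_id=item["cluster_id"],
                    frame_index=item.get("frame_index", -1),
                    replica_index=item.get("replica_index", -1),
                )
                for item in payload["entries"]
            ]
            return cls(entries=entries, glycan_id=payload.get("glycan_id", ""),
                       metadata=payload.get("metadata", {}))
        # no sidecar: equal weights, model order taken as rank order
        n = len(models)
        entries = [
            LibraryEntry(structure=m, weight=1.0 / n, cluster_id=i)
            for i, m in enumerate(models)
        ]
        return cls(entries=entries)


def build_conformer_library(
    ensemble: ConformationEnsemble,
    embedding: ReducedEmbedding,
    clusters: ClusterModel,
    density_models: dict[int, DensityModel],
    glycan_id: str = "",
) -> ConformerLibrary:
    """Pick each cluster's representative frame and weight it by population.

    The representative is the sampled frame whose embedding row lies nearest
    (Euclidean) to the cluster's density peak; the weight is the cluster's
    frame count divided by the total.  Empty clusters are dropped and the
    remaining weights renormalized.
    """
    F = ensemble.n_frames
    labels = clusters.labels
    raw_entries = []
    for cid in range(clusters.n_clusters):
        members = np.flatnonzero(labels == cid)
        if len(members) == 0:
            warnings.warn(f"cluster {cid} is empty; excluded from the library",
                          stacklevel=2)
            continue
        if cid not in density_models:
            raise KeyError(f"no density model supplied for cluster {cid}")
        peak = density_models[cid].peak
        dists = np.linalg.norm(embedding.T[members] - peak, axis=1)
        frame = int(members[np.argmin(dists)])
        raw_entries.append((cid, frame, len(members)))
    total = sum(count for _, _, count in raw_entries)
    if total == 0:
        raise ValueError("no populated clusters")
    entries = [
        LibraryEntry(
            structure=ensemble.frame_model(frame),
            weight=count / total,
            cluster_id=cid,
            frame_index=frame,
            replica_index=int(ensemble.replica_of[frame]),
        )
        for cid, frame, count in raw_entries
    ]
    meta = {
        "n_frames": F,
        "seed": clusters.seed,
        "silhouette_by_k": {str(k): v for k, v in clusters.silhouette_by_k.items()},
        "cluster_sizes": {str(cid): int(c) for cid, _, c in raw_entries},
        "bandwidths": {
            str(cid): (None if np.isnan(dm.bandwidth) else dm.bandwidth)
            for cid, dm in density_models.items()
        },
    }
    return ConformerLibrary(entries=entries, glycan_id=glycan_id, metadata=meta)


@dataclass
class TorsionProfile:
    """Per-frame torsion series (degrees) and per-cluster circular histograms."""

    quartets: list[tuple[int, int, int, int]]
    series: np.ndarray  # (n_quartets, F), NaN where geometry was degenerate
    histograms: dict[int, np.ndarray] = field(default_factory=dict)
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(-180.0, 180.0 + HISTOGRAM_BIN_WIDTH,
                                          HISTOGRAM_BIN_WIDTH)
    )

    def circular_mean(self, quartet_index: int) -> float:
        vals = self.series[quartet_index]
        vals = vals[np.isfinite(vals)]
        rad = np.radians(vals)
        return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def torsion_profiles(
    ensemble: ConformationEnsemble,
    quartets: list[tuple[int, int, int, int]],
    labels: np.ndarray | None = None,
) -> TorsionProfile:
    """Measure each quartet's dihedral in every frame; histogram per cluster.

    Frames with degenerate (collinear) geometry for a quartet are recorded
    as missing for that quartet.
    """
    F = ensemble.n_frames
    series = np.full((len(quartets), F), np.nan)
    for f in range(F):
        model = ensemble.frame_model(f)
        for q, quartet in enumerate(quartets):
            try:
                series[q, f] = measure_dihedral(model, quartet)
            except ValueError:
                pass  # stays NaN
    profile = TorsionProfile(quartets=list(quartets), series=series)
    if labels is not None:
        labels = np.asarray(labels)
        for cid in np.unique(labels):
            member_vals = series[:, labels == cid]
            hists = [
                np.histogram(row[np.isfinite(row)], bins=profile.bin_edges)[0]
                for row in member_vals
            ]
            profile.histograms[int(cid)] = np.asarray(hists)
    return profile


def run_pipeline(
    trajectories: "list | ConformationEnsemble",
    glycan_id: str = "",
    dim: int = 3,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 42,
) -> tuple[ConformerLibrary, ReducedEmbedding, ClusterModel, dict[int, DensityModel]]:
    """End-to-end conformer analysis: merge -> featurize -> PCA -> GMM -> KDE.

    ``trajectories`` may be an existing ensemble or a list of replicas (each
    a list of models or an ensemble).  Returns the library plus the
    intermediate objects for reporting.
    """
    if isinstance(trajectories, ConformationEnsemble):
        ensemble = trajectories
    else:
        ensemble = merge_replicas(trajectories)
    flat = flatten_distances(ensemble)
    embedding = reduce_dimensionality(flat, dim=dim)
    clusters = select_cluster_count(embedding, k_min=k_min, k_max=k_max, seed=seed)
    density_models = {
        cid: find_density_peak(embedding.T[clusters.labels == cid], seed=seed)
        for cid in range(clusters.n_clusters)
        if np.any(clusters.labels == cid)
    }
    library = build_conformer_library(
        ensemble, embedding, clusters, density_models, glycan_id=glycan_id
    )
    return library, embedding, clusters, density_models
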