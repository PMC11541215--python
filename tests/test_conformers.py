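"""Conformer pipeline: replica merging, distance featurization, PCA,
mixture clustering, density peaks, and library assembly."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import confusion_matrix

from glycokit.conformers import (
    ConformationEnsemble,
    build_conformer_library,
    find_density_peak,
    flatten_distances,
    gaussian_kernel,
    merge_replicas,
    reduce_dimensionality,
    run_pipeline,
    select_cluster_count,
    torsion_profiles,
)
from glycokit.conformers.density import kde_density
from glycokit.conformers.features import FlatDistanceRepresentation, ReducedEmbedding
from glycokit.core.geometry import random_rigid_motion
from glycokit.core.model import AtomRecord, MolecularModel
from glycokit.fixtures import make_planted_ensemble, make_toy_glycan


def _linear_ensemble(positions):
    """One frame of collinear pseudo-atoms at the given x positions."""
    atoms = [
        AtomRecord(serial=i + 1, name=f"C{i+1}", element="C", residue_name="UNK",
                   residue_number=1, chain="A", coordinates=(x, 0.0, 0.0))
        for i, x in enumerate(positions)
    ]
    template = MolecularModel(atoms=atoms)
    return ConformationEnsemble(frames=template.coordinates[None], template=template)


class TestMerge:
    def test_frames_concatenate_with_replica_index(self):
        ens1, _, _ = make_planted_ensemble(k=2, n_frames=10, seed=1)
        ens2, _, _ = make_planted_ensemble(k=2, n_frames=15, seed=2)
        merged = merge_replicas([ens1, ens2])
        assert merged.n_frames == 25
        assert (merged.replica_of == [0] * 10 + [1] * 15).all()

    def test_hydrogens_removed_on_merge(self):
        glycan = make_toy_glycan()
        with_h = glycan.copy()
        for i in range(7):
            with_h.atoms.append(
                AtomRecord(serial=100 + i, name=f"H{i+1}", element="H",
                           residue_name="NAG", residue_number=1, chain="X",
                           coordinates=(10.0 + i, 0.0, 0.0))
            )
        merged = merge_replicas([[with_h, with_h]])
        assert merged.n_atoms == len(glycan.atoms)
        assert all(el != "H" for _, el, _ in merged.atom_meta)

    def test_permuted_atoms_rematched_by_identity(self):
        glycan = make_toy_glycan()
        permuted = glycan.copy()
        order = np.arange(len(glycan.atoms))[::-1]
        permuted.atoms = [permuted.atoms[i] for i in order]
        merged = merge_replicas([[glycan], [permuted]])
        assert np.abs(merged.frames[0] - merged.frames[1]).max() < 1e-12

    def test_composition_mismatch_names_offender(self):
        glycan = make_toy_glycan()
        broken = glycan.copy()
        broken.atoms[3].name = "XX"
        with pytest.raises(ValueError, match="mismatch"):
            merge_replicas([[glycan], [broken]])


class TestFlatten:
    def test_three_collinear_atoms_hand_computed(self):
        flat = flatten_distances(_linear_ensemble([0.0, 1.0, 2.0]))
        # lower-triangle column-major: g21, g31, g32
        assert np.allclose(flat.matrix[0], [1.0, 2.0, 1.0])

    def test_rigid_motion_invariance(self, rng):
        ens, _, _ = make_planted_ensemble(k=2, n_frames=12, seed=3)
        reference = flatten_distances(ens).matrix
        moved = ens.frames.copy()
        for f in range(len(moved)):
            moved[f] = random_rigid_motion(rng)(moved[f])
        shaken = ConformationEnsemble(frames=moved, template=ens.template)
        assert np.abs(flatten_distances(shaken).matrix - reference).max() < 1e-9

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(-4, 4, (5, 3))
        ens = _linear_ensemble(range(5))
        ens.frames = coords[None]
        row = flatten_distances(ens).matrix[0]
        expected = [
            np.linalg.norm(coords[i] - coords[j])
            for j in range(5) for i in range(j + 1, 5)
        ]
        assert np.allclose(row, expected, atol=1e-12)

    def test_nonfinite_coordinate_is_located(self):
        ens, _, _ = make_planted_ensemble(k=2, n_frames=5, seed=4)
        ens.frames[3, 2, 1] = np.nan
        with pytest.raises(ValueError, match="frame 3, atom 2"):
            flatten_distances(ens)


class TestReduce:
    def test_planted_rank_three_data_fully_explained(self, rng):
        basis = rng.normal(size=(3, 20))
        data = rng.normal(size=(50, 3)) @ basis + rng.normal(size=20)
        flat = FlatDistanceRepresentation(matrix=data)
        emb = reduce_dimensionality(flat, dim=3)
        assert emb.cumulative_variance[-1] == pytest.approx(1.0, abs=1e-9)
        assert emb.T.shape == (50, 3)

    def test_default_dimension_is_three(self):
        ens, _, _ = make_planted_ensemble(k=2, n_frames=30, seed=5)
        emb = reduce_dimensionality(flatten_distances(ens))
        assert emb.dim == 3
        assert np.all(np.diff(emb.explained_variance_ratio) <= 1e-12)

    def test_loadings_orthonormal(self):
        ens, _, _ = make_planted_ensemble(k=2, n_frames=30, seed=6)
        emb = reduce_dimensionality(flatten_distances(ens))
        gram = emb.components @ emb.components.T
        assert np.allclose(gram, np.eye(3), atol=1e-9)

    def test_zero_variance_rejected(self):
        flat = FlatDistanceRepresentation(matrix=np.ones((10, 6)))
        with pytest.raises(ValueError, match="degenerate"):
            reduce_dimensionality(flat)

    def test_separated_groups_stay_separated(self):
        ens, labels, _ = make_planted_ensemble(
            k=2, n_frames=200, seed=7, spread=5.0
        )
        emb = reduce_dimensionality(flatten_distances(ens))
        a, b = emb.T[labels == 0], emb.T[labels == 1]
        gap = np.linalg.norm(a.mean(0) - b.mean(0))
        spread = max(np.linalg.norm(a - a.mean(0), axis=1).mean(),
                     np.linalg.norm(b - b.mean(0), axis=1).mean())
        assert gap > 5 * spread


class TestClusterSelection:
    def test_three_planted_gaussians_recovered(self, rng):
        centers = np.array([[0, 0, 0], [40, 0, 0], [0, 40, 0]], dtype=float)
        labels_true = rng.integers(0, 3, size=600)
        points = centers[labels_true] + rng.normal(0, 1.5, (600, 3))
        emb = ReducedEmbedding(T=points, components=np.eye(3),
                               explained_variance_ratio=np.ones(3) / 3,
                               cumulative_variance=np.cumsum(np.ones(3) / 3))
        model = select_cluster_count(emb, seed=42)
        assert model.n_clusters == 3
        cm = confusion_matrix(labels_true, model.labels)
        r, c = linear_sum_assignment(-cm)
        assert cm[r, c].sum() / 600 >= 0.95

    def test_two_tight_blobs_near_ideal_silhouette(self, rng):
        points = np.vstack([
            rng.normal(0, 0.05, (100, 3)),
            rng.normal(0, 0.05, (100, 3)) + 30.0,
        ])
        emb = ReducedEmbedding(T=points, components=np.eye(3),
                               explained_variance_ratio=np.ones(3) / 3,
                               cumulative_variance=np.cumsum(np.ones(3) / 3))
        model = select_cluster_count(emb, seed=42)
        assert model.n_clusters == 2
        assert model.silhouette_by_k[2] > 0.9

    def test_search_covers_two_through_ten(self, rng):
        points = rng.normal(size=(300, 3)) + rng.integers(0, 4, 300)[:, None] * 25
        emb = ReducedEmbedding(T=points, components=np.eye(3),
                               explained_variance_ratio=np.ones(3) / 3,
                               cumulative_variance=np.cumsum(np.ones(3) / 3))
        model = select_cluster_count(emb, seed=42)
        assert set(model.silhouette_by_k) == set(range(2, 11))
        assert model.mixture_weights.sum() == pytest.approx(1.0)


class TestDensityPeak:
    def test_gaussian_kernel_at_zero(self):
        assert gaussian_kernel(0.0) == pytest.approx(1.0 / np.sqrt(2 * np.pi))

    def test_peak_near_mean_of_symmetric_gaussian(self):
        rng = np.random.default_rng(11)
        points = rng.normal(loc=[2.0, -1.0, 0.5], scale=1.0, size=(2000, 3))
        model = find_density_peak(points, seed=42)
        assert np.linalg.norm(model.peak - points.mean(0)) < 0.1

    def test_peak_inside_bounding_box(self):
        rng = np.random.default_rng(12)
        points = np.abs(rng.normal(size=(200, 2))) ** 2  # skewed
        model = find_density_peak(points, seed=42)
        assert (model.peak >= points.min(0) - 1e-12).all()
        assert (model.peak <= points.max(0) + 1e-12).all()

    def test_tiny_cluster_falls_back_to_medoid(self):
        points = np.arange(15.0).reshape(5, 3)
        with pytest.warns(UserWarning, match="medoid"):
            model = find_density_peak(points, seed=42)
        assert model.method == "medoid"
        assert any(np.allclose(model.peak, p) for p in points)

    def test_peak_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(13)
        points = np.vstack([
            rng.normal([0, 0], 0.6, (150, 2)),
            rng.normal([2.5, 1.0], 0.4, (80, 2)),
        ])
        model = find_density_peak(points, seed=42)
        lo, hi = points.min(0), points.max(0)
        step = 0.05 * (hi - lo)
        grid_axes = [np.arange(lo[d], hi[d] + step[d] / 2, step[d]) for d in range(2)]
        grid = np.array([[x, y] for x in grid_axes[0] for y in grid_axes[1]])
        dens = kde_density(grid, points, model.bandwidth)
        best = grid[np.argmax(dens)]
        assert np.all(np.abs(model.peak - best) <= step + 1e-12)


class TestLibrary:
    def _pipeline_pieces(self, proportions, n_frames, seed):
        ens, labels, centers = make_planted_ensemble(
            k=len(proportions), proportions=np.asarray(proportions),
            n_frames=n_frames, seed=seed,
        )
        emb = reduce_dimensionality(flatten_distances(ens))
        clusters = select_cluster_count(emb, seed=42)
        densities = {
            cid: find_density_peak(emb.T[clusters.labels == cid], seed=42)
            for cid in range(clusters.n_clusters)
        }
        return ens, labels, centers, emb, clusters, densities

    def test_weights_and_ordering_follow_populations(self):
        ens, _, _, emb, clusters, densities = self._pipeline_pieces(
            [0.6, 0.3, 0.1], 400, seed=21
        )
        library = build_conformer_library(ens, emb, clusters, densities)
        assert library.weights.sum() == pytest.approx(1.0)
        assert (np.diff(library.weights) <= 1e-12).all()
        sizes = np.bincount(clusters.labels, minlength=clusters.n_clusters)
        assert library.weights[0] == pytest.approx(sizes.max() / ens.n_frames)

    def test_representative_is_exhaustive_argmin(self):
        ens, _, _, emb, clusters, densities = self._pipeline_pieces(
            [0.5, 0.5], 200, seed=22
        )
        library = build_conformer_library(ens, emb, clusters, densities)
        for entry in library.entries:
            members = np.flatnonzero(clusters.labels == entry.cluster_id)
            dists = np.linalg.norm(
                emb.T[members] - densities[entry.cluster_id].peak, axis=1
            )
            assert entry.frame_index == members[np.argmin(dists)]

    def test_single_frame_cluster_is_its_own_representative(self):
        ens, _, _ = make_planted_ensemble(k=2, n_frames=40, seed=23)
        emb = reduce_dimensionality(flatten_distances(ens))
        labels = np.zeros(40, dtype=int)
        labels[7] = 1  # plant a singleton cluster
        from glycokit.conformers.cluster import ClusterModel

        clusters = ClusterModel(
            n_clusters=2, labels=labels, means=np.zeros((2, 3)),
            covariances=np.zeros((2, 3, 3)), mixture_weights=np.array([0.975, 0.025]),
            silhouette_by_k={2: 0.0}, seed=42,
        )
        with pytest.warns(UserWarning, match="medoid"):
            densities = {
                cid: find_density_peak(emb.T[labels == cid], seed=42)
                for cid in (0, 1)
            }
        library = build_conformer_library(ens, emb, clusters, densities)
        singleton = [e for e in library.entries if e.cluster_id == 1][0]
        assert singleton.frame_index == 7

    def test_write_load_round_trip(self, tmp_path):
        ens, _, _, emb, clusters, densities = self._pipeline_pieces(
            [0.7, 0.3], 120, seed=24
        )
        library = build_conformer_library(ens, emb, clusters, densities,
                                          glycan_id="toy")
        library.write(tmp_path / "lib.pdb")
        again = __import__("glycokit.conformers.library", fromlist=["ConformerLibrary"]
                           ).ConformerLibrary.load(tmp_path / "lib.pdb")
        assert len(again) == len(library)
        assert np.allclose(again.weights, library.weights)
        assert again.glycan_id == "toy"


class TestTorsionProfiles:
    def test_identical_frames_have_zero_circular_variance(self):
        glycan = make_toy_glycan()
        ens = ConformationEnsemble(
            frames=np.repeat(glycan.coordinates[None], 5, axis=0),
            template=glycan,
        )
        idx = {a.name: i for i, a in enumerate(glycan.atoms)}
        quartet = (idx["C1"], idx["C2"], idx["N2"], idx["C7"])
        profile = torsion_profiles(ens, [quartet])
        assert np.nanstd(profile.series[0]) < 1e-9

    def test_planted_torsion_value_recovered(self):
        from glycokit.core.geometry import set_dihedral
        from glycokit.core.graph import build_graph

        glycan = make_toy_glycan()
        graph = build_graph(glycan)
        idx = {a.name: i for i, a in enumerate(glycan.atoms)}
        quartet = (idx["C1"], idx["C2"], idx["N2"], idx["C7"])
        set_dihedral(glycan, quartet, graph.rotating_set(*quartet[1:3]), 60.0)
        ens = ConformationEnsemble(frames=glycan.coordinates[None], template=glycan)
        profile = torsion_profiles(ens, [quartet])
        assert profile.series[0, 0] == pytest.approx(60.0, abs=1e-9)

    def test_histogram_counts_sum_to_frames(self):
        ens, labels, _ = make_planted_ensemble(k=2, n_frames=60, seed=25)
        idx = {a.name: i for i, a in enumerate(ens.template.atoms)}
        quartet = (idx["C1"], idx["C2"], idx["N2"], idx["C7"])
        profile = torsion_profiles(ens, [quartet], labels=labels)
        total = sum(h.sum() for h in profile.histograms.values())
        assert total == np.isfinite(profile.series[0]).sum()


def test_end_to_end_recovery_small():
    """Pipeline recovers a planted 2-conformer split at modest n."""
    ens, labels, _ = make_planted_ensemble(
        k=2, proportions=np.array([0.65, 0.35]), n_frames=300, seed=31
    )
    library, _, clusters, _ = run_pipeline(ens, seed=42)
    assert clusters.n_clusters == 2
    assert np.allclose(sorted(library.weights), sorted([0.35, 0.65]), atol=0.05)
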