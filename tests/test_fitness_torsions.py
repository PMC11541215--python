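"""Steric loss, rotatable-torsion detection, attachment and linkage
torsion control."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from glycokit.core.graph import build_graph
from glycokit.core.linkage import wrap_angle
from glycokit.core.model import AtomRecord, MolecularModel
from glycokit.fixtures import make_sequon_protein, make_toy_glycan
from glycokit.graft.attach import AttachmentError, attach_reducing_end
from glycokit.graft.fitness import steric_fitness
from glycokit.graft.torsions import detect_torsion_pairs


def _brute_force_fitness(P, G, threshold=1.7, exclusions=()):
    total = 0.0
    for gi in range(len(G)):
        if gi in exclusions:
            continue
        for pj in range(len(P)):
            d = np.linalg.norm(G[gi] - P[pj])
            if d < threshold:
                total += 200.0 * np.exp(d * d)
    return total


class TestStericFitness:
    def test_coincident_pair_scores_exactly_200(self):
        f, clashes = steric_fitness(np.zeros((1, 3)), np.zeros((1, 3)))
        assert f == 200.0
        assert clashes == [(0, 0, 0.0)]

    def test_pair_at_threshold_contributes_nothing(self):
        # the inequality is strict: exactly 1.7 Å is not a clash
        f, clashes = steric_fitness(np.zeros((1, 3)), np.array([[1.7, 0, 0]]))
        assert f == 0.0
        assert clashes == []

    def test_pair_at_one_angstrom(self):
        f, _ = steric_fitness(np.zeros((1, 3)), np.array([[1.0, 0, 0]]))
        assert f == pytest.approx(200.0 * np.e, rel=1e-12)

    def test_reducing_end_exclusion(self):
        f, clashes = steric_fitness(
            np.zeros((1, 3)), np.array([[0.5, 0, 0]]), exclusions={0}
        )
        assert f == 0.0 and clashes == []

    def test_empty_sets_are_vacuous(self):
        assert steric_fitness(np.zeros((0, 3)), np.zeros((3, 3))) == (0.0, [])
        assert steric_fitness(np.zeros((3, 3)), np.zeros((0, 3))) == (0.0, [])

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(8):
            P = rng.uniform(-4, 4, (int(rng.integers(5, 60)), 3))
            G = rng.uniform(-4, 4, (int(rng.integers(2, 20)), 3))
            excl = {0} if rng.random() < 0.5 else set()
            f, clashes = steric_fitness(P, G, exclusions=excl)
            assert f == pytest.approx(_brute_force_fitness(P, G, exclusions=excl),
                                      rel=1e-12)
            # clash list is consistent with the distance matrix
            d = cdist(G, P)
            expected_pairs = {
                (pj, gi)
                for gi in range(len(G)) if gi not in excl
                for pj in range(len(P)) if d[gi, pj] < 1.7
            }
            assert {(pj, gi) for pj, gi, _ in clashes} == expected_pairs

    def test_positivity_boundary_bisects_to_threshold(self):
        lo, hi = 0.5, 3.0  # clash at lo, free at hi
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            f, _ = steric_fitness(np.zeros((1, 3)), np.array([[mid, 0, 0]]))
            if f > 0:
                lo = mid
            else:
                hi = mid
        assert hi == pytest.approx(1.7, abs=1e-6)


class TestTorsionDetection:
    def test_bare_ring_has_no_rotatable_torsions(self):
        atoms = [
            AtomRecord(serial=i + 1, name=f"C{i+1}", element="C",
                       residue_name="UNK", residue_number=1, chain="A",
                       coordinates=(1.5 * np.cos(np.radians(60 * i)),
                                    1.5 * np.sin(np.radians(60 * i)), 0.0))
            for i in range(6)
        ]
        ring = MolecularModel(atoms=atoms,
                              bonds=[(i, (i + 1) % 6) for i in range(6)])
        assert detect_torsion_pairs(build_graph(ring)) == []

    def test_four_atom_chain_deduplicates_to_one_quartet(self):
        atoms = [
            AtomRecord(serial=i + 1, name=f"C{i+1}", element="C",
                       residue_name="UNK", residue_number=1, chain="A",
                       coordinates=(1.5 * i, 0.6 * (i % 2), 0.0))
            for i in range(4)
        ]
        chain = MolecularModel(atoms=atoms, bonds=[(0, 1), (1, 2), (2, 3)])
        quartets = detect_torsion_pairs(build_graph(chain))
        assert len(quartets) == 1
        assert quartets[0].central_bond == (1, 2)
        assert sorted(quartets[0].atoms) == [0, 1, 2, 3]

    def test_glycosidic_bridge_oxygen_yields_both_linkage_torsions(self):
        """Two rings joined by C-O-C: the bridge O is non-ring degree two and
        must contribute one quartet per bridge bond (the phi/psi pair)."""
        atoms = []
        bonds = []
        for r, (cx, names) in enumerate(
            [(0.0, [f"C{i+1}" for i in range(6)]),
             (6.0, [f"C{i+1}'" for i in range(6)])]
        ):
            for i in range(6):
                atoms.append(AtomRecord(
                    serial=len(atoms) + 1, name=names[i], element="C",
                    residue_name="UNK", residue_number=r + 1, chain="A",
                    coordinates=(cx + 1.5 * np.cos(np.radians(60 * i)),
                                 1.5 * np.sin(np.radians(60 * i)), 0.0)))
            base = 6 * r
            bonds += [(base + i, base + (i + 1) % 6) for i in range(6)]
        atoms.append(AtomRecord(serial=13, name="O1", element="O",
                                residue_name="UNK", residue_number=1, chain="A",
                                coordinates=(3.0, 1.2, 0.5)))
        bonds += [(0, 12), (12, 6)]
        model = MolecularModel(atoms=atoms, bonds=bonds)
        quartets = detect_torsion_pairs(build_graph(model))
        central = {q.central_bond for q in quartets}
        assert central == {(0, 12), (6, 12)}

    def test_toy_glycan_matches_exhaustive_enumeration(self, toy_glycan):
        graph = build_graph(toy_glycan)
        quartets = detect_torsion_pairs(graph)
        # oracle: every non-ring degree-2 atom whose bond partner can extend
        expected_bonds = set()
        for x in graph.nodes:
            if graph.ring_membership[x] or graph.degrees[x] != 2:
                continue
            for near in graph.neighbors(x):
                if any(w != x for w in graph.neighbors(near)):
                    expected_bonds.add((min(x, near), max(x, near)))
        assert {q.central_bond for q in quartets} == expected_bonds
        assert len(quartets) >= 3

    def test_rotating_set_partitions_molecule(self, toy_glycan):
        graph = build_graph(toy_glycan)
        for q in detect_torsion_pairs(graph):
            j, k = q.atoms[1], q.atoms[2]
            assert k in q.rotating_set and j not in q.rotating_set
            complement = set(range(len(toy_glycan.atoms))) - set(q.rotating_set)
            assert j in complement


class TestAttachment:
    def test_bond_length_and_site_atom(self, bare_sequon_protein, n_linkage):
        pose = attach_reducing_end(bare_sequon_protein, "A:2", make_toy_glycan(),
                                   n_linkage)
        nd2 = pose.protein.atoms[pose.c_p]
        assert nd2.name == "ND2"  # N-glycans bond at the Asn amide nitrogen
        c1 = pose.glycan.atoms[pose.b_g]
        assert np.linalg.norm(c1.coordinates - nd2.coordinates) == pytest.approx(
            n_linkage.bond_length, abs=1e-6
        )

    def test_initial_torsions_at_range_midpoints(self, bare_sequon_protein, n_linkage):
        pose = attach_reducing_end(bare_sequon_protein, "A:2", make_toy_glycan(),
                                   n_linkage)
        assert pose.phi == pytest.approx(n_linkage.phi_range.midpoint, abs=1e-6)
        assert wrap_angle(pose.psi - n_linkage.psi_range.midpoint) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_c_mannosylation_bonds_at_trp_indole(self, linkage_table):
        protein = make_sequon_protein("GWG")
        pose = attach_reducing_end(protein, "A:2", make_toy_glycan(),
                                   linkage_table["C-Man"])
        assert pose.protein.atoms[pose.c_p].name == "CD1"

    def test_missing_sidechain_atom_is_actionable(self, n_linkage):
        protein = make_sequon_protein("GNAS")
        keep = [i for i, a in enumerate(protein.atoms)
                if not (a.residue_number == 2 and a.name == "ND2")]
        protein.atoms = [protein.atoms[i] for i in keep]
        with pytest.raises(AttachmentError, match="ND2.*swap"):
            attach_reducing_end(protein, "A:2", make_toy_glycan(), n_linkage)


class TestLinkageTorsions:
    @pytest.fixture()
    def pose(self, bare_sequon_protein, n_linkage):
        return attach_reducing_end(bare_sequon_protein, "A:2", make_toy_glycan(),
                                   n_linkage)

    def test_setting_current_values_is_identity(self, pose):
        before = pose.glycan.coordinates
        pose.set_torsions(phi=pose.phi, psi=pose.psi)
        assert np.abs(pose.glycan.coordinates - before).max() < 1e-9

    def test_requested_angles_are_realized(self, pose):
        pose.set_torsions(phi=60.0, psi=-120.0)
        assert pose.phi == pytest.approx(60.0, abs=1e-6)
        assert pose.psi == pytest.approx(-120.0, abs=1e-6)

    def test_glycan_internal_distances_rigid(self, pose):
        before = pdist(pose.glycan.coordinates)
        pose.set_torsions(phi=45.0, psi=170.0)
        assert np.abs(pdist(pose.glycan.coordinates) - before).max() < 1e-9

    def test_protein_untouched(self, pose, bare_sequon_protein):
        before = bare_sequon_protein.coordinates
        pose.set_torsions(phi=10.0, psi=-10.0)
        assert np.abs(pose.protein.coordinates - before).max() == 0.0

    def test_round_trip_restores_coordinates(self, pose):
        phi0, psi0 = pose.phi, pose.psi
        before = pose.glycan.coordinates
        pose.set_torsions(phi=phi0 + 75.0, psi=psi0 - 40.0)
        pose.set_torsions(phi=phi0, psi=psi0)
        assert np.abs(pose.glycan.coordinates - before).max() < 1e-8
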