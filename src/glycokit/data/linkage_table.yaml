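# Protein-glycan linkage geometry, one entry per supported glycosylation
# chemistry.  Atoms are labelled a-e across the linkage: a, b belong to the
# glycan (ring oxygen and anomeric carbon of the reducing end); c, d, e are
# protein sidechain atoms, given per acceptor residue.  phi is the dihedral
# a-b-c-d, psi is b-c-d-e.  Ranges are degrees in (-180, 180]; an entry
# whose low bound exceeds its high bound wraps through 180 (e.g. [120, -120]
# spans 120 -> 180 -> -120).
#
# Provenance: bond lengths/angles are standard amide / glycosidic ether /
# aryl-C geometry; the N-linked torsion ranges reflect the well-characterized
# beta-GlcNAc-Asn linkage preferences (phi clustered near -97 deg, psi near
# trans).  O-linked ranges are deliberately permissive defaults: published
# per-chemistry ranges vary with the anomeric configuration of the donor, and
# this file is meant to be edited or overridden (--linkage-table) when a
# tighter prior is known.
N-GlcNAc:
  acceptor_residues: [ASN]
  glycan_atoms: {a: O5, b: C1}
  protein_atoms:
    ASN: {c: ND2, d: CG, e: CB}
  phi_range: [-155.0, -55.0]
  psi_range: [120.0, -120.0]
  bond_length: 1.44
  bond_angle: 124.0
O-GalNAc:
  acceptor_residues: [SER, THR]
  glycan_atoms: {a: O5, b: C1}
  protein_atoms:
    SER: {c: OG, d: CB, e: CA}
    THR: {c: OG1, d: CB, e: CA}
  phi_range: [-180.0, 180.0]
  psi_range: [-180.0, 180.0]
  bond_length: 1.43
  bond_angle: 117.0
O-GlcNAc:
  acceptor_residues: [SER, THR]
  glycan_atoms: {a: O5, b: C1}
  protein_atoms:
    SER: {c: OG, d: CB, e: CA}
    THR: {c: OG1, d: CB, e: CA}
  phi_range: [-180.0, 180.0]
  psi_range: [-180.0, 180.0]
  bond_length: 1.43
  bond_angle: 117.0
O-Fuc:
  acceptor_residues: [SER, THR]
  glycan_atoms: {a: O5, b: C1}
  protein_atoms:
    SER: {c: OG, d: CB, e: CA}
    THR: {c: OG1, d: CB, e: CA}
  phi_range: [-180.0, 180.0]
  psi_range: [-180.0, 180.0]
  bond_length: 1.43
  bond_angle: 117.0
O-Man:
  acceptor_residues: [SER, THR]
  glycan_atoms: {a: O5, b: C1}
  protein_atoms:
    SER: {c: OG, d: CB, e: CA}
    THR: {c: OG1, d: CB, e: CA}
  phi_range: [-180.0, 180.0]
  psi_range: [-180.0, 180.0]
  bond_length: 1.43
  bond_angle: 117.0
O-Glc:
  acceptor_residues: [SER, THR]
  glycan_atoms: {a: O5, b: C1}
  protein_atoms:
    SER: {c: OG, d: CB, e: CA}
    THR: {c: OG1, d: CB, e: CA}
  phi_range: [-180.0, 180.0]
  psi_range: [-180.0, 180.0]
  bond_length: 1.43
  bond_angle: 117.0
O-Xyl:
  acceptor_residues: [SER, THR]
  glycan_atoms: {a: O5, b: C1}
  protein_atoms:
    SER: {c: OG, d: CB, e: CA}
    THR: {c: OG1, d: CB, e: CA}
  phi_range: [-180.0, 180.0]
  psi_range: [-180.0, 180.0]
  bond_length: 1.43
  bond_angle: 117.0
C-Man:
  acceptor_residues: [TRP]
  glycan_atoms: {a: O5, b: C1}
  protein_atoms:
    # CD1 is the C2 position of the indole ring in PDB nomenclature
    TRP: {c: CD1, d: CG, e: CB}
  phi_range: [-180.0, 180.0]
  psi_range: [-180.0, 180.0]
  bond_length: 1.52
  bond_angle: 126.0
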