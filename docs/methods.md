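# Methods

## Conformer analysis

The pipeline assumes the input trajectory samples the free glycan's
room-temperature conformational equilibrium exhaustively — typically
several uncorrelated replicas started from the distinct gauche states of
each flexible linkage. Replicas are merged frame-wise after stripping
hydrogens (they carry no conformational signal at this resolution and
triple the atom count); atoms permuted between replicas are re-matched by
their (chain, residue, insertion code, name) identity, so pairwise
distances are unaffected.

Each frame is described by the condensed vector of all heavy-atom pairwise
distances (lower triangle of the distance matrix, column-major — SciPy's
condensed order). Internal distances are blind to rigid-body motion, which
is why the pipeline needs, and performs, no superposition; this invariance
is asserted to 1e-9 Å in the tests. PCA reduces the frames × distances
matrix to three components. Three is a deliberate operating point: the
mixture model and silhouette degrade as dimensions grow and points spread
apart, and the explained-variance curve is retained in the output for
judging how much structure the projection keeps (0.99 cumulative on the
synthetic ensembles).

Clustering uses a full-covariance Gaussian mixture (fixed random state 42
for reproducibility) for every k from 2 to 10; the k with the highest
silhouette score on the 3-D embedding wins, with ties within 1e-6 broken
toward the smaller k. Silhouette is O(F²), so above 50 000 frames a seeded
subsample of 50 000 is scored (and logged). A k whose EM fit fails or
collapses to one occupied component is skipped with a warning.

The representative of a cluster is the *sampled frame* nearest the
cluster's density peak, not the centroid: skewed or curved clusters have
centroids in regions the molecule never visits. The density is an
isotropic Gaussian KDE, p̂(x) = (1/nh) Σ K(‖x − xᵢ‖/h) with
K(u) = exp(−u²/2)/√(2π). The bandwidth grid for five-fold cross-validation
is 20 log-spaced values spanning 0.1–10× the Scott's-rule plug-in estimate
(brackets the plug-in symmetrically); the CV loss is negative mean held-out
log-density, which the scheme "minimize validation error" leaves open. The
peak is the box-bounded (per-dimension min/max of the cluster) L-BFGS-B
minimizer of −p̂, restarted from the 8 highest-density training points.
Clusters under 10 points fall back to their medoid — cross-validated
bandwidth selection is meaningless at that size. Whether the KDE should
live in embedding space or the full distance space is genuinely open; the
embedding was chosen because that is where the clusters are defined.

Library weights are cluster frame counts over total frames; entries are
ordered by descending weight (ties toward the smaller cluster id), so
entry 0 is the dominant solution conformer. Each entry keeps its source
frame and replica index for provenance. Torsion profiles use 5° circular
histograms and vector (circular) means.

## Steric grafting

The loss `F = Σ_{D<1.7 Å} 200·exp(D²)` counts protein–glycan atom pairs
strictly inside the carbon van der Waals radius; the reducing-end anomeric
carbon is excluded because it is covalently bonded to the sidechain by
construction. `F = 0` is the success criterion everywhere — "unresolvable
clashes" means `F > 0` after the wiggle phase. No energy model beyond this
steric term is used or intended.

Attachment places the anomeric carbon at the configured bond length and
angle from the sidechain atom (editable linkage table,
`glycokit/data/linkage_table.yaml`: atoms a–e, torsion ranges, bond
geometry per chemistry), removes an anomeric hydroxyl if present, and
starts both linkage torsions at their range midpoints. The glycan moves as
a rigid body; rotating about the b–c and c–d axes changes φ and ψ exactly
and independently, and protein atoms never move. Where a range is not
well characterized (most O-linked chemistries) the shipped table is
deliberately permissive; the well-studied β-GlcNAc–Asn linkage gets an
informative φ window around −97°, ψ near trans.

The genetic algorithm is specified by its published skeleton — population
128, eight generations, lowest-fitness half as parents, "crossover and
mutation (0.2)" — and this implementation fills the unstated operators in
the simplest way consistent with a two-gene genome: gene-wise uniform
crossover, per-gene mutation probability 0.2 resampling uniformly within
the gene's range, children replacing the bottom half wholesale, and the
best individual always surviving. Generation 0 is the randomly initialized
population, so at most eight populations are ever evaluated. Because the
loss cannot go below zero, the search exits early on a zero-loss
individual — a pure speed optimization that cannot change the success set.

Rotatable torsions are found on the molecular graph (networkx): ring atoms
are flagged by cycle detection, and every non-ring atom with exactly two
bonds contributes a torsion quartet through each of its bonds (so a
glycosidic bridge oxygen yields both linkage torsions); quartets sharing a
central bond are deduplicated. Bonds come from CONECT records when present
and from covalent-radius distance perception ((r₁+r₂)×1.3) otherwise —
one rule for all atoms, since the idealized geometries the package is
validated on make distance perception exact.

The wiggle phase perturbs *all* rotatable torsions (detected quartets plus
linkage φ/ψ) each iteration with independent uniform draws; "within a
range of 10°" is read as half-width, i.e. moves in [−10°, +10°], with a
full-width mode selectable. The best pose is kept across at most 40
iterations, stopping early at zero loss.

Conformers are tried strictly in descending-weight order; the first
zero-loss GA result wins, otherwise the lowest-loss conformer goes to the
wiggle. During multi-site grafting, sites are processed in residue order
and previously placed glycans join the protein atom set for later sites
(toggleable), preventing glycan–glycan overlap. One master seed fans out
deterministic per-site and per-cluster sub-streams, so whole-protein runs
are reproducible bit-for-bit.

## Scanning, swap, ensembles, SASA

Occupancy scanning applies the full grafting protocol with a single
GlcNAc probe at every N-X-S/T sequon (literal rule by default; the
conventional X ≠ Pro refinement is a flag, since biological sequons
exclude proline but the structural accessibility question does not).
Each sequon is probed against the bare protein: a one-monosaccharide probe
at another sequon should not change accessibility. Numbering gaps at chain
breaks cannot create spurious motifs, terminal partial motifs are not
sequons, and author numbering (including offsets and insertion codes) is
reported verbatim. The OD1/ND2 swap exchanges the two amide coordinates of
an Asn — crystallography cannot distinguish them, and a wrong assignment
manifests as a false-negative scan that the swap flips.

Ensemble fitting draws 200 frames per repeat (without replacement within a
repeat; with replacement plus a warning if the trajectory is shorter),
five repeats per site, attaches each with uniform (φ, ψ) from the linkage
ranges, and accepts a frame iff no clash-counted glycan atom is strictly
within 1.7 Å of a protein atom.

SASA is computed natively by Shrake–Rupley dot sampling with
Fibonacci-lattice spheres; the radii table (Bondi-style) ships as an
overridable dict and unknown elements are refused by name. The headline
parameter "probe diameter 0.14 nm" collides with the conventional water
probe *radius* of 0.14 nm; the default reads it as a radius, and a
literal-diameter mode exists. Results are nm² (coordinates are Å
internally; the unit conversion happens only at this boundary). Glycan
occlusion is reported as ΔSASA = SASA(protein alone) − mean over accepted
models of the protein-part SASA within the complex.

## Synthetic fixtures

All test inputs are pure functions of (parameters, seed). The toy glycan
is an idealized GlcNAc-like monosaccharide (planar ring, internal-
coordinate substituents, no force field) chosen so torsion detection finds
at least three rotatable quartets and attachment finds the O5/C1 linkage
atoms. Planted ensembles set three rotatable torsions to cluster centers
plus Gaussian noise (default spread 8°, centers > 6× spread apart), giving
ground-truth labels for recovery tests. Pocket fixtures cage the sequon in
concentric carbon dot-spheres starting at the clearance radius; since
neither linkage torsion changes a glycan atom's distance to the attachment
atom, feasibility is analytic — clear iff clearance exceeds the probe's
radial extent (≈ 6.0 Å) plus 1.7 Å — and monotone in clearance. A windowed
variant opens a cone in the cage for optimizer benchmarks whose feasible
torsion region a grid search can map exactly, and a blocked-amide variant
opens the cage only toward the OD1 direction to manufacture the
false-negative the swap tool exists for.

What these fixtures do *not* emulate: real sidechain rotamer
distributions, backbone flexibility, solvent, or chemically accurate sugar
geometry. Passing tests therefore demonstrate the correctness of the
algorithms (loss accounting, search contracts, recovery of planted
structure), not predictive accuracy on experimental structures.

## Problem sizes and numerical choices

Default validation sizes — 1 000 frames × 14 heavy atoms for conformer
recovery, pockets of a few thousand pseudo-atoms, 100-seed success-rate
checks — were chosen as the smallest at which the statistical contracts
are sharp. Dihedrals follow the IUPAC signed convention on (−180, 180];
torsion ranges may wrap through 180° (encoded lo > hi). Angle collinearity
raises rather than returning a garbage dihedral; a frame with degenerate
geometry records a missing torsion value instead of failing the profile.
PDB output renumbers atom serials from 1 but never touches author residue
numbering; files over 99 999 atoms are refused rather than silently
wrapped. Glycan residue names use PDB Chemical Component Dictionary codes
(NAG, MAN, …); GLYCAM naming, mmCIF, hydrogen placement and force-field
assignment are out of scope.

## Known limitations

* The steric loss is the only energy term: no electrostatics, hydrogen
  bonding, or torsional strain; a clash-free pose is necessary, not
  sufficient, for a physically favorable glycoform.
* The protein is rigid by design; genuinely occluded sites that a small
  backbone or rotamer adjustment would open are reported as "no".
* The shipped O-linked torsion ranges are permissive placeholders; tighten
  them from linkage surveys for production O-glycosylation work.
* KDE bandwidth selection assumes clusters of at least ~10 points;
  smaller clusters silently degrade to medoid representatives (with a
  warning).
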