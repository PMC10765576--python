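# Methods

This note documents the models and procedures implemented in `plbap`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## Complex model and conventions

A complex is a protein and a ligand, each an ordered atom list with
coordinates in ångström plus covalent bonds stored once per pair.  Global
conventions, applied uniformly:

* **Half-open shells.** Every distance interval is `(low, high]`: a pair at
  exactly the upper boundary belongs to the lower shell.  Binding-site
  cropping keeps protein atoms at distance `≤ cutoff` from any ligand atom.
* **0-based indices, no unit conversion.** Coordinates stay in Å throughout.
* **Hydrogens are kept.** The default 8-letter contact alphabet contains H;
  schemes that ignore hydrogens can strip them upstream.
* **Waters and ions.** PDB waters are dropped (count logged); other HETATM
  groups count as protein atoms.
* **Protein bonds.** PDB files rarely carry protein CONECT records, and no
  canonical perception rule exists for this representation family; bonds are
  taken from CONECT when present, otherwise inferred by an element-dependent
  distance rule (heavy–heavy < 1.8 Å, X–H < 1.2 Å, no H–H bonds).
* **Van der Waals radii** come from a fixed built-in Bondi/Alvarez-style
  element table (`VDW_RADII`); unknown elements fall back to 1.70 Å with a
  logged warning.  The fixture property ruleset can override any radius.
* **Atom typing** is total by construction: element-table lookup, halogens
  to `HAX` where the alphabet has one, everything else to the catch-all
  (`Du` / `other`).

File I/O uses Biopython for PDB parsing, RDKit for SDF/MOL2, and
fixed-column writers for the fixture round-trips.  The "fixture" property
ruleset accepts a per-atom table verbatim so no test depends on an external
perception toolkit; the default "heuristic" ruleset derives pharmacophore
flags from elements and bonds with deliberately simple rules (donors are
N/O/S bonded to H, acceptors N/O/F, aromaticity = a cycle of aromatic
bonds, and so on).  These heuristics are coarse approximations of
SMARTS-based perception, adequate for exercising featurization arithmetic
but not for production pharmacophore assignment.

## Atomic-environment tensors

`build_atom_env_tensor` finds the M nearest neighbors of each atom
(unrestricted by the pooling cutoff — the kernel's hard cutoff handles
range), scatters neighbor distances into the channel of the neighbor's type,
and records the neighbor indices.  Ties in neighbor distance are broken by
ascending atom index for determinism.  Structures with fewer than M+1 atoms
leave trailing slots all-zero; a single-atom input yields an all-zero tensor
with a warning.

The radial pooling kernel
`f_q(x) = ½·exp(−(x−r_q)²/σ_q²)·(cos(πx/R_c)+1)` is defined on the open
interval `0 < x < R_c` and zero elsewhere, so zero tensor entries (missing
neighbors, other-type channels, or exactly coincident atoms) contribute
nothing.  Each `f_q` value lies in [0, 1]; a pooled entry is therefore
bounded by the number of same-type neighbors inside the cutoff.  Defaults
follow the published reference settings: σ_q² = 2.5 Å², R_c = 12 Å, centers
on an even grid strictly below R_c (spacing 4 Å gives {0,4,8}; spacing 2 Å
gives six filters).  The filter bank is fixed here; learnable centers are
left to the pluggable training backend.

The thermodynamic-cycle head featurizes complex, protein-alone and
ligand-alone with one shared scheme and bank, maps each pooled row through a
shared dense stack to an atomic energy, and returns
ΔG = E_complex − E_protein − E_ligand.

## Intermolecular contacts

Pair types are the row-major crossing of the protein and ligand alphabets
(protein-major), fixed and documented so matrices are comparable across
runs.  The default shell scheme is (0,1] followed by 59 shells of 0.5 Å; the
edges end at 30.5 Å.  (The span is often summarized as "0 to 30 Å"; the
constructor follows the interval definition rather than that round number.)

Counting pre-filters protein atoms farther than the outermost shell edge
from every ligand atom; the result is provably identical to the naive double
loop, which the tests assert.  The contact profile's mean distance for an
empty cell is defined as 0 — the mean of zero distances is otherwise
undefined — and tests check that occupied-cell means always lie inside their
shell.

## Voxel grids

The grid is a cubic lattice of side X centered on the unweighted ligand
centroid, with `G = round(X/r) + 1` lattice points per axis (a 20 Å grid at
1 Å resolution has 21³ points).  Some tools count r-sized *cells* instead of
lattice points; `cells_mode` reproduces that convention (24 Å at 1 Å → 24).

Two filling strategies:

* **contribution** — every atom adds `(1 − exp(−(r_vdw/d)^12))·p` to every
  voxel.  The weight is undefined at d = 0 and is assigned its limiting
  value 1.  At d = 4·r_vdw the weight is ~6e−8, so atoms outside the extent
  need no special handling.
* **aggregate** — each atom's property vector is summed into its nearest
  lattice point; exact midpoints resolve to the lower index, atoms outside
  the extent are ignored.

Default channels are the 8 pharmacophore/occupancy properties per role
(`excluded_volume` counts 1 per atom); the two-grid layout stacks protein
then ligand channels (16 total).  No Gaussian blurring or other kernels are
applied.

Grids ride on the ligand center, hence translation invariance.  They are not
rotation invariant; right-angle augmentation fills the grid after rotating
coordinates about the center by elements of the cube rotation group (4
z-quarter-turns by default, or all 24), represented as exact signed
permutation matrices so that rotation equivariance is an index permutation.

Numerical note: recomputing the ligand centroid of a translated complex
rounds in the last bits, and rotating coordinates permutes the summation
order inside distance computations.  Aggregate grids are still bit-identical
(assignments flip only at exact cell midpoints, a measure-zero event);
contribution grids are compared at 1e−9 (translation) and 1e−12 (rotation)
rather than bitwise.

## Binding-site graphs

Nodes are all ligand atoms plus protein atoms within the crop cutoff, padded
to N_max.  The canonical order — ligand atoms by distance from the ligand
centroid, then protein atoms by minimum distance to the ligand, ties by
original index — makes the padded graph reproducible and maps any reindexing
of the input atoms to the same graph (generic coordinates have no ties).
If the crop exceeds N_max the farthest protein atoms are dropped
deterministically; a ligand alone exceeding N_max is an error.  The default
node-feature list has 18 columns: 9 element one-hots, partial charge,
heavy/hetero neighbor counts, 5 pharmacophore flags, and a ±1
protein/ligand sign.

Adjacency tensors are symmetric per slice with zero diagonals; self-loops
are *not* stored — the propagation rule adds the identity (Ã = A + I) at
compute time.  Variants:

* equal-width shells over (0, 4] Å (the 4 Å span is kept fixed regardless
  of the crop cutoff, as published);
* covalent slice + strict `d < t_k` noncovalent slices excluding bonded
  pairs;
* distance-valued over the fixed shells (0, 1.5] and (1.5, 4.5];
* Gaussian: 1 for covalent pairs, `exp(−(d−μ)²/σ)` for noncovalent pairs
  within a cutoff (5 Å default).  No published values exist for μ and σ;
  they default to μ = 0 Å, σ = 1 Å² and are explicit configuration — note a
  noncovalent pair at exactly d = μ also reaches weight 1.

## Reference network computations

The atomistic head, thermodynamic delta, spectral GCN propagation
(`H′ = act(D^{−1/2}(A+I)D^{−1/2} H Θ)`) and a generic message-passing step
with sum/mean readout are implemented as backend-free deterministic
numerics and run in inference mode (no dropout).  Padded nodes get degree 1
from the self-loop and propagate zero rows.  The published layer/filter
counts of the four reference architectures are kept as declarative configs
only (including the between-block aggregator for the GCN reference, which
its source leaves unstated; sum is the configurable default).  Training is
behind a thin `fit(features, labels, config, seed)` interface backed by
scikit-learn (ridge regression or a small MLP) — a learnability hook, not a
benchmark trainer.  The composite correlation+error loss is implemented as
`α·(1−PC) + β·RMSE` with configurable weights, since only its ingredients
are published.

## Evaluation

* **Masking importance** stores the signed published deltas
  (ΔPC = PC_i − PC_0, ΔRMSE = RMSE_i − RMSE_0) and a convenience
  `pc_drop = PC_0 − PC_i` column for heatmaps.  If masking silences the
  model entirely (constant predictions), PC_i is recorded as 0 — the
  maximal drop — rather than raising.
* **Enrichment factors** are computed in two conventions, because the
  verbal definition ("proportion of actives in the top X%") reads as a
  precision yet reported magnitudes of 10–20 require base-rate
  normalization; `normalized` (precision / base rate) is the default.
  Ranking ties are broken by id for reproducibility.  `enrichment_sweep`
  draws decoy subsets without replacement at fixed decoy-to-active ratios
  and averages EF over repeats, fully seeded.

## Synthetic data: what it shows and what it does not

`generate_complex` places ligand atoms uniformly in a ball (default 24
atoms, 4 Å radius) and protein atoms uniformly in a shell (default 120
atoms, 2–12 Å), samples elements from organic frequency tables, and bonds
the ligand with a random spanning tree plus extra edges.  Affinity labels
are planted as `intercept + ⟨weights, contact counts⟩ + N(0, σ²)` — the
contact representation is the cheapest to recompute exactly, so the planted
signal lives there; grid and graph pipelines are validated by invariants
and brute-force oracles instead.  All randomness flows through explicit
seeds; there is no global random state.

Passing tests on these fixtures demonstrate that the featurization
arithmetic, symmetry properties, masking bookkeeping and enrichment
statistics are correct.  They do **not** demonstrate predictive performance
on crystal structures: the fixtures have no real chemistry (no valence
rules, no conformers, no binding physics), and full-scale training on
curated affinity benchmarks is out of scope.

## Problem sizes in the validation suites

The test and acceptance runs use deliberately compact inputs chosen to
exercise every code path densely: 50 complexes × 20 rigid motions (10+30
atoms each) for the symmetry suite, 30-atom fixtures for brute-force
oracles, 5 × 300 complexes at default size for planted-signal recovery, and
100 fresh screening fixtures (20 actives + 400 decoys) for enrichment
sanity.  The planted-recovery criterion checks that all k planted cells
rank within the top 2k by ΔRMSE — they in fact rank top-k in every seed
tried.

## Known limitations

* Pharmacophore perception is heuristic, not SMARTS-based; partial charges
  default to 0 unless supplied via the fixture ruleset.
* Protein bond inference is a distance rule; unusual bond lengths
  (organometallics, distorted geometries) will be missed or over-connected.
* The aggregate-grid tie rule (lower index at exact midpoints) breaks exact
  permutation symmetry only for atoms duplicated at the same midpoint
  coordinate — a case that cannot arise from the generator.
* MOL2 is read but not written; fixture round-trips use PDB + SDF.
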