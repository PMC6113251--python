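# Methods

This note documents the models and algorithms `allodyn` implements, the
assumptions they make, the defaults and why, and what the synthetic-data
generator does and does not emulate.

## Scope and data model

The package analyzes a coordinate trajectory (F frames × N atoms × 3, Å)
over a fixed topology of a protein or two-chain protein complex. It does
not run dynamics: trajectories come from an MD engine (DCD/XYZ/multi-model
PDB) or from the built-in statistical generator. Indices are 0-based
internally; the file-facing residue number is preserved verbatim so PDB
round-trips are lossless. Per-atom parameters (mass, vdW radius, charge,
LJ well depth) default to a built-in element table (Bondi radii) and can be
overridden from a whitespace-delimited per-atom table — radius-sensitive
results (SASA, nonpolar solvation) therefore never depend on a hard-coded
table the user cannot change.

## Superposition and alignment

Rigid-body motion is removed by Kabsch least-squares superposition (SVD
with a determinant correction, proper rotations only). Selections of fewer
than three atoms, or collinear ones, leave the rotation underdetermined and
are rejected rather than resolved arbitrarily. Superposition is unweighted
by default (fluctuation analyses here operate on Cα atoms, all carbons);
mass weighting is available via an argument.

The fluctuation/covariance reference is the *iteratively refined average
structure*: all frames are repeatedly fitted to the running mean until no
frame moves by more than 1e-9 Å RMSD in a round (≤ 50 rounds). The
iteration starts from the mean of the input frames, falling back to a
first-frame prefit only if that raw mean is degenerate. Starting from the
input mean makes an already-aligned trajectory an exact fixed point, so
alignment is idempotent to machine precision — a property a
first-frame-seeded loop cannot provide, because the prefit re-rotates
already-converged frames. A plain first-frame mode is kept for diagnostics.
Alignment applies only rigid transforms per frame, so all intra-frame
internal distances are preserved exactly.

## Fluctuations, distances, SASA

**RMSF** of atom i over a frame window is √⟨|r_i(t) − ⟨r_i⟩|²⟩ with ⟨r_i⟩
the window-mean position of the aligned trajectory. Windows are always
explicit `[a, b)` frame ranges (or named trailing fractions in the CLI);
nothing is inferred from nominal simulation time.

**Distances** are per-frame Euclidean separations between two atoms or
mass-weighted group centroids.

**SASA** uses the Shrake–Rupley construction: each atom's probe-expanded
sphere (probe 1.4 Å by default) is sampled with a deterministic
Fibonacci-spiral point set (960 points by default; no random seeds), and a
point is exposed iff strictly outside every other atom's expanded sphere.
Ties — including exactly coincident duplicate atoms — count as buried, a
conservative, deterministic convention (a small relative tolerance absorbs
floating-point rounding on exact ties). Selection SASA is computed in the
context of *all* atoms, so non-selected atoms occlude. Neighbor search is
brute force below 200 atoms and KD-tree-based above. At 960 points the
isolated-sphere error is < 0.5 % and 20-atom clusters agree with a
4000-point evaluation within 2 %.

## Cross-correlation and PCA

The dynamic cross-correlation matrix is

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨Δr_i · Δr_i⟩ ⟨Δr_j · Δr_j⟩)

with Δr_i the 3-vector displacement from the window-mean position and ⟨·⟩
the population mean over the window (normalization by F, not F−1: the
population form matches the ensemble-average notation and the difference is
immaterial at trajectory scale). The numerator is the full 3-D dot product,
not a per-axis average. The caller is responsible for removing rigid-body
motion first (`align_trajectory`). A zero-variance atom is an error, not a
silent C = 0: a frozen coordinate almost always indicates an upstream bug.

PCA eigendecomposes the 3N × 3N covariance of the concatenated Cartesian
coordinates. Eigenvalues are sorted descending with stable tie-breaking;
each eigenvector's sign is fixed so its largest-magnitude coefficient is
positive, making projections and plots reproducible. The information
content of component n is I_n = λ_n / Σλ over all 3N eigenvalues.
Projections are centered frame coordinates dotted onto the leading
eigenvectors. Conformer densities are normalized 2-D histograms of two
components' scores; the occupied area counts bins holding more than one
frame's worth of probability mass (> 1/F) times the bin area. Occupied
areas are comparable between runs only on a common grid, and the measure
grows sub-quadratically with fluctuation amplitude because the peak density
drops as the distribution spreads.

## Residue networks and communities

Nodes are residues, represented by one marker atom each (Cα by default,
matching the convention that each Cα is a node; a heavy-atom contact mode
exists because some network toolchains use it, but Cα is the default). Two
*nonconsecutive* residues are in contact in a frame if their marker atoms
are within the cutoff (4.5 Å default, inclusive); the occupancy is the
fraction of window frames in contact, and an edge exists iff occupancy ≥
the threshold (0.75 default, inclusive). Consecutive residues of one chain
are always excluded — they are covalently tethered and carry no contact
information; consecutive *numbering* across a chain boundary is not
excluded.

Edge weights are w_ij = −log|C_ij|, so strong correlation means a short
edge in the information-transfer sense. |C| below 1e-6 is capped at
−log(1e-6) with a logged warning rather than dropped: an infinite weight
would silently delete topology.

All-pairs shortest paths use Floyd–Warshall (SciPy's implementation, with
predecessor recovery); the critical path length (CPL) is the mean of the
finite off-diagonal path lengths, with unreachable pairs counted and
reported separately. Suboptimal paths between a chosen source and sink are
enumerated by bounded depth-first search pruned with exact
remaining-distance bounds, capped at 1e5 paths with an explicit truncation
flag.

Community detection is Girvan–Newman: repeatedly remove the edge of
highest betweenness (betweenness computed on the weighted graph with w as
length, recomputed after every removal) and return the partition in the
removal sequence maximizing Newman–Girvan modularity Q. Q is computed on
the unweighted edge set by default (the classical formulation; a weighted-Q
flag exists for sensitivity analysis). Determinism is guaranteed by two tie
rules: among equal-betweenness edges the lexicographically smallest (i, j)
is removed, and among equal-Q partitions the earliest in the sequence wins.
Communities whose members span both chains are reported as interface
communities — the observable that distinguishes cross-interface allosteric
coupling from chain-local dynamics.

## Single-trajectory MM-GBSA

The binding free energy of a complex is estimated from one trajectory of
the whole complex by decomposing receptor and ligand frames out of the same
coordinates:

    G_TOT  = H_MM + G_solv − TΔS_conf
    ΔG_bind = G_TOT(complex) − [G_TOT(receptor) + G_TOT(ligand)]

applied termwise. Because all three subsets share the same frames, every
intra-subset bonded term appears identically in the complex and in its
fragment and cancels exactly: the bonded contribution to ΔG_bind is
machine zero, which the tests assert exactly. Likewise ΔE_elec + ΔE_vdw
equals the receptor–ligand inter-fragment interaction energy exactly.

Two input routes exist. The *table* route aggregates per-frame term tables
(`frame E_bonded E_elec E_vdw G_polar G_np`) written by an MD engine — the
format-stable path, since production GBSA terms are engine-specific. The
*computed* route is a self-contained desk-scale evaluator for toy/synthetic
systems: Coulomb 332.0636·q_iq_j/r (kcal/mol, Å, e), Lennard-Jones 12-6
from per-atom (Rmin/2, ε) with Lorentz–Berthelot combining, no cutoff;
Still-type generalized Born

    ΔG_GB = −(1/2)(1 − 1/ε_w) · 332.0636 · Σ_ij q_i q_j / f_GB,
    f_GB = sqrt(r_ij² + a_i a_j exp(−r_ij² / 4 a_i a_j)),

self-terms included, solvent dielectric 78.5; and nonpolar solvation
γ·SASA + b with γ = 0.00542 kcal/mol/Å², b = 0.92 kcal/mol. Born radii are
an input (default: vdW radius − 0.09 Å); full pairwise-descreening radius
calculation is out of scope. Each subset's SASA treats the subset as an
isolated molecule, consistent with the decomposition.

Uncertainties: the ± on every Δ term is the standard deviation (ddof 1) of
the per-frame Δ series. Quadrature over the three subsets' standard
deviations would be wrong here — in the single-trajectory scheme the
subsets are evaluated on identical frames and are perfectly correlated, so
common-mode fluctuations must cancel in the difference before the spread is
measured.

The entropy term is off by default (ΔG_bind = ΔH_MM + ΔG_solv), reflecting
common practice for protein–protein estimates where normal-mode entropy is
prohibitively expensive; when requested, a precomputed TΔS_conf is
subtracted.

## Quasi-harmonic configurational entropy

Eigenvalues σ_k² (amu·Å²) of the mass-weighted covariance of the aligned
coordinates define quasi-harmonic frequencies ω_k = sqrt(k_B T / σ_k²).
Each mode contributes the quantum harmonic-oscillator entropy

    S_k / k_B = α/(e^α − 1) − ln(1 − e^{−α}),   α = ħω_k / k_B T,

(the Andricioaei–Karplus estimator; the Schlitter upper-bound formula
S_k/k_B = ½ ln(1 + e²/α²) is available behind a flag and always bounds the
former from above). The six smallest-eigenvalue modes — residual rigid-body
motion after alignment — are excluded by default (`n_exclude`, settable to
0 for fully internal toy systems). Static modes contribute zero (the stiff
limit). T defaults to 298 K. A warning is emitted when the window has fewer
than 3N frames (rank-deficient covariance). Entropy is invariant under
rigid rotation of the whole trajectory and additive over blocks whose
sample cross-covariance vanishes.

## Synthetic data: what it emulates, and what it does not

The generator produces a Cα-level one- or two-chain complex with:

- **Planted correlation**: residues are grouped into blocks with a common
  within-block correlation and a global between-block correlation; the
  implied matrix is validated positive semi-definite (violations are
  rejected, naming the infeasible block pair). Displacements are drawn from
  a symmetric factor of D R D (amplitudes × correlation), independently per
  Cartesian axis — isotropy per residue makes the analytic C_ij equal the
  planted scalar correlation under the 3-D dot-product definition, keeping
  the oracle closed-form. Default per-axis amplitude is 0.5 Å for block
  residues and 0.3 Å otherwise, typical of Cα fluctuations in folded
  proteins at ambient temperature.
- **Scripted contacts**: designated residue pairs switch between a contact
  distance (4.0 Å) and an apart distance (9.0 Å) on a deterministic
  schedule (the first round(p·F) frames), so occupancy thresholds are
  exactly testable at boundary values such as 0.74/0.75/0.76. Scripted
  residues carry only a small perpendicular jitter (0.01 Å) so no atom is
  perfectly frozen; they may not belong to covariance blocks.
- **Geometry**: a gentle 3-D helix with 3.8 Å Cα spacing (consecutive
  residues bonded-neighbor-like, nonconsecutive ones well separated), or a
  "clustered" layout in which each block is a compact serpentine-ordered
  grid (3.0 Å cells, so face and face-diagonal neighbors are contacts and
  each block's contact graph is connected after the consecutive-pair
  exclusion) with 3.6 Å gaps between clusters, giving a few bridge contacts
  between adjacent blocks — the between-community edges Girvan–Newman must
  cut.
- **Energy tables**: receptor/ligand baselines plus a per-frame difference
  series with planted mean and standard deviation per term; bonded columns
  are constructed from exactly representable constants so the bonded
  difference cancels to machine zero, as the single-trajectory scheme
  guarantees.

Everything is seeded; the same spec and seed give byte-identical
trajectories and tables.

The generator emulates the *statistical* structure the analyses assume —
not physics. It has no force field, no integrator, no solvent, no realistic
excluded volume (clustered blocks are denser than real Cα packing), no
anisotropic or time-correlated fluctuations, and its contacts are scripted
rather than emergent. Passing tests therefore demonstrate that the
estimators recover planted statistical structure correctly at realistic
sample sizes; they say nothing about force-field accuracy or sampling
adequacy of any real simulation.

## Problem sizes and numerical choices

The test suite and the acceptance script run on desk-scale problems chosen
to make sampling error small relative to the tested tolerances: 60 residues
× 5000 frames for correlation recovery (elementwise error ≲ 0.03 against
the analytic matrix), 60 residues × 2000 frames for community recovery
(exact planted-partition recovery, ARI = 1), 20 random 30-node graphs for
the path-algorithm cross-check, and 10⁴–10⁵ frames for scalar
distributional checks. Other fixed choices: Coulomb constant 332.0636
kcal·Å/(mol·e²) stated once and used everywhere; eigenvalue clipping at
zero for numerically tiny negative covariance eigenvalues; correlation
floor 1e-6 for edge weights; SASA tie tolerance 1e-9 relative. All output
writers use fixed numeric formats and sorted keys, so a rerun with the same
config and seed is byte-identical.

## Known limitations

- Girvan–Newman with full betweenness recomputation is O(E²·V)-ish and
  intended for networks of a few hundred nodes; no stochastic community
  methods are provided, by design.
- The desk-scale energy evaluator has no cutoffs, periodicity, or
  descreening-based Born radii; it is for synthetic/toy systems and
  cross-checks, not production energetics.
- On short windows or small blocks, maximum-modularity partitions of noisy
  sample-correlation networks can attach boundary residues to a neighboring
  community; this is inherent to modularity optimization, not a defect of
  the implementation (the planted partition is recovered exactly at the
  documented problem sizes).
- PDB support covers fixed-column v3 ATOM/HETATM/TER/MODEL/ENDMDL records;
  no insertion codes, altlocs, or mmCIF.
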