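# allodyn

Trajectory analysis for detecting allosteric changes in two-chain protein
complexes — the kind of question raised by phosphorylation of a Ras-family
GTPase (e.g. Rap1A bound to the Ras-binding domain of Raf): does a local
perturbation change the complex's correlated motions, its residue
communication network, and its binding free energy?

`allodyn` implements the complete analysis chain that molecular-dynamics
studies of such systems use, as a tested, reusable library with a CLI:

- **Trajectory handling** — PDB / DCD (CHARMM-NAMD) / XYZ I/O, an atom
  selection mini-language, Kabsch superposition, and iterative-average
  alignment.
- **Observables** — per-residue RMSF, atom/centroid distance time series,
  and Shrake–Rupley solvent-accessible surface area (probe 1.4 Å,
  deterministic Fibonacci-spiral point sets).
- **Correlated motions** — the dynamic cross-correlation matrix
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) over displacements from the mean
  structure, and Cartesian PCA with per-component information content
  I_n = λ_n / Σλ and conformer-density maps.
- **Residue networks** — nodes are Cα atoms; edges join nonconsecutive
  residues within 4.5 Å for ≥ 75 % of frames, weighted w_ij = −log|C_ij|;
  Floyd–Warshall all-pairs paths and the critical path length (CPL);
  suboptimal-path enumeration; Girvan–Newman community detection with
  maximum-modularity partition selection and interface-spanning community
  reporting.
- **Energetics** — single-trajectory MM-GBSA:
  ΔG_bind = G(complex) − G(receptor) − G(ligand) with
  G = H_MM + G_solv (− TΔS_conf), evaluated either from per-frame energy
  tables produced by an MD engine or from a built-in desk-scale evaluator
  (Coulomb, Lennard-Jones 12-6, Still-type generalized Born, γ·SASA + b);
  quasi-harmonic configurational entropy from the mass-weighted covariance.
- **Synthetic data** — a generator that plants known covariance blocks,
  contact occupancies, interface communities, and energy differences, so
  every stage is testable against analytic ground truth without external
  trajectories.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

Compare two synthetic 30-residue, two-chain complexes: one whose correlated
blocks are confined to single chains, and one with a block spanning the
R–L interface (the signature of cross-interface allosteric coupling).

```bash
allodyn run demo/config.yaml
```

with `demo/config.yaml`:

```yaml
output_dir: demo_out
seed: 7
window: last-half
node_selection: "name CA"
conditions:
  - label: chain-local
    synthetic:
      chains: {R: 15, L: 15}
      n_frames: 1000
      geometry: clustered
      blocks:
        - {members: [0,1,2,3,4,5,6,7,8,9,10,11,12,13,14], within: 0.85}
        - {members: [15,16,17,18,19,20,21,22,23,24,25,26,27,28,29], within: 0.85}
      between: 0.1
  - label: interface
    synthetic:
      chains: {R: 15, L: 15}
      n_frames: 1000
      geometry: clustered
      blocks:
        - {members: [0,1,2,3,4,5,6,7,8,9], within: 0.85}
        - {members: [10,11,12,13,14,15,16,17,18,19], within: 0.85}   # spans R and L
        - {members: [20,21,22,23,24,25,26,27,28,29], within: 0.85}
      between: 0.1
energetics: {mode: computed, receptor: "chain R", ligand: "chain L"}
entropy: true
```

The run writes per-condition artifacts (RMSF profile, correlation matrix,
PCA eigensystem and projections, weighted edge list, community table, GML
network, MM-GBSA summary, JSON manifest) under `demo_out/<label>/` and
prints a comparison report. Key numbers from this run:

| quantity                  | chain-local | interface |
|---------------------------|-------------|-----------|
| communities               | 2           | 3         |
| interface-spanning        | 0           | 2         |
| CPL                       | 1.824       | 1.628     |
| modularity Q              | 0.443       | 0.551     |
| ΔG_bind (kcal/mol)        | −1.82       | −2.51     |

The chain-local condition yields communities that respect the chain
boundary (no interface-spanning community), while the planted cross-chain
block produces communities containing residues of both chains — the
community planted across the interface plus a second one picked up by a
boundary residue under finite-sample correlation noise, which is typical of
community detection on short windows. The lower CPL of the interface
condition reflects shorter correlation-weighted paths across the complex,
i.e. stronger inter-chain communication.

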