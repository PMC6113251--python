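output_dir: demo_out
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
        - {members: [10,11,12,13,14,15,16,17,18,19], within: 0.85}
        - {members: [20,21,22,23,24,25,26,27,28,29], within: 0.85}
      between: 0.1
energetics: {mode: computed, receptor: "chain R", ligand: "chain L"}
entropy: true
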