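seed: 7
synthetic:
  scaffold:
    box: [60, 60, 60]
    cavity_radius: 10.0
    cavity_depth: 24.0
    wall_atom_spacing: 2.0
    anchors:
      - {resname: LYS, resid: 539, position: [30.0, 30.0, 24.0]}
      - {resname: ARG, resid: 730, position: [30.0, 30.0, 36.0]}
  markov:
    states:
      - {name: bulk, kind: bulk}
      - {name: S1, kind: site, center: [30.0, 30.0, 24.0], jitter_sd: 0.5}
      - {name: S2, kind: site, center: [30.0, 30.0, 36.0], jitter_sd: 0.5}
    transition:
      - [0.8, 0.1, 0.1]
      - [0.05, 0.95, 0.0]
      - [0.05, 0.0, 0.95]
    dt_ns: 0.1
    n_steps: 400
    ions: {Cl-: 5}
regions:
  S1zone: {residues: ["LYS:539"], radius: 6.0}
  S2zone: {residues: ["ARG:730"], radius: 6.0}
analysis:
  isovalue: 0.05
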