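# Multiple-walker PBMetaD on the 2D three-state folder analogue.
seed: 1
system:
  name: three_well_2d
  populations: [0.55, 0.15, 0.30]
integrator:
  dt: 0.003
  n_steps: 150000
  save_stride: 20
metad:
  mode: pb
  cvs: [x1, x2]
  sigma: {x1: 0.15, x2: 0.15}
  height: 1.0
  pace: 250
  biasfactor: 10
  walkers: 4
analysis:
  cv: dist
  bins: 40
  partition:
    thresholds: [1.5, 3.6]
    labels: [folded, misfolded, unfolded]
  n_blocks: 10
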