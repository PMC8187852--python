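# SAXS-like-restrained M&M: 80/20 prior pushed toward reference targets.
seed: 1
system:
  name: two_state_1d
  populations: [0.8, 0.2]
integrator:
  dt: 0.004
  n_steps: 200000
  save_stride: 20
metad:
  mode: pb
  cvs: [x]
  sigma: {x: 0.15}
  height: 1.0
  pace: 250
  walkers: 16
metainference:
  replicas: 16
  stride: 2
  averaging: 250
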