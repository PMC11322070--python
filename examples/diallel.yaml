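simulate:
  seed: 1
  trait: trait
  design:
    type: diallel
    parents: [A, B, C, D]
    crosses: [[A, C], [A, D], [B, C], [B, D]]
    offspring: dh
  map:
    n_chromosomes: 2
    length_cM: 80.0
  n_per_family: 40
  n_env: 2
  grid_step_cM: 5.0
  qtls:
    - {chrom: "1", pos_cM: 40.0, type: ecfc, variance: 2.0}
    - {chrom: "2", pos_cM: 30.0, type: esfc, variance: [3.0, 0.0]}
  polygenic:
    met_variances: [1.0, 1.0]
    met_corr: 0.5
    mpp_weights: [1.0, 1.3, 0.8, 1.1]
  residual_var: [0.5, 0.8]
scan:
  types: [ecfc, esfc, ecfs, esfs]
  alpha: 0.05
  window_cM: 20.0
  polygenic: [us, idh]
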