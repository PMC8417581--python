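# Minimal end-to-end configuration: 20 + 20 subjects on a 50-vertex strip,
# 200 cluster permutations, 2,000 bootstrap draws.
out_dir: results_minimal
seed: 7
stages: [simulate, gradient, ifc, stats, mediate]
params:
  simulate:
    n_case: 20
    n_control: 20
    T: 200
    n_axis: 25
    n_width: 2
  stats:
    n_perm: 200
  mediate:
    n_boot: 2000
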