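# End-to-end demo: one synthetic 60-chromosome cohort over an 18 kb
# promoter-like region with a 10x hotspot near the TSS (physical 16 kb),
# run through every stage.
#
#   promoterpop pipeline --config examples/demo.yaml --out-dir runs/demo --seed 1
simulate:
  n_chromosomes: 60
  theta_per_kb: 1.2
  region_length_bp: 18000
  background_rho_per_kb: 0.5
  hotspots:
    - {center_bp: 15500, width_bp: 2000, factor: 10.0}
  case_fraction: 0.5
phase:
  tol: 1.0e-6
  restarts: 3
recomb:
  lookup_reps: 2000
  window_bp: 2000
  step_bp: 500
stages: [phase, ld, recomb, selection, phylo, assoc]
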