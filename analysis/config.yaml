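# Shared configuration for the analysis drivers (01..05).
# One global seed, forked deterministically per stage.
seed: 2026
out_dir: results/study
simulate: {}          # default two-cohort study conditions
carry_forward_probes: []
thresholds:
  ewas_fdr: 0.05
  meqtl_fdr: 0.05
  clump_r2: 0.1
  screen_alpha: 0.05
  screen_mode: strict
  min_f: 10.0
  mr_alpha: 0.05
  cis_window_bp: 2000000
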