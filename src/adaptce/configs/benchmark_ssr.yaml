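# Interim-selection study with sample size reassessment: trials initially
# sized for the composite at correlation 0; blinded selection after half the
# planned sample, then the size is recomputed (never below those recruited,
# capped at the maximum-correlation bound).
name: benchmark-interim-ssr
designs: [fixed_re, fixed_ce, select_at_interim_ssr]
truth: alternative
sizing: ce_rho0
omega: 0.5
alpha: 0.05
beta: 0.2
pi: 0.5
n_reps: 500
estimator: blinded
grid:
  p1: [0.1, 0.2]
  or1: [0.6, 0.8]
  p2: [0.1, 0.25]
  or2: [0.75, 0.8]
  rho: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
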