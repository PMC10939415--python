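# Selection-at-the-end study: trials sized for the relevant endpoint,
# blinded selection (adaptive design) at the planned end, no reassessment.
name: benchmark-selection-at-end
designs: [fixed_re, fixed_ce, select_at_end_no_ssr]
truth: alternative
sizing: re
alpha: 0.05
beta: 0.2
pi: 0.5
n_reps: 1000
estimator: blinded
grid:
  p1: [0.1, 0.2]
  or1: [0.6, 0.8]
  p2: [0.1, 0.25]
  or2: [0.75, 0.8]
  rho: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
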