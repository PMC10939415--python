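# Peritoneal-dialysis worked example: peritonitis/membrane deterioration
# (relevant endpoint) and technical failure combined into the MAPE composite.
# The adaptive design selects the composite for small correlations and
# switches to the relevant endpoint from correlation 0.2 on.
name: peritoneal-dialysis-example
designs: [fixed_re, fixed_ce, select_at_end_no_ssr]
truth: alternative
sizing: re
alpha: 0.05
beta: 0.2
pi: 0.5
n_reps: 1000
estimator: blinded
grid:
  p1: [0.615]
  or1: [0.52]
  p2: [0.15]
  or2: [0.66]
  rho: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
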