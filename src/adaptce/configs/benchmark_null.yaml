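# Global-null study for type-1-error: sizing reuses the alternative design
# assumptions (relevant-endpoint sizing with the anticipated odds ratios)
# while the data are generated with no effect in either component.
name: benchmark-global-null
designs: [select_at_end_no_ssr, select_at_interim_no_ssr]
truth: global_null
sizing: re
omega: 0.5
alpha: 0.05
beta: 0.2
pi: 0.5
n_reps: 2000
estimator: blinded
grid:
  p1: [0.1, 0.2]
  or1: [0.6, 0.8]
  p2: [0.1, 0.25]
  or2: [0.75, 0.8]
  rho: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
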