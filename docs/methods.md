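# Methods

This note documents the statistical model behind `adaptce`, the estimators and
decision rules it implements, the numerical conventions, and what the
simulation engine does and does not emulate.

## Model and assumptions

Each subject in arm *i* (control *i = 0*, treatment *i = 1*) contributes two
binary responses, indicators of the component events ε₁ (the clinically most
relevant) and ε₂. Their joint law within an arm is the 2×2 table determined by
the marginals `p1^(i)`, `p2^(i)` and Pearson's correlation ρ between the
indicators:

    p11 = p1 p2 + ρ √(p1 q1 p2 q2),   q = 1 − p.

Standing assumptions, carried from the underlying methodology:

- **Shared correlation.** ρ is the same in both (all) arms. This is what makes
  the blinded correlation estimator well defined; the feasible range for ρ is
  therefore the *intersection* of the per-arm Fréchet-implied intervals.
- **Prespecified effects.** Treatment effects are odds ratios `OR_k`, fixed at
  the design stage. Blinded estimation recovers nuisance parameters
  (`p_k^(0)`, ρ) but never effect sizes — those cannot be identified from
  pooled data by construction.
- **Asymptotic tests.** The final analysis is the one-sided log-OR z test;
  sample-size formulas are its asymptotic inversion. Small-sample exactness is
  out of scope.

The composite ε\* = ε₁ ∪ ε₂ has probability
`p* = 1 − q1 q2 − ρ √(p1 q1 p2 q2)` per arm; its odds ratio OR\* is *derived*
from the two arms' union probabilities, never assumed. At `OR1 = OR2 = 1` the
derivation yields OR\* = 1 for every feasible ρ (null preservation), and `p*`
is decreasing in ρ: overlapping components add fewer new events.

All association conversions (conditional probability ↔ ρ) go through the joint
cell `p11` as the canonical intermediate, since every such measure is a
function of `(p1, p2, p11)`.

## Sample size and the decision rule

The total size for the one-sided log-OR test at level α, power 1−β, control
allocation π is

    N = ((z_α + z_β)/log OR)² · ( 1/(π p0 q0) + 1/((1−π) p1 q1) ),

the z's entering through their magnitudes. Per-arm sizes are ceilings of the
allocation split (`⌈πN⌉`, `⌈(1−π)N⌉`), which preserves the power target; the
decision ratio `d = N₁/N*` is always computed from the *unrounded* sizes so
that rounding cannot create ties. `d` is scale-free in `(z_α + z_β)²` and
monotone non-increasing in ρ. `d < 1` selects the relevant endpoint; `d ≥ 1`
the composite.

For M treatment arms sharing one control, each comparison is tested at α/M
(Bonferroni) and the trial total is `N·(M − (M−1)π)`.

## Blinded estimation

With ñ pooled subjects (arm sizes ñ⁽⁰⁾, ñ⁽¹⁾ known by design), the pooled rate
of component k is the mixture `π p_k^(0) + (1−π) p_k^(1)`, strictly increasing
in `p_k^(0)` for fixed OR_k; bisection on (0,1) (60 iterations, interval
below 1e-15) recovers the control probability. The correlation estimator
inverts the union identity applied to the pooled composite rate, with arm
weights ñ⁽ⁱ⁾/ñ. Both weights use ñ in the denominator — the weights must sum
to one for the estimator to be exact at population level, which the test suite
asserts to 1e-10 (`estimate_from_rates`).

Numerical conventions:

- **Degenerate counts** (0 or ñ) are replaced by a 0.5 continuity offset so an
  interim decision is always defined in small samples.
- **Clamping.** ρ̂ is truncated to the feasible interval of the reconstructed
  marginals (both arms). The raw value is kept alongside
  (`rho_hat_raw`). A config flag (`rho_floor_zero`) optionally floors ρ̂ at 0
  for settings where negative correlation is implausible; the default clamps
  to the full feasible interval, because discarding admissible negative
  estimates would bias the composite's size upward.
- **Feasibility tolerance** 1e-9 absorbs floating-point noise at Fréchet
  boundaries before joint cells are clipped at zero.

**Reassessment**: `n_a = max(ñ, N_selected(estimates))` — never below the
subjects already recruited — capped at the protocol bound (the larger of the
relevant-endpoint size and the composite size at the largest feasible design
correlation). With selection at the planned end (ω = 1) the size can only
stay or grow.

**K components**: the recursive rule compares the running endpoint against its
union with the next component in importance order; when it continues, the
running composite's probability and odds ratio are recomputed from the current
estimates and serve as "anticipated values" for the next comparison, whose
correlation is estimated from the pooled counts of the running endpoint, the
next component, and their union. Bookkeeping stores all K component
indicators per pooled subject, which supplies every union count the recursion
needs.

## Simulation engine

An arm of a trial is a multinomial draw over the four joint cells, so a
replicate reduces to a handful of counts and the engine vectorises across
replicates; cost is independent of trial size. Variants:

| variant | sizing default | selection | reassessment |
|---|---|---|---|
| `fixed_re` / `fixed_ce` | relevant endpoint | none | none |
| `select_at_end_no_ssr` | relevant endpoint | blinded, all n | none |
| `select_at_interim_no_ssr` | relevant endpoint | blinded, ω·n | none |
| `select_at_interim_ssr` | composite at ρ=0 | blinded, ω·n | `max(ñ, N̂)`, capped |

Conventions chosen where the design was genuinely open:

- **Zero cells** in a final 2×2 table get the Haldane–Anscombe 0.5 correction
  (all four cells), keeping the statistic defined at small n.
- **Stage pooling.** The final test naively pools stages; legitimate because
  selection and reassessment use blinded data only.
- **Null scenarios** reuse the alternative design assumptions for sizing and
  estimation while generating data at `OR1 = OR2 = 1`.
- **Feasibility** of a scenario is judged against the *true* generating
  marginals of both arms; infeasible grid combinations are discarded (the
  benchmark grid keeps 122 of 144 alternative combinations, 124 of 144 null
  ones).
- **Fixed comparator designs run to their planned n** in the interim studies
  (they have no interim machinery of their own).
- **Determinism.** Each scenario draws from a generator spawned from the
  master seed by scenario index (`SeedSequence(seed, spawn_key=(i,))`), so a
  results table is reproducible bit-for-bit for a given grid and seed,
  independent of execution order.
- **Multi-arm trials** are simulated with per-comparison rejection recorded
  for the first treatment arm at level α/M (the arms are exchangeable under
  the equal-effects assumption); the unblinded-estimation variant is
  implemented for the two-arm case only.

The **unblinded variant** estimates control probabilities and the correlation
from arm-labelled data (effects still assumed) and then tests naively pooled
stages; it exists to demonstrate the resulting type-1-error inflation, not as
a recommended design.

### What the generator does and does not emulate

The generator reproduces exactly the probabilistic structure the design
assumes: exchangeable subjects, constant probabilities and correlation,
complete follow-up, simultaneous availability of both indicators. Real trials
deviate in ways the engine does not model — staggered recruitment, dropout,
time-varying event rates, unequal correlations across arms, misspecified
effect sizes (the last can be studied via the partial-null truths). Passing
operating-characteristics tests therefore certifies the *method under its own
assumptions*, not robustness to those violations.

## Benchmark studies and problem sizes

The packaged benchmark grid (control probabilities {0.1, 0.2} × {0.1, 0.25},
odds ratios {0.6, 0.8} × {0.75, 0.8}, ρ ∈ {0, …, 0.8}, π = 0.5, α = 0.05,
power 0.80) is simulated at 1000 replicates per scenario for the
selection-at-end and reassessment studies and 2000 for the global-null study
— sizes at which the Monte-Carlo error of a grid mean is below 0.002 while
the whole acceptance run stays in seconds. Expected summaries: mean power
0.80 / 0.85 / 0.88 (RE / CE / adaptive, selection at end, RE sizing),
0.64 / 0.72 / 0.80 (RE / CE / adaptive with reassessment, composite-at-ρ=0
sizing), median null rejection ≈ 0.0498.

The per-scenario type-1-error check uses a simultaneous (familywise 0.1%)
bound rather than a per-scenario 3·SE cutoff: across ~250 Monte-Carlo
estimates of a controlled rate, a 3·SE exceedance is expected by chance
alone, so the naive bound would reject a correct design.

## Known limitations

- Unequal correlations across arms are not supported (the shared-ρ assumption
  is structural to blinded estimation here).
- Unblinded selection with proper multiplicity adjustment (adaptive closed
  testing) is out of scope; the unblinded variant is a demonstration of the
  problem, not a solution.
- Time-to-event endpoints, group-sequential boundaries, and platform designs
  with staggered arm entry are not modelled.
- Sample-size formulas are asymptotic; for very small trials the normal
  approximation and the continuity conventions dominate behaviour.
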