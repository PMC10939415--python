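"""Correlated binary trial simulation and the operating-characteristics engine.

Subjects contribute a pair of binary responses whose joint law within an arm is
the 2x2 table with success cell ``p11 = p1*p2 + rho*sqrt(p1*q1*p2*q2)`` — the
same correlation in both arms.  A simulated arm is therefore a multinomial draw
over four cells, and a whole trial reduces to a handful of multinomial counts;
the engine exploits this to vectorise across replicates, so per-scenario cost
is independent of the trial's sample size.

Three designs are compared: a fixed design testing only the relevant endpoint
(RE), a fixed design testing only the composite (CE), and the adaptive design
(AD) that pools the blinded responses, estimates the nuisance parameters,
selects the endpoint with the smaller estimated sample size, and (optionally)
reassesses the sample size.  Selection can happen at the planned end or at an
interim after a fraction ``omega`` of the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .composite import (
    EndpointMarginals,
    correlation_bounds,
    joint_bounds_both_arms,
    joint_cells,
    treatment_prob,
)
from .blinded import _estimate_vec
from .design import (
    DesignConfig,
    nraw_binary,
    nraw_composite,
    ss_binary,
    ss_composite,
)
from .exceptions import (
    ConfigurationError,
    InfeasibleCorrelationError,
    InvalidParameterError,
    UnsupportedConfigurationError,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "TrialOutcome",
    "VARIANTS",
    "TRUTHS",
    "draw_correlated_pair",
    "z_test_logor",
    "run_trial",
    "unblinded_variant",
    "simulate_scenario",
    "operating_characteristics",
    "results_to_frame",
    "benchmark_scenarios",
    "DEFAULT_RHO_GRID",
]

VARIANTS = (
    "fixed_re",
    "fixed_ce",
    "select_at_end_no_ssr",
    "select_at_interim_ssr",
    "select_at_interim_no_ssr",
)
TRUTHS = ("alternative", "global_null", "null_component_1", "null_component_2")
SIZINGS = ("re", "ce_rho0")

DEFAULT_RHO_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario: design assumptions, data-generating truth, variant.

    ``e1`` and ``e2`` carry the *design* parameters (control probabilities and
    anticipated odds ratios) used for sizing and blinded estimation.  The data
    are generated from the same control probabilities with odds ratios set by
    ``truth``: under ``"alternative"`` the design effects are real, under
    ``"global_null"`` both ORs are 1, and the two partial nulls switch off one
    component's effect.  ``rho_true`` is the correlation generating the data
    (in both arms); it must be feasible for the true marginals of both arms.
    ``sizing`` chooses the initial sample size: ``"re"`` sizes for the
    relevant endpoint, ``"ce_rho0"`` for the composite at the design
    correlation (0 by default); if None it defaults to ``"ce_rho0"`` for the
    reassessment variant and ``"re"`` otherwise.
    """

    e1: EndpointMarginals
    e2: EndpointMarginals
    rho_true: float
    cfg: DesignConfig = field(default_factory=DesignConfig)
    variant: str = "select_at_end_no_ssr"
    truth: str = "alternative"
    sizing: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.truth not in TRUTHS:
            raise ConfigurationError(f"unknown truth {self.truth!r}; one of {TRUTHS}")
        if self.sizing is not None and self.sizing not in SIZINGS:
            raise ConfigurationError(f"unknown sizing {self.sizing!r}; one of {SIZINGS}")

    @property
    def sizing_effective(self) -> str:
        if self.sizing is not None:
            return self.sizing
        return "ce_rho0" if self.variant == "select_at_interim_ssr" else "re"

    @property
    def omega_effective(self) -> float:
        if self.variant in ("fixed_re", "fixed_ce", "select_at_end_no_ssr"):
            return 1.0
        return self.cfg.omega

    def true_or(self) -> tuple[float, float]:
        if self.truth == "alternative":
            return self.e1.or_, self.e2.or_
        if self.truth == "global_null":
            return 1.0, 1.0
        if self.truth == "null_component_1":
            return 1.0, self.e2.or_
        return self.e1.or_, 1.0

    def true_marginals(self) -> tuple[float, float, float, float]:
        """(p1_control, p2_control, p1_treat, p2_treat) under the generating truth."""
        or1, or2 = self.true_or()
        return (
            self.e1.p0,
            self.e2.p0,
            treatment_prob(self.e1.p0, or1),
            treatment_prob(self.e2.p0, or2),
        )

    def is_feasible(self) -> bool:
        """True when rho_true is within the feasible range of both arms' true marginals."""
        p10, p20, p11, p21 = self.true_marginals()
        b0 = correlation_bounds(p10, p20)
        b1 = correlation_bounds(p11, p21)
        return (self.rho_true in b0) and (self.rho_true in b1)


@dataclass(frozen=True)
class ScenarioResult:
    """Empirical operating characteristics of one scenario."""

    rejection_rate: float
    mc_se: float
    prop_composite_selected: float
    mean_final_n: float
    n_reps: int
    seed: Optional[int] = None


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated trial: final decision and bookkeeping."""

    rejected: bool
    selected: str
    n_final: int
    d_value: float
    rho_hat: float


def draw_correlated_pair(p1, p2, rho, n, seed=None):
    """Draw ``n`` subjects' paired binary responses with given marginals and correlation.

    Sampling is multinomial over the joint 2x2 cells; rows are shuffled.
    Returns an ``(n, 2)`` int array.
    """
    b = correlation_bounds(p1, p2)
    if rho not in b:
        raise InfeasibleCorrelationError(
            f"rho={rho} outside feasible range [{b.lower:.6g}, {b.upper:.6g}]"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cells = joint_cells(p1, p2, rho)
    counts = rng.multinomial(int(n), cells)
    patterns = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int64)
    out = np.repeat(patterns, counts, axis=0)
    rng.shuffle(out, axis=0)
    return out


def _logor_stat(x0, n0, x1, n1):
    """Vectorised log-OR z statistic with Haldane-Anscombe zero-cell correction.

    ``1/(n p_hat q_hat) = 1/x + 1/(n-x)``, so the statistic is computed from
    the four 2x2 cells; when any cell is empty 0.5 is added to all four cells
    of that replicate's table.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    a, b_ = x1, n1 - x1  # treatment events / non-events
    c, d_ = x0, n0 - x0  # control events / non-events
    zero = (a == 0) | (b_ == 0) | (c == 0) | (d_ == 0)
    corr = np.where(zero, 0.5, 0.0)
    a, b_, c, d_ = a + corr, b_ + corr, c + corr, d_ + corr
    log_or = np.log(a / b_) - np.log(c / d_)
    se = np.sqrt(1.0 / a + 1.0 / b_ + 1.0 / c + 1.0 / d_)
    return log_or / se


def z_test_logor(x0, n0, x1, n1, alpha_level: float = 0.05):
    """One-sided test of OR = 1 against OR < 1 on a 2x2 table (array-friendly).

    Returns ``(statistic, reject)`` with rejection when the statistic falls
    below the lower-tail normal quantile at ``alpha_level``.
    """
    if np.any(np.asarray(n0) < 1) or np.any(np.asarray(n1) < 1):
        raise InvalidParameterError("arm sizes must be >= 1")
    stat = _logor_stat(x0, n0, x1, n1)
    crit = norm.ppf(alpha_level)
    reject = stat < crit
    if np.ndim(stat) == 0:
        return float(stat), bool(reject)
    return stat, reject


def _planned_per_comparison(scn: Scenario) -> float:
    """Unrounded per-comparison total size from the design assumptions."""
    cfg = scn.cfg
    if scn.sizing_effective == "re":
        return ss_binary(scn.e1.p0, scn.e1.or_, cfg).n_raw
    return ss_composite(scn.e1, scn.e2, cfg.rho_design, cfg).n_raw


def _ssr_cap_per_comparison(scn: Scenario) -> float:
    """Protocol bound on the reassessed size: RE and CE sizes at the largest
    feasible correlation of the design marginals, whichever is larger."""
    cfg = scn.cfg
    n1 = ss_binary(scn.e1.p0, scn.e1.or_, cfg).n_raw
    rho_hi = joint_bounds_both_arms(scn.e1, scn.e2).upper
    ns = ss_composite(scn.e1, scn.e2, rho_hi - 1e-9, cfg).n_raw
    bound = max(n1, ns)
    return bound if math.isfinite(bound) else np.inf


def _simulate_arrays(scn: Scenario, n_reps: int, rng: np.random.Generator,
                     estimator: str = "blinded") -> dict:
    """Core engine: simulate ``n_reps`` replicates of one scenario, vectorised.

    Returns per-replicate arrays: ``reject`` (first treatment comparison),
    ``composite_selected``, ``n_final``, ``d``, ``rho_hat``.
    """
    if not scn.is_feasible():
        p10, p20, p11, p21 = scn.true_marginals()
        raise InfeasibleCorrelationError(
            f"rho_true={scn.rho_true} infeasible for true marginals "
            f"control=({p10}, {p20}), treatment=({p11}, {p21})"
        )
    if estimator not in ("blinded", "unblinded"):
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    cfg = scn.cfg
    m_arms = cfg.n_arms
    if estimator == "unblinded" and m_arms != 1:
        raise UnsupportedConfigurationError("unblinded estimation is implemented for one treatment arm")
    pi = cfg.pi
    alpha_cmp = cfg.alpha_comparison
    crit = norm.ppf(alpha_cmp)

    p10, p20, p11, p21 = scn.true_marginals()
    cells0 = np.array(joint_cells(p10, p20, scn.rho_true))
    cells1 = np.array(joint_cells(p11, p21, scn.rho_true))
    cells0 /= cells0.sum()
    cells1 /= cells1.sum()

    n_raw = _planned_per_comparison(scn)
    n0 = max(2, math.ceil(pi * n_raw - 1e-9))
    nt = max(2, math.ceil((1.0 - pi) * n_raw - 1e-9))

    omega = scn.omega_effective
    m0 = max(2, math.ceil(omega * n0 - 1e-9))
    mt = max(2, math.ceil(omega * nt - 1e-9))

    c0 = rng.multinomial(m0, cells0, size=n_reps).astype(np.int64)
    ct = [rng.multinomial(mt, cells1, size=n_reps).astype(np.int64) for _ in range(m_arms)]

    adaptive = scn.variant not in ("fixed_re", "fixed_ce")
    d = np.full(n_reps, np.nan)
    rho_hat = np.full(n_reps, np.nan)
    if adaptive:
        n_blind = m0 + m_arms * mt
        x1 = c0[:, 0] + c0[:, 1] + sum(c[:, 0] + c[:, 1] for c in ct)
        x2 = c0[:, 0] + c0[:, 2] + sum(c[:, 0] + c[:, 2] for c in ct)
        xs = n_blind - c0[:, 3] - sum(c[:, 3] for c in ct)
        if estimator == "blinded":
            est = _estimate_vec(
                x1, x2, xs, m0, n_blind - m0, scn.e1.or_, scn.e2.or_,
                floor_zero=cfg.rho_floor_zero,
            )
            p10_h, p20_h = est["p0_hat_1"], est["p0_hat_2"]
            rho_hat = est["rho_hat"]
        else:
            p10_h, p20_h, rho_hat = _unblinded_estimates(c0, ct[0], m0, mt, cfg)
        n1_raw = nraw_binary(p10_h, scn.e1.or_, alpha_cmp, cfg.beta, pi)
        ns_raw = nraw_composite(
            p10_h, p20_h, scn.e1.or_, scn.e2.or_, rho_hat, alpha_cmp, cfg.beta, pi
        )
        d = n1_raw / ns_raw
        composite_sel = d >= 1.0
    elif scn.variant == "fixed_ce":
        composite_sel = np.ones(n_reps, dtype=bool)
    else:
        composite_sel = np.zeros(n_reps, dtype=bool)

    if scn.variant == "select_at_interim_ssr":
        sel_raw = np.where(composite_sel, ns_raw, n1_raw)
        cap = _ssr_cap_per_comparison(scn)
        sel_raw = np.minimum(sel_raw, cap)
        f0 = np.maximum(m0, np.ceil(pi * sel_raw - 1e-9)).astype(np.int64)
        ft = np.maximum(mt, np.ceil((1.0 - pi) * sel_raw - 1e-9)).astype(np.int64)
    else:
        f0 = np.full(n_reps, n0, dtype=np.int64)
        ft = np.full(n_reps, nt, dtype=np.int64)

    if np.any(f0 > m0):
        c0 = c0 + rng.multinomial(f0 - m0, cells0)
    ct = [
        c + rng.multinomial(ft - mt, cells1) if np.any(ft > mt) else c
        for c in ct
    ]

    x0_re = c0[:, 0] + c0[:, 1]
    x0_ce = f0 - c0[:, 3]
    x0_sel = np.where(composite_sel, x0_ce, x0_re)
    rejects = []
    for c in ct:
        xt_re = c[:, 0] + c[:, 1]
        xt_ce = ft - c[:, 3]
        xt_sel = np.where(composite_sel, xt_ce, xt_re)
        rejects.append(_logor_stat(x0_sel, f0, xt_sel, ft) < crit)

    return {
        "reject": rejects[0],
        "reject_any": np.logical_or.reduce(rejects),
        "composite_selected": composite_sel,
        "n_final": f0 + m_arms * ft,
        "d": d,
        "rho_hat": rho_hat,
    }


def _unblinded_estimates(c0, c1, m0, m1, cfg: DesignConfig):
    """Arm-labelled estimates: observed control rates and the weighted per-arm
    Pearson correlation of the two indicators (effects still assumed)."""
    eps = 0.5

    def _arm(c, m):
        x1 = np.clip(c[:, 0] + c[:, 1], eps, m - eps)
        x2 = np.clip(c[:, 0] + c[:, 2], eps, m - eps)
        p1 = x1 / m
        p2 = x2 / m
        p11 = c[:, 0] / m
        den = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        rho = (p11 - p1 * p2) / den
        return p1, p2, np.clip(rho, -1.0, 1.0)

    p10, p20, rho0 = _arm(c0, m0)
    p11_, p21_, rho1 = _arm(c1, m1)
    n = m0 + m1
    rho = (m0 / n) * rho0 + (m1 / n) * rho1
    if cfg.rho_floor_zero:
        rho = np.maximum(rho, 0.0)
    # clamp to the feasible range of the control marginals (shared-rho assumption)
    from .composite import FEASIBILITY_TOL  # local import avoids cycle noise

    q10, q20 = 1 - p10, 1 - p20
    upper = np.minimum(np.sqrt(p10 * q20 / (p20 * q10)), np.sqrt(p20 * q10 / (p10 * q20)))
    lower = np.maximum(-np.sqrt(p10 * p20 / (q10 * q20)), -np.sqrt(q10 * q20 / (p10 * p20)))
    rho = np.clip(rho, lower + FEASIBILITY_TOL, upper - FEASIBILITY_TOL)
    return p10, p20, rho


def simulate_scenario(
    scn: Scenario, n_reps: int, seed=None, estimator: str = "blinded"
) -> ScenarioResult:
    """Monte-Carlo operating characteristics of one scenario."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = _simulate_arrays(scn, n_reps, rng, estimator=estimator)
    rate = float(np.mean(out["reject"]))
    return ScenarioResult(
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1.0 - rate) / n_reps)),
        prop_composite_selected=float(np.mean(out["composite_selected"])),
        mean_final_n=float(np.mean(out["n_final"])),
        n_reps=n_reps,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def run_trial(scn: Scenario, seed=None) -> TrialOutcome:
    """Execute a single trial under the scenario's design variant."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = _simulate_arrays(scn, 1, rng)
    return TrialOutcome(
        rejected=bool(out["reject"][0]),
        selected="composite" if out["composite_selected"][0] else "relevant",
        n_final=int(out["n_final"][0]),
        d_value=float(out["d"][0]),
        rho_hat=float(out["rho_hat"][0]),
    )


def unblinded_variant(scn: Scenario, seed=None) -> TrialOutcome:
    """Single trial with *unblinded* nuisance estimation (effects still assumed).

    Provided to demonstrate that selection on unblinded data followed by a
    naive pooled final test can inflate the type-1 error; the blinded flow of
    :func:`run_trial` is the proposed design.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = _simulate_arrays(scn, 1, rng, estimator="unblinded")
    return TrialOutcome(
        rejected=bool(out["reject"][0]),
        selected="composite" if out["composite_selected"][0] else "relevant",
        n_final=int(out["n_final"][0]),
        d_value=float(out["d"][0]),
        rho_hat=float(out["rho_hat"][0]),
    )


def operating_characteristics(
    scenarios: Sequence[Scenario],
    n_reps: int,
    seed: int = 0,
    estimator: str = "blinded",
) -> list[ScenarioResult]:
    """Simulate every scenario with independent, order-insensitive substreams.

    Each scenario draws from a dedicated generator spawned from the master
    seed by scenario index, so results are reproducible and independent of
    execution order.
    """
    if len(scenarios) == 0:
        raise ConfigurationError("scenario list is empty")
    results = []
    for i, scn in enumerate(scenarios):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        results.append(simulate_scenario(scn, n_reps, rng, estimator=estimator))
    return results


def results_to_frame(scenarios: Sequence[Scenario], results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tidy one-row-per-scenario table of parameters and empirical results."""
    rows = []
    for i, (scn, res) in enumerate(zip(scenarios, results)):
        rows.append(
            {
                "scenario": i,
                "p1_0": scn.e1.p0,
                "or1": scn.e1.or_,
                "p2_0": scn.e2.p0,
                "or2": scn.e2.or_,
                "rho": scn.rho_true,
                "omega": scn.omega_effective,
                "variant": scn.variant,
                "truth": scn.truth,
                "sizing": scn.sizing_effective,
                "n_reps": res.n_reps,
                "rejection_rate": res.rejection_rate,
                "mc_se": res.mc_se,
                "prop_composite_selected": res.prop_composite_selected,
                "mean_final_n": res.mean_final_n,
            }
        )
    return pd.DataFrame(rows)


def benchmark_scenarios(
    variant: str,
    truth: str = "alternative",
    sizing: Optional[str] = None,
    omega: float = 0.5,
    *,
    p1_values: Sequence[float] = (0.1, 0.2),
    or1_values: Sequence[float] = (0.6, 0.8),
    p2_values: Sequence[float] = (0.1, 0.25),
    or2_values: Sequence[float] = (0.75, 0.8),
    rho_values: Sequence[float] = DEFAULT_RHO_GRID,
    alpha: float = 0.05,
    beta: float = 0.2,
    pi: float = 0.5,
) -> tuple[list[Scenario], int]:
    """Build the benchmark scenario grid for one design variant.

    The default parameter values are the simulation-study grid: control
    probabilities, anticipated odds ratios below one (the no-effect value 1 is
    used via ``truth``, not by inflating the grid), correlations 0 to 0.8 in
    steps of 0.1, equal allocation, one-sided alpha 0.05, power 0.80.
    Combinations whose correlation is infeasible for the *true* marginals of
    either arm are discarded; the count of discarded combinations is returned
    alongside the kept scenarios.
    """
    cfg = DesignConfig(alpha=alpha, beta=beta, pi=pi, omega=omega)
    kept: list[Scenario] = []
    dropped = 0
    for p1 in p1_values:
        for or1 in or1_values:
            for p2 in p2_values:
                for or2 in or2_values:
                    e1 = EndpointMarginals(p1, or1)
                    e2 = EndpointMarginals(p2, or2)
                    for rho in rho_values:
                        scn = Scenario(
                            e1=e1, e2=e2, rho_true=float(rho), cfg=cfg,
                            variant=variant, truth=truth, sizing=sizing,
                        )
                        if scn.is_feasible():
                            kept.append(scn)
                        else:
                            dropped += 1
    if not kept:
        raise ConfigurationError("grid is empty after feasibility filtering")
    return kept, dropped
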