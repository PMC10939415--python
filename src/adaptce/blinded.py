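"""Blinded estimation of nuisance parameters and the adaptive endpoint decision.

At the interim look (or the planned end) only the pooled responses are used:
event counts over both arms combined, without treatment labels.  Arm *sizes*
are known by design.  Given the prespecified odds ratios, the pooled event
probability of component k,

    p_k = pi * p_k^(0) + (1 - pi) * p_k^(1),     p_k^(1) = OR_k p_k^(0) / (q_k^(0) + OR_k p_k^(0)),

is strictly increasing in ``p_k^(0)``, so the control probability is recovered
by a root solve.  The correlation follows by inverting the union-probability
identity applied to the pooled composite rate:

    rho_hat = [ w0 (1 - q1^(0) q2^(0)) + w1 (1 - q1^(1) q2^(1)) - p_star_hat ]
              / [ w0 sqrt(p1^(0) q1^(0) p2^(0) q2^(0)) + w1 sqrt(p1^(1) q1^(1) p2^(1) q2^(1)) ],

with arm weights ``w_i`` equal to the blinded arm fractions.  Fed exact
population-level pooled quantities these estimators return the true parameters
exactly; the module's tests assert that inversion to 1e-10.

The decision then compares required sample sizes (``d = N_relevant /
N_composite``) and the reassessment rule never drops below the number already
recruited: ``n_a = max(n_recruited, N_selected)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .composite import (
    EndpointMarginals,
    composite_or,
    joint_bounds_both_arms,
)
from .design import DesignConfig, decision_ratio, ss_binary, ss_composite
from .exceptions import (
    InvalidParameterError,
    SchemaError,
    UnsupportedConfigurationError,
)

__all__ = [
    "PooledCounts",
    "BlindedSummary",
    "DecisionOutcome",
    "solve_control_prob",
    "estimate_rho",
    "estimate_from_rates",
    "select_and_reassess",
    "recursive_selection",
    "multiarm_blinded_pool",
]

_BISECT_LO = 1e-12
_BISECT_HI = 1.0 - 1e-12
_BISECT_ITER = 60  # interval 2^-60 ~ 9e-19, far below the 1e-10 contract


@dataclass(frozen=True)
class PooledCounts:
    """Pooled (blinded) event counts at the interim look.

    ``x1``, ``x2`` count subjects with each component event and ``x_star``
    subjects with either (the composite), all over the pooled sample of size
    ``n_blind = n0_blind + n1_blind``.  Arm sizes are known by design; no
    arm-labelled responses are carried, which is what keeps downstream
    estimation blinded by construction.
    """

    n0_blind: int
    n1_blind: int
    x1: int
    x2: int
    x_star: int

    def __post_init__(self) -> None:
        n = self.n_blind
        if self.n0_blind <= 0 or self.n1_blind <= 0:
            raise SchemaError("n0_blind and n1_blind must be positive")
        for name in ("x1", "x2", "x_star"):
            v = getattr(self, name)
            if not 0 <= v <= n:
                raise SchemaError(f"{name}={v} outside [0, n_blind={n}]")
        if self.x_star < max(self.x1, self.x2):
            raise SchemaError(
                f"x_star={self.x_star} smaller than max(x1, x2)="
                f"{max(self.x1, self.x2)}: impossible union count"
            )
        if self.x_star > self.x1 + self.x2:
            raise SchemaError(
                f"x_star={self.x_star} exceeds x1+x2={self.x1 + self.x2}: impossible union count"
            )

    @property
    def n_blind(self) -> int:
        return self.n0_blind + self.n1_blind


@dataclass(frozen=True)
class BlindedSummary:
    """Blinded estimates: pooled rates, reconstructed per-arm probabilities, correlation."""

    p_hat_1: float
    p_hat_2: float
    p_hat_star: float
    p0_hat_1: float
    p0_hat_2: float
    p1_hat_1: float
    p1_hat_2: float
    rho_hat: float
    rho_hat_raw: float  # before clamping to the feasible range


@dataclass(frozen=True)
class DecisionOutcome:
    """Endpoint decision and reassessed size.

    ``selected`` is ``"composite"`` (d >= 1) or ``"relevant"`` (d < 1); for the
    recursive K-component rule ``n_components`` records how many of the ordered
    components the selected endpoint unites.
    """

    d_value: float
    selected: str
    n_a: int
    n_components: Optional[int] = None


def _solve_control_prob_vec(p_hat, or_, pi):
    """Vectorised bisection for p0 in pi*p0 + (1-pi)*p1(p0, OR) = p_hat."""
    p_hat = np.asarray(p_hat, dtype=float)
    lo = np.full_like(p_hat, _BISECT_LO)
    hi = np.full_like(p_hat, _BISECT_HI)
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        p1 = or_ * mid / (1.0 - mid + or_ * mid)
        f = pi * mid + (1.0 - pi) * p1 - p_hat
        too_low = f < 0.0
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def solve_control_prob(p_hat: float, or_: float, pi: float) -> tuple[float, float]:
    """Recover the control-arm probability from a pooled rate and prespecified OR.

    Returns ``(p0, p1)``.  The pooled rate is a strictly increasing function of
    ``p0``, so bisection on (0, 1) converges unconditionally.
    """
    if not 0.0 < p_hat < 1.0:
        raise InvalidParameterError(f"pooled probability must be in (0, 1); got {p_hat}")
    if or_ <= 0.0:
        raise InvalidParameterError(f"or_ must be positive; got {or_}")
    if not 0.0 < pi < 1.0:
        raise InvalidParameterError(f"pi must be in (0, 1); got {pi}")
    p0 = float(_solve_control_prob_vec(p_hat, or_, pi))
    p1 = or_ * p0 / (1.0 - p0 + or_ * p0)
    return p0, float(p1)


def _estimate_vec(x1, x2, xs, n0, n1, or1, or2, *, floor_zero=False):
    """Vectorised blinded estimation from pooled counts; returns dict of arrays.

    Degenerate counts (0 or n) get a 0.5 continuity offset so the interim
    decision stays defined in small samples.  The correlation estimate is
    clamped to the feasible range of the reconstructed marginals (intersection
    over arms) and optionally floored at zero.
    """
    n = n0 + n1
    w0 = n0 / n
    w1 = n1 / n
    p1h = np.clip(np.asarray(x1, dtype=float), 0.5, n - 0.5) / n
    p2h = np.clip(np.asarray(x2, dtype=float), 0.5, n - 0.5) / n
    psh = np.clip(np.asarray(xs, dtype=float), 0.5, n - 0.5) / n

    p10 = _solve_control_prob_vec(p1h, or1, w0)
    p20 = _solve_control_prob_vec(p2h, or2, w0)
    p11 = or1 * p10 / (1.0 - p10 + or1 * p10)
    p21 = or2 * p20 / (1.0 - p20 + or2 * p20)
    q10, q20, q11, q21 = 1.0 - p10, 1.0 - p20, 1.0 - p11, 1.0 - p21

    num = w0 * (1.0 - q10 * q20) + w1 * (1.0 - q11 * q21) - psh
    den = w0 * np.sqrt(p10 * q10 * p20 * q20) + w1 * np.sqrt(p11 * q11 * p21 * q21)
    rho_raw = num / den

    # feasible range of the reconstructed marginals, intersected over arms
    def _upper(a, b):
        qa, qb = 1.0 - a, 1.0 - b
        return np.minimum(np.sqrt(a * qb / (b * qa)), np.sqrt(b * qa / (a * qb)))

    def _lower(a, b):
        qa, qb = 1.0 - a, 1.0 - b
        return np.maximum(-np.sqrt(a * b / (qa * qb)), -np.sqrt(qa * qb / (a * b)))

    upper = np.minimum(1.0, np.minimum(_upper(p10, p20), _upper(p11, p21)))
    lower = np.maximum(-1.0, np.maximum(_lower(p10, p20), _lower(p11, p21)))
    if floor_zero:
        lower = np.maximum(lower, 0.0)
    rho = np.clip(rho_raw, lower, upper)

    return {
        "p_hat_1": p1h, "p_hat_2": p2h, "p_hat_star": psh,
        "p0_hat_1": p10, "p0_hat_2": p20, "p1_hat_1": p11, "p1_hat_2": p21,
        "rho_hat": rho, "rho_hat_raw": rho_raw,
    }


def estimate_rho(
    counts: PooledCounts, or1: float, or2: float, pi: Optional[float] = None,
    *, floor_zero: bool = False,
) -> BlindedSummary:
    """Blinded nuisance-parameter estimates from pooled counts.

    ``pi`` defaults to the blinded control fraction ``n0_blind / n_blind``
    (which by design equals the trial's allocation).  ``or1``, ``or2`` are the
    prespecified design effects; they are *assumed*, not estimated — that is
    what makes blinded estimation possible.
    """
    if pi is None:
        pi = counts.n0_blind / counts.n_blind
    elif abs(pi - counts.n0_blind / counts.n_blind) > 1e-9:
        raise SchemaError(
            f"pi={pi} inconsistent with blinded arm sizes "
            f"{counts.n0_blind}/{counts.n_blind}"
        )
    est = _estimate_vec(
        counts.x1, counts.x2, counts.x_star,
        counts.n0_blind, counts.n1_blind, or1, or2, floor_zero=floor_zero,
    )
    return BlindedSummary(**{k: float(v) for k, v in est.items()})


def estimate_from_rates(
    p_hat_1: float,
    p_hat_2: float,
    p_hat_star: float,
    or1: float,
    or2: float,
    pi: float = 0.5,
    *,
    floor_zero: bool = False,
) -> BlindedSummary:
    """Blinded estimation from pooled *rates* instead of counts.

    Useful for population-level (infinite-sample) calculations: fed the exact
    pooled probabilities implied by some true parameter set, the returned
    estimates reproduce that parameter set to solver tolerance, because the
    estimator is the algebraic inverse of the pooled-mixture identities.
    """
    for name, v in (("p_hat_1", p_hat_1), ("p_hat_2", p_hat_2), ("p_hat_star", p_hat_star)):
        if not 0.0 < v < 1.0:
            raise InvalidParameterError(f"{name} must be in (0, 1); got {v}")
    # scale-free: weights enter only through pi
    big = 10**9
    n0 = pi * big
    est = _estimate_vec(
        p_hat_1 * big, p_hat_2 * big, p_hat_star * big,
        n0, big - n0, or1, or2, floor_zero=floor_zero,
    )
    return BlindedSummary(**{k: float(v) for k, v in est.items()})


def select_and_reassess(
    summary: BlindedSummary,
    or1: float,
    or2: float,
    cfg: DesignConfig,
    n_recruited: int,
    n_planned: Optional[int] = None,
    n_max: Optional[int] = None,
) -> DecisionOutcome:
    """Select the primary endpoint and reassess the sample size.

    The decision ratio is evaluated at the blinded estimates with the design
    odds ratios.  With reassessment enabled, ``n_a = max(n_recruited,
    N_selected)``, optionally capped at the protocol maximum ``n_max`` (never
    below ``n_recruited``).  With ``cfg.reassess`` False the planned size is
    kept (``n_planned`` required).
    """
    e1 = EndpointMarginals(summary.p0_hat_1, or1)
    e2 = EndpointMarginals(summary.p0_hat_2, or2)
    rho = float(joint_bounds_both_arms(e1, e2).clip(summary.rho_hat))
    d = decision_ratio(e1, e2, rho, cfg)
    selected = "composite" if d >= 1.0 else "relevant"
    if not cfg.reassess:
        if n_planned is None:
            raise InvalidParameterError("n_planned is required when reassessment is disabled")
        return DecisionOutcome(d, selected, int(max(n_planned, n_recruited)), 2 if selected == "composite" else 1)
    if selected == "composite":
        size = ss_composite(e1, e2, rho, cfg)
    else:
        size = ss_binary(summary.p0_hat_1, or1, cfg)
    n_a = max(int(n_recruited), size.n_total)
    if n_max is not None:
        n_a = min(n_a, max(int(n_max), int(n_recruited)))
    return DecisionOutcome(d, selected, n_a, 2 if selected == "composite" else 1)


def recursive_selection(
    indicators: np.ndarray,
    ors: Sequence[float],
    cfg: DesignConfig,
    n0_blind: int,
    n1_blind: int,
    n_recruited: Optional[int] = None,
) -> DecisionOutcome:
    """Stepwise endpoint construction for K >= 2 components ordered by importance.

    ``indicators`` is the pooled 0/1 response matrix of shape ``(n_blind, K)``
    with columns ordered by decreasing clinical importance; storing all
    component indicators per subject provides the union counts each step
    needs.  Step i compares the running endpoint (component 1 or the composite
    built so far) against its union with component i+1: the pooled counts of
    both and of their union feed the two-endpoint blinded estimator, with the
    running composite's derived odds ratio as its assumed effect.  The first
    comparison with d < 1 stops the growth; otherwise the composite absorbs the
    next component and its parameters are recomputed for the following step.
    The final step reassesses the sample size for the selected endpoint.
    """
    indicators = np.asarray(indicators)
    if indicators.ndim != 2 or indicators.shape[1] < 2:
        raise InvalidParameterError("indicators must be (n_blind, K) with K >= 2")
    if not np.isin(indicators, (0, 1)).all():
        raise InvalidParameterError("indicators must be 0/1")
    n, k = indicators.shape
    if n != n0_blind + n1_blind:
        raise SchemaError(f"n0_blind+n1_blind={n0_blind + n1_blind} != rows of indicators ({n})")
    if len(ors) != k:
        raise InvalidParameterError(f"need {k} odds ratios, got {len(ors)}")
    if n_recruited is None:
        n_recruited = n

    cur = indicators[:, 0].astype(bool)
    or_cur = float(ors[0])
    d = np.nan
    n_components = 1
    sel_p0, sel_or = None, None
    for i in range(1, k):
        nxt = indicators[:, i].astype(bool)
        counts = PooledCounts(
            n0_blind, n1_blind,
            x1=int(cur.sum()), x2=int(nxt.sum()), x_star=int((cur | nxt).sum()),
        )
        summ = estimate_rho(counts, or_cur, float(ors[i]), floor_zero=cfg.rho_floor_zero)
        e_a = EndpointMarginals(summ.p0_hat_1, or_cur)
        e_b = EndpointMarginals(summ.p0_hat_2, float(ors[i]))
        rho = float(joint_bounds_both_arms(e_a, e_b).clip(summ.rho_hat))
        d = decision_ratio(e_a, e_b, rho, cfg)
        if d < 1.0:
            sel_p0, sel_or = summ.p0_hat_1, or_cur
            break
        comp = composite_or(e_a, e_b, rho)
        cur = cur | nxt
        or_cur = comp.or_star
        sel_p0, sel_or = comp.p0_star, comp.or_star
        n_components = i + 1

    size = ss_binary(sel_p0, sel_or, cfg)
    n_a = max(int(n_recruited), size.n_total)
    selected = "relevant" if n_components == 1 else "composite"
    return DecisionOutcome(float(d), selected, n_a, n_components)


def multiarm_blinded_pool(
    counts: PooledCounts,
    or1,
    or2,
    cfg: DesignConfig,
) -> BlindedSummary:
    """Blinded estimation when M treatment arms share one control.

    Assumes equal prespecified odds ratios (and correlation) across treatment
    arms — then the pooled rate is ``pi*p0 + (1-pi)*p1`` exactly as in the
    two-arm case with ``pi`` the control fraction, and the two-arm estimator
    applies unchanged; the resulting decision is shared by all arms.  Per-arm
    odds-ratio sequences must be constant or the configuration is rejected.
    """

    def _shared(or_k, name):
        if np.ndim(or_k) == 0:
            return float(or_k)
        vals = np.asarray(or_k, dtype=float)
        if vals.size != cfg.n_arms:
            raise UnsupportedConfigurationError(
                f"{name}: expected {cfg.n_arms} per-arm values, got {vals.size}"
            )
        if not np.allclose(vals, vals[0]):
            raise UnsupportedConfigurationError(
                f"{name}: blinded pooling requires equal assumed odds ratios across arms"
            )
        return float(vals[0])

    return estimate_rho(
        counts, _shared(or1, "or1"), _shared(or2, "or2"), floor_zero=cfg.rho_floor_zero
    )
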