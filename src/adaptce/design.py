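"""Sample-size formulas for the one-sided log-odds-ratio test and the endpoint
decision rule.

The trial tests H: OR = 1 against K: OR < 1 with the z statistic

    T = log(OR_hat) / sqrt( 1/(n0*p0_hat*q0_hat) + 1/(n1*p1_hat*q1_hat) ),

rejecting when T < z_alpha (lower-tail quantile).  Solving the power condition
for the total sample size n = n0 + n1 with control allocation pi = n0/n gives

    N = ((z_alpha + z_beta) / log(OR))^2 * ( 1/(pi*p0*q0) + 1/((1-pi)*p1*q1) ),

where the z's enter through their magnitudes.  Fed the composite parameters
(control union probability and derived composite odds ratio) the same formula
sizes the composite design; fed a single component's parameters it sizes the
single-endpoint design.

The decision rule compares the two requirements through the ratio
``d = N_relevant / N_composite`` computed from *unrounded* sizes: ``d < 1``
selects the relevant endpoint alone, ``d >= 1`` the composite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .composite import EndpointMarginals, composite_or, joint_bounds_both_arms
from .exceptions import InvalidParameterError, UndefinedSampleSizeError

__all__ = [
    "DesignConfig",
    "SampleSizeResult",
    "InterimRecommendation",
    "ss_binary",
    "ss_composite",
    "decision_ratio",
    "ss_multiarm",
    "interim_timing",
    "nraw_binary",
    "nraw_composite",
]


@dataclass(frozen=True)
class DesignConfig:
    """Design constants of the trial.

    Parameters
    ----------
    alpha : float
        One-sided significance level (per family; divided by ``n_arms`` for
        each comparison in a multi-arm trial).
    beta : float
        Type-II error; target power is ``1 - beta``.
    pi : float
        Allocation fraction to the control arm, ``n0/n``.
    omega : float
        Fraction of the planned sample observed at the blinded interim look;
        ``omega = 1`` means selection at the planned end.
    rho_design : float
        Correlation assumed at the planning stage (0 is the conservative
        choice for composite sizing: the composite size is smallest there).
    n_arms : int
        Number of treatment arms M compared against the shared control.
    reassess : bool
        Whether the interim look may change the sample size.
    rho_floor_zero : bool
        If True, the blinded correlation estimate is floored at 0 (use when
        only non-negatively correlated components are plausible).
    """

    alpha: float = 0.05
    beta: float = 0.2
    pi: float = 0.5
    omega: float = 0.5
    rho_design: float = 0.0
    n_arms: int = 1
    reassess: bool = True
    rho_floor_zero: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise InvalidParameterError(f"alpha must be in (0, 0.5); got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise InvalidParameterError(f"beta must be in (0, 1); got {self.beta}")
        if not 0.0 < self.pi < 1.0:
            raise InvalidParameterError(f"pi must be in (0, 1); got {self.pi}")
        if not 0.0 < self.omega <= 1.0:
            raise InvalidParameterError(f"omega must be in (0, 1]; got {self.omega}")
        if not (isinstance(self.n_arms, (int, np.integer)) and self.n_arms >= 1):
            raise InvalidParameterError(f"n_arms must be an integer >= 1; got {self.n_arms}")

    @property
    def alpha_comparison(self) -> float:
        """Per-comparison significance level (Bonferroni over treatment arms)."""
        return self.alpha / self.n_arms

    def with_(self, **kwargs) -> "DesignConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SampleSizeResult:
    """A required sample size, raw and rounded.

    ``n_raw`` is the unrounded analytic total; per-arm sizes are ceilings of
    the allocation split (preserving the power target), and ``n_total`` their
    sum.  For a multi-arm result ``n_treat`` is the size of *each* treatment
    arm.
    """

    n_raw: float
    n_control: int
    n_treat: int
    n_total: int


@dataclass(frozen=True)
class InterimRecommendation:
    """Recommended interim size and protocol maximum.

    ``n_tilde`` is the smaller of the single-endpoint requirement and the
    composite requirement at rho = 0 (the composite's minimum over rho >= 0),
    so the blinded look happens no later than the smallest plausible trial.
    ``n_max`` is the larger of the two requirements at the largest feasible
    correlation, bounding the reassessed size.
    """

    n_tilde: int
    n_max: int
    n_relevant: SampleSizeResult
    n_composite_rho0: SampleSizeResult


def _zsum(alpha: float, beta: float) -> float:
    # magnitudes of the two normal quantiles
    return float(norm.isf(alpha) + norm.isf(beta))


def nraw_binary(p0, or_, alpha, beta, pi):
    """Unrounded total sample size for the one-sided log-OR test (array-friendly)."""
    p0 = np.asarray(p0, dtype=float)
    or_ = np.asarray(or_, dtype=float)
    p1 = or_ * p0 / (1.0 - p0 + or_ * p0)
    zz = _zsum(alpha, beta)
    with np.errstate(divide="ignore"):
        out = (zz / np.log(or_)) ** 2 * (
            1.0 / (pi * p0 * (1.0 - p0)) + 1.0 / ((1.0 - pi) * p1 * (1.0 - p1))
        )
    return float(out) if out.ndim == 0 else out


def nraw_composite(p10, p20, or1, or2, rho, alpha, beta, pi):
    """Unrounded total composite-design size from component parameters (array-friendly).

    Derives both arms' union probabilities with the shared rho (assumed
    pre-clamped to the feasible range when arrays are passed), the composite
    odds ratio, and applies the binary-size formula.
    """
    p10 = np.asarray(p10, dtype=float)
    p20 = np.asarray(p20, dtype=float)
    rho = np.asarray(rho, dtype=float)
    p11_ = np.asarray(or1, dtype=float) * p10 / (1.0 - p10 + np.asarray(or1) * p10)
    p21_ = np.asarray(or2, dtype=float) * p20 / (1.0 - p20 + np.asarray(or2) * p20)
    q10, q20, q11_, q21_ = 1.0 - p10, 1.0 - p20, 1.0 - p11_, 1.0 - p21_
    p0s = 1.0 - q10 * q20 - rho * np.sqrt(p10 * q10 * p20 * q20)
    p1s = 1.0 - q11_ * q21_ - rho * np.sqrt(p11_ * q11_ * p21_ * q21_)
    eps = 1e-12
    p0s = np.clip(p0s, eps, 1.0 - eps)
    p1s = np.clip(p1s, eps, 1.0 - eps)
    or_star = (p1s / (1.0 - p1s)) / (p0s / (1.0 - p0s))
    zz = _zsum(alpha, beta)
    with np.errstate(divide="ignore"):
        out = (zz / np.log(or_star)) ** 2 * (
            1.0 / (pi * p0s * (1.0 - p0s)) + 1.0 / ((1.0 - pi) * p1s * (1.0 - p1s))
        )
    return float(out) if out.ndim == 0 else out


def _round_result(n_raw: float, pi: float) -> SampleSizeResult:
    n_control = max(2, math.ceil(pi * n_raw - 1e-9))
    n_treat = max(2, math.ceil((1.0 - pi) * n_raw - 1e-9))
    return SampleSizeResult(float(n_raw), n_control, n_treat, n_control + n_treat)


def ss_binary(p0: float, or_: float, cfg: DesignConfig) -> SampleSizeResult:
    """Required total sample size for a single binary endpoint.

    Applies equally to a component (fed its control probability and odds
    ratio) and to the composite (fed the union probability and derived
    composite odds ratio).  Uses the per-comparison level ``alpha/n_arms``.
    """
    if not 0.0 < p0 < 1.0:
        raise InvalidParameterError(f"p0 must be in (0, 1); got {p0}")
    if or_ <= 0.0:
        raise InvalidParameterError(f"or_ must be positive; got {or_}")
    if abs(math.log(or_)) < 1e-12:
        raise UndefinedSampleSizeError("sample size undefined for OR = 1 (zero log-odds effect)")
    n_raw = nraw_binary(p0, or_, cfg.alpha_comparison, cfg.beta, cfg.pi)
    return _round_result(n_raw, cfg.pi)


def ss_composite(
    e1: EndpointMarginals, e2: EndpointMarginals, rho: float, cfg: DesignConfig
) -> SampleSizeResult:
    """Required total sample size for the composite design at correlation ``rho``."""
    comp = composite_or(e1, e2, rho)
    return ss_binary(comp.p0_star, comp.or_star, cfg)


def decision_ratio(
    e1: EndpointMarginals, e2: EndpointMarginals, rho: float, cfg: DesignConfig
) -> float:
    """Decision ratio ``d = N_relevant / N_composite`` from unrounded sizes.

    ``d < 1``: the relevant endpoint alone needs fewer subjects, select it.
    ``d >= 1``: the composite is at least as efficient, select the composite.
    Monotone non-increasing in rho (the composite size grows with rho).
    """
    n1 = ss_binary(e1.p0, e1.or_, cfg)
    ns = ss_composite(e1, e2, rho, cfg)
    return n1.n_raw / ns.n_raw


def ss_multiarm(base: SampleSizeResult, cfg: DesignConfig) -> SampleSizeResult:
    """Scale a per-comparison size to a shared-control trial with M treatment arms.

    ``N_M = N * (M - (M-1)*pi)``: the control is shared, each treatment arm is
    sized as in the two-arm comparison.  ``base`` must already be computed at
    the per-comparison level alpha/M (as :func:`ss_binary` does given ``cfg``).
    """
    m = cfg.n_arms
    factor = m - (m - 1) * cfg.pi
    n_raw = base.n_raw * factor
    n_control = max(2, math.ceil(cfg.pi * base.n_raw - 1e-9))
    n_treat = max(2, math.ceil((1.0 - cfg.pi) * base.n_raw - 1e-9))
    return SampleSizeResult(float(n_raw), n_control, n_treat, n_control + m * n_treat)


def interim_timing(
    e1: EndpointMarginals, e2: EndpointMarginals, cfg: DesignConfig
) -> InterimRecommendation:
    """Recommended interim size ``min(N_relevant, N_composite(rho=0))`` and the maximum bound.

    The composite requirement is smallest at rho = 0 (over non-negative
    correlations), so the minimum of the two sizes is the smallest sample the
    trial could end with; scheduling the blinded look there guarantees it
    happens.  The maximum bound evaluates both designs at the largest feasible
    correlation.
    """
    n1 = ss_binary(e1.p0, e1.or_, cfg)
    ns0 = ss_composite(e1, e2, 0.0, cfg)
    rho_hi = joint_bounds_both_arms(e1, e2).upper
    ns_hi = ss_composite(e1, e2, rho_hi - 1e-9, cfg)
    n_max = max(n1.n_total, ns_hi.n_total)
    return InterimRecommendation(
        n_tilde=min(n1.n_total, ns0.n_total),
        n_max=int(n_max),
        n_relevant=n1,
        n_composite_rho0=ns0,
    )
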