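"""Closed-form links between two binary endpoints and their union composite.

Two binary events observed on the same subject are described by their marginal
probabilities ``(p1, p2)`` and the Pearson correlation ``rho`` between the 0/1
indicators.  The composite event ("either occurs") then has probability

    p_star = 1 - q1*q2 - rho*sqrt(p1*q1*p2*q2),        q_k = 1 - p_k,

which is the union probability written through the joint 2x2 table with success
cell ``p11 = p1*p2 + rho*sqrt(p1*q1*p2*q2)``.  Every association measure used
here (correlation, conditional probability) is a function of ``(p1, p2, p11)``,
so the joint table is the canonical intermediate representation.

Treatment effects are parameterised by odds ratios.  The correlation is assumed
equal in both arms, so the composite's odds ratio is determined by the control
probabilities, the component odds ratios, and the shared ``rho``.

All scalar functions also accept numpy arrays (elementwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InfeasibleCorrelationError, InvalidParameterError

__all__ = [
    "EndpointMarginals",
    "CompositeParams",
    "CorrelationBounds",
    "treatment_prob",
    "composite_prob",
    "composite_or",
    "correlation_bounds",
    "joint_bounds_both_arms",
    "joint_cells",
    "rho_from_joint",
    "rho_from_conditional",
    "conditional_from_rho",
]

#: Tolerance used by feasibility checks: a correlation may sit on a Frechet
#: boundary, and floating-point noise up to this amount is absorbed before the
#: joint cells are clipped at zero.
FEASIBILITY_TOL = 1e-9


def _check_prob(p, name: str) -> None:
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p >= 1.0):
        raise InvalidParameterError(f"{name} must lie strictly in (0, 1); got {p}")


def _check_or(or_, name: str = "or_") -> None:
    or_ = np.asarray(or_, dtype=float)
    if np.any(~np.isfinite(or_)) or np.any(or_ <= 0.0):
        raise InvalidParameterError(f"{name} must be a positive odds ratio; got {or_}")


@dataclass(frozen=True)
class EndpointMarginals:
    """Marginal description of one binary endpoint.

    Parameters
    ----------
    p0 : float
        Event probability in the control arm, strictly in (0, 1).
    or_ : float
        Odds ratio of treatment versus control, strictly positive.
        Values below 1 denote a beneficial treatment (fewer events).
    """

    p0: float
    or_: float

    def __post_init__(self) -> None:
        _check_prob(self.p0, "p0")
        _check_or(self.or_)

    @property
    def p1(self) -> float:
        """Event probability in the treatment arm implied by (p0, or_)."""
        return float(treatment_prob(self.p0, self.or_))


@dataclass(frozen=True)
class CompositeParams:
    """Composite-endpoint parameters derived from two components and a shared rho."""

    p0_star: float
    p1_star: float
    or_star: float
    rho: float


@dataclass(frozen=True)
class CorrelationBounds:
    """Feasible range of the Pearson correlation between two Bernoulli indicators."""

    lower: float
    upper: float

    def __contains__(self, rho: float) -> bool:
        return self.lower - FEASIBILITY_TOL <= rho <= self.upper + FEASIBILITY_TOL

    def clip(self, rho):
        """Clamp ``rho`` (scalar or array) into the feasible interval."""
        return np.clip(rho, self.lower, self.upper)


def treatment_prob(p0, or_):
    """Treatment-arm event probability implied by a control probability and odds ratio.

    Inverts ``OR = (p1/q1)/(p0/q0)`` for ``p1``:  ``p1 = OR*p0 / (q0 + OR*p0)``.
    Strictly increasing in both arguments.
    """
    _check_prob(p0, "p0")
    _check_or(or_)
    p0 = np.asarray(p0, dtype=float)
    or_ = np.asarray(or_, dtype=float)
    out = or_ * p0 / (1.0 - p0 + or_ * p0)
    return float(out) if out.ndim == 0 else out


def correlation_bounds(p1, p2) -> CorrelationBounds:
    """Feasible Pearson-correlation range for Bernoulli marginals ``(p1, p2)``.

    The joint success cell ``p11`` is constrained by the Frechet bounds
    ``max(0, p1+p2-1) <= p11 <= min(p1, p2)``; mapping those extremes through
    ``rho = (p11 - p1*p2)/sqrt(p1*q1*p2*q2)`` gives

        upper = min( sqrt(p1*q2/(p2*q1)), sqrt(p2*q1/(p1*q2)) )
        lower = max( -sqrt(p1*p2/(q1*q2)), -sqrt(q1*q2/(p1*p2)) )

    Zero (independence) is always inside the interval.
    """
    _check_prob(p1, "p1")
    _check_prob(p2, "p2")
    q1, q2 = 1.0 - p1, 1.0 - p2
    upper = min(np.sqrt(p1 * q2 / (p2 * q1)), np.sqrt(p2 * q1 / (p1 * q2)))
    lower = max(-np.sqrt(p1 * p2 / (q1 * q2)), -np.sqrt(q1 * q2 / (p1 * p2)))
    return CorrelationBounds(float(min(lower, 0.0)), float(min(upper, 1.0)))


def _require_feasible(p1, p2, rho) -> None:
    b = correlation_bounds(p1, p2)
    if not (b.lower - FEASIBILITY_TOL <= rho <= b.upper + FEASIBILITY_TOL):
        raise InfeasibleCorrelationError(
            f"rho={rho} outside feasible range [{b.lower:.6g}, {b.upper:.6g}] "
            f"for marginals ({p1}, {p2})"
        )


def joint_cells(p1, p2, rho, *, check: bool = True):
    """Joint 2x2 cell probabilities ``(p11, p10, p01, p00)`` for given marginals and rho.

    ``p11 = p1*p2 + rho*sqrt(p1*q1*p2*q2)``; the remaining cells follow from the
    marginals.  With ``check=False`` the caller guarantees feasibility and cells
    are merely clipped at zero (used on pre-clamped vectorised inputs).
    """
    if check:
        _check_prob(p1, "p1")
        _check_prob(p2, "p2")
        if np.ndim(rho) == 0 and np.ndim(p1) == 0 and np.ndim(p2) == 0:
            _require_feasible(float(p1), float(p2), float(rho))
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    q1, q2 = 1.0 - p1, 1.0 - p2
    p11 = p1 * p2 + rho * np.sqrt(p1 * q1 * p2 * q2)
    p11 = np.clip(p11, 0.0, np.minimum(p1, p2))
    p10 = np.clip(p1 - p11, 0.0, None)
    p01 = np.clip(p2 - p11, 0.0, None)
    p00 = np.clip(1.0 - p1 - p2 + p11, 0.0, None)
    if p11.ndim == 0:
        return float(p11), float(p10), float(p01), float(p00)
    return p11, p10, p01, p00


def rho_from_joint(p1, p2, p11):
    """Pearson correlation implied by marginals and the joint success cell ``p11``."""
    _check_prob(p1, "p1")
    _check_prob(p2, "p2")
    p11 = np.asarray(p11, dtype=float)
    lo = np.maximum(0.0, np.asarray(p1) + np.asarray(p2) - 1.0)
    hi = np.minimum(p1, p2)
    if np.any(p11 < lo - FEASIBILITY_TOL) or np.any(p11 > hi + FEASIBILITY_TOL):
        raise InfeasibleCorrelationError(
            f"p11={p11} outside Frechet bounds [{lo}, {hi}] for marginals ({p1}, {p2})"
        )
    q1, q2 = 1.0 - p1, 1.0 - p2
    out = (p11 - p1 * p2) / np.sqrt(p1 * q1 * p2 * q2)
    return float(out) if out.ndim == 0 else out


def rho_from_conditional(p1, p2, cond):
    """Correlation implied by ``cond = P(event 2 | event 1)``.

    Goes through the joint table: ``p11 = cond*p1``, then
    ``rho = (p11 - p1*p2)/sqrt(p1*q1*p2*q2)``.
    """
    if not 0.0 <= cond <= 1.0:
        raise InvalidParameterError(f"conditional probability must be in [0, 1]; got {cond}")
    return rho_from_joint(p1, p2, cond * p1)


def conditional_from_rho(p1, p2, rho):
    """Inverse of :func:`rho_from_conditional`: ``P(event 2 | event 1)`` from rho."""
    p11 = joint_cells(p1, p2, rho)[0]
    return p11 / p1


def composite_prob(p1, p2, rho, *, check: bool = True):
    """Probability of the union (composite) event for one arm.

    ``p_star = 1 - q1*q2 - rho*sqrt(p1*q1*p2*q2)``.  Decreasing in rho: the more
    the components overlap, the less the union adds over a single component.
    """
    if check:
        _check_prob(p1, "p1")
        _check_prob(p2, "p2")
        if np.ndim(rho) == 0 and np.ndim(p1) == 0 and np.ndim(p2) == 0:
            _require_feasible(float(p1), float(p2), float(rho))
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    q1, q2 = 1.0 - p1, 1.0 - p2
    out = 1.0 - q1 * q2 - rho * np.sqrt(p1 * q1 * p2 * q2)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def composite_or(e1: EndpointMarginals, e2: EndpointMarginals, rho: float) -> CompositeParams:
    """Composite probability in both arms and the composite odds ratio.

    The correlation is shared across arms, so ``rho`` must be feasible for the
    control marginals and for the treatment marginals implied by the odds
    ratios.  The composite odds ratio is derived, not assumed:
    ``OR_star = (p1_star/q1_star) / (p0_star/q0_star)``.
    """
    p0_star = composite_prob(e1.p0, e2.p0, rho)
    p1_star = composite_prob(e1.p1, e2.p1, rho)
    if not (0.0 < p0_star < 1.0) or not (0.0 < p1_star < 1.0):
        raise InfeasibleCorrelationError(
            f"composite probability degenerate (p0*={p0_star}, p1*={p1_star}) at rho={rho}"
        )
    or_star = (p1_star / (1.0 - p1_star)) / (p0_star / (1.0 - p0_star))
    return CompositeParams(p0_star, p1_star, float(or_star), float(rho))


def joint_bounds_both_arms(e1: EndpointMarginals, e2: EndpointMarginals) -> CorrelationBounds:
    """Intersection of the per-arm feasible correlation ranges.

    Needed because the design assumes one correlation shared by both arms.  The
    intersection is never empty: independence (rho = 0) is feasible in any arm.
    """
    b0 = correlation_bounds(e1.p0, e2.p0)
    b1 = correlation_bounds(e1.p1, e2.p1)
    return CorrelationBounds(max(b0.lower, b1.lower), min(b0.upper, b1.upper))
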