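"""Blinded estimators, endpoint selection, reassessment, and the recursive rule.

Population-level checks feed the estimators the exact pooled probabilities
implied by a known parameter set and require exact recovery; finite-sample
checks use simulated pooled counts and require consistency.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from adaptce import (
    BlindedSummary,
    DesignConfig,
    EndpointMarginals,
    PooledCounts,
    composite_prob,
    correlation_bounds,
    decision_ratio,
    draw_correlated_pair,
    estimate_from_rates,
    estimate_rho,
    joint_bounds_both_arms,
    multiarm_blinded_pool,
    recursive_selection,
    select_and_reassess,
    solve_control_prob,
    ss_binary,
    ss_composite,
    treatment_prob,
)
from adaptce.blinded import _estimate_vec
from adaptce.exceptions import (
    InvalidParameterError,
    SchemaError,
    UnsupportedConfigurationError,
)


def pooled_rates(p10, p20, or1, or2, rho, pi=0.5):
    """Exact population pooled probabilities for a parameter set."""
    p11 = treatment_prob(p10, or1)
    p21 = treatment_prob(p20, or2)
    ps0 = composite_prob(p10, p20, rho)
    ps1 = composite_prob(p11, p21, rho)
    mix = lambda a, b: pi * a + (1 - pi) * b
    return mix(p10, p11), mix(p20, p21), mix(ps0, ps1)


class TestPooledCounts:
    def test_union_count_below_components_rejected(self):
        with pytest.raises(SchemaError):
            PooledCounts(50, 50, x1=30, x2=20, x_star=25)

    def test_union_count_above_sum_rejected(self):
        with pytest.raises(SchemaError):
            PooledCounts(50, 50, x1=30, x2=20, x_star=60)

    def test_counts_above_n_rejected(self):
        with pytest.raises(SchemaError):
            PooledCounts(50, 50, x1=130, x2=20, x_star=130)

    def test_carries_no_arm_labelled_responses(self):
        """Blindness by construction: the estimator input type holds only
        pooled counts and design-known arm sizes."""
        names = {f.name for f in dataclasses.fields(PooledCounts)}
        assert names == {"n0_blind", "n1_blind", "x1", "x2", "x_star"}


class TestSolveControlProb:
    def test_or_one_gives_pooled_rate(self):
        p0, p1 = solve_control_prob(0.5, 1.0, 0.5)
        assert p0 == pytest.approx(0.5, abs=1e-10)
        assert p1 == pytest.approx(0.5, abs=1e-10)

    def test_dialysis_forward_backward(self):
        p_hat = 0.5 * 0.615 + 0.5 * treatment_prob(0.615, 0.52)
        p0, p1 = solve_control_prob(p_hat, 0.52, 0.5)
        assert p0 == pytest.approx(0.615, abs=1e-10)

    @given(
        p0=st.floats(0.02, 0.98),
        or_=st.floats(0.1, 10.0),
        pi=st.floats(0.2, 0.8),
    )
    def test_roundtrip_contract(self, p0, or_, pi):
        """The solved root must reproduce the pooled rate to 1e-10."""
        p_hat = pi * p0 + (1 - pi) * treatment_prob(p0, or_)
        p0_hat, p1_hat = solve_control_prob(p_hat, or_, pi)
        forward = pi * p0_hat + (1 - pi) * p1_hat
        assert forward == pytest.approx(p_hat, abs=1e-10)
        assert p0_hat == pytest.approx(p0, abs=1e-8)

    def test_boundary_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            solve_control_prob(1.0, 0.6, 0.5)


class TestEstimateRho:
    def test_exact_inversion_population_level(self, rng):
        """Fed exact pooled rates, the estimator returns the truth to 1e-10."""
        for _ in range(50):
            p10, p20 = rng.uniform(0.05, 0.9, size=2)
            or1, or2 = rng.uniform(0.3, 1.8, size=2)
            e1, e2 = EndpointMarginals(p10, or1), EndpointMarginals(p20, or2)
            b = joint_bounds_both_arms(e1, e2)
            rho = rng.uniform(b.lower + 0.01, b.upper - 0.01)
            s = estimate_from_rates(*pooled_rates(p10, p20, or1, or2, rho), or1, or2)
            assert s.p0_hat_1 == pytest.approx(p10, abs=1e-8)
            assert s.p0_hat_2 == pytest.approx(p20, abs=1e-8)
            assert s.rho_hat == pytest.approx(rho, abs=1e-7)

    def test_zero_numerator_gives_zero_rho(self):
        """Counts consistent with the independence mixture estimate rho = 0."""
        p1h, p2h, psh = pooled_rates(0.3, 0.2, 0.7, 0.8, 0.0)
        s = estimate_from_rates(p1h, p2h, psh, 0.7, 0.8)
        assert s.rho_hat == pytest.approx(0.0, abs=1e-9)

    def test_large_sample_recovery(self, rng):
        p10, p20, or1, or2, rho = 0.2, 0.25, 0.6, 0.75, 0.3
        p11, p21 = treatment_prob(p10, or1), treatment_prob(p20, or2)
        n_arm = 500_000
        c0 = rng.multinomial(n_arm, _cells(p10, p20, rho))
        c1 = rng.multinomial(n_arm, _cells(p11, p21, rho))
        counts = PooledCounts(
            n_arm, n_arm,
            x1=int(c0[0] + c0[1] + c1[0] + c1[1]),
            x2=int(c0[0] + c0[2] + c1[0] + c1[2]),
            x_star=int(2 * n_arm - c0[3] - c1[3]),
        )
        s = estimate_rho(counts, or1, or2)
        assert s.rho_hat == pytest.approx(rho, abs=0.01)

    def test_consistency_small_bias(self, rng):
        """Mean estimate over replicates at n=1e5 is within 0.02 of the truth."""
        n_arm = 50_000
        reps = 100
        for p10, p20, or1, or2, rho in [
            (0.2, 0.25, 0.6, 0.75, 0.3),
            (0.1, 0.1, 0.8, 0.8, 0.0),
            (0.615, 0.15, 0.52, 0.66, 0.2),
            (0.3, 0.4, 0.7, 0.9, -0.2),
        ]:
            p11, p21 = treatment_prob(p10, or1), treatment_prob(p20, or2)
            c0 = rng.multinomial(n_arm, _cells(p10, p20, rho), size=reps)
            c1 = rng.multinomial(n_arm, _cells(p11, p21, rho), size=reps)
            est = _estimate_vec(
                c0[:, 0] + c0[:, 1] + c1[:, 0] + c1[:, 1],
                c0[:, 0] + c0[:, 2] + c1[:, 0] + c1[:, 2],
                2 * n_arm - c0[:, 3] - c1[:, 3],
                n_arm, n_arm, or1, or2,
            )
            assert abs(np.mean(est["rho_hat"]) - rho) < 0.02

    def test_pi_mismatch_rejected(self):
        counts = PooledCounts(60, 40, x1=20, x2=10, x_star=25)
        with pytest.raises(SchemaError):
            estimate_rho(counts, 0.7, 0.8, pi=0.5)

    def test_degenerate_counts_stay_defined(self):
        counts = PooledCounts(10, 10, x1=0, x2=20, x_star=20)
        s = estimate_rho(counts, 0.7, 0.8)
        assert np.isfinite(s.rho_hat)
        assert 0.0 < s.p0_hat_1 < 1.0

    def test_rho_floor_zero_option(self):
        p1h, p2h, psh = pooled_rates(0.3, 0.4, 0.7, 0.9, -0.2)
        s = estimate_from_rates(p1h, p2h, psh, 0.7, 0.9, floor_zero=True)
        assert s.rho_hat == 0.0
        assert s.rho_hat_raw == pytest.approx(-0.2, abs=1e-7)


def _cells(p1, p2, rho):
    from adaptce import joint_cells

    return np.array(joint_cells(p1, p2, rho))


class TestSelectAndReassess:
    def _summary(self, p10, p20, or1, or2, rho):
        return estimate_from_rates(*pooled_rates(p10, p20, or1, or2, rho), or1, or2)

    def test_low_correlation_selects_composite(self, cfg):
        s = self._summary(0.615, 0.15, 0.52, 0.66, 0.1)
        out = select_and_reassess(s, 0.52, 0.66, cfg, n_recruited=100)
        assert out.selected == "composite"
        assert out.d_value >= 1.0

    def test_high_correlation_selects_relevant(self, cfg):
        """An estimate beyond the feasible range is clamped, not fatal, and the
        clamped value still selects the relevant endpoint."""
        s = self._summary(0.615, 0.15, 0.52, 0.66, 0.3)
        s = dataclasses.replace(s, rho_hat=0.4)  # outside the feasible range
        out = select_and_reassess(s, 0.52, 0.66, cfg, n_recruited=232)
        assert out.selected == "relevant"
        n1 = ss_binary(s.p0_hat_1, 0.52, cfg)
        assert out.n_a == max(232, n1.n_total)

    def test_never_below_recruited(self, cfg):
        s = self._summary(0.615, 0.15, 0.52, 0.66, 0.0)
        out = select_and_reassess(s, 0.52, 0.66, cfg, n_recruited=300)
        assert out.n_a == 300  # recomputed size 232 < already recruited

    def test_reassessment_disabled_keeps_plan(self, cfg):
        s = self._summary(0.615, 0.15, 0.52, 0.66, 0.0)
        out = select_and_reassess(
            s, 0.52, 0.66, cfg.with_(reassess=False), n_recruited=120, n_planned=240
        )
        assert out.n_a == 240

    def test_cap_applies(self, cfg):
        s = self._summary(0.1, 0.1, 0.95, 0.95, 0.0)  # tiny effect -> huge size
        out = select_and_reassess(s, 0.95, 0.95, cfg, n_recruited=100, n_max=5000)
        assert out.n_a == 5000


class TestRecursiveSelection:
    def _pooled_matrix(self, p10, p20, or1, or2, rho, n_arm, seed):
        a0 = draw_correlated_pair(p10, p20, rho, n_arm, seed)
        a1 = draw_correlated_pair(
            treatment_prob(p10, or1), treatment_prob(p20, or2), rho, n_arm, seed + 1
        )
        return np.vstack([a0, a1])

    def test_two_components_reduces_to_pairwise_rule(self, cfg):
        m = self._pooled_matrix(0.615, 0.15, 0.52, 0.66, 0.1, 600, seed=5)
        counts = PooledCounts(
            600, 600,
            x1=int(m[:, 0].sum()), x2=int(m[:, 1].sum()), x_star=int(m.any(axis=1).sum()),
        )
        summary = estimate_rho(counts, 0.52, 0.66)
        direct = select_and_reassess(summary, 0.52, 0.66, cfg, n_recruited=1200)
        rec = recursive_selection(m, [0.52, 0.66], cfg, 600, 600)
        assert rec.selected == direct.selected
        assert rec.d_value == pytest.approx(direct.d_value, rel=1e-12)
        assert rec.n_a == direct.n_a

    def test_null_overlapping_third_component_is_refused(self, cfg):
        """A third component with no assumed effect that duplicates an existing
        one dilutes the composite effect without adding events, so the
        recursion stops at two components."""
        m2 = self._pooled_matrix(0.615, 0.15, 0.52, 0.66, 0.0, 2000, seed=7)
        m = np.column_stack([m2, m2[:, 1]])  # third indicator == second
        rec = recursive_selection(m, [0.52, 0.66, 1.0], cfg, 2000, 2000)
        assert rec.n_components == 2
        assert rec.selected == "composite"

    def test_independent_affected_third_component_is_absorbed(self, cfg, rng):
        """An uncorrelated component with a real assumed effect lowers the
        composite requirement, so the full three-component union is selected."""
        m2 = self._pooled_matrix(0.615, 0.15, 0.52, 0.66, 0.0, 2000, seed=11)
        p3 = np.concatenate([
            rng.binomial(1, 0.25, 2000),
            rng.binomial(1, treatment_prob(0.25, 0.5), 2000),
        ])
        m = np.column_stack([m2, p3])
        rec = recursive_selection(m, [0.52, 0.66, 0.5], cfg, 2000, 2000)
        assert rec.n_components == 3
        assert rec.d_value >= 1.0

    def test_input_validation(self, cfg):
        with pytest.raises(InvalidParameterError):
            recursive_selection(np.zeros((10, 1)), [0.5], cfg, 5, 5)
        with pytest.raises(SchemaError):
            recursive_selection(np.zeros((10, 2), dtype=int), [0.5, 0.6], cfg, 4, 4)


class TestMultiarmPool:
    def test_single_arm_reduces_to_two_arm_estimator(self):
        counts = PooledCounts(500, 500, x1=200, x2=150, x_star=300)
        cfg = DesignConfig(n_arms=1)
        a = multiarm_blinded_pool(counts, 0.6, 0.75, cfg)
        b = estimate_rho(counts, 0.6, 0.75)
        assert a == b

    def test_equal_or_sequences_accepted(self):
        counts = PooledCounts(400, 800, x1=300, x2=250, x_star=450)
        cfg = DesignConfig(pi=1 / 3, n_arms=2)
        a = multiarm_blinded_pool(counts, [0.6, 0.6], [0.75, 0.75], cfg)
        assert np.isfinite(a.rho_hat)

    def test_or_one_everywhere_equals_pool(self):
        counts = PooledCounts(400, 800, x1=300, x2=250, x_star=450)
        cfg = DesignConfig(pi=1 / 3, n_arms=2)
        s = multiarm_blinded_pool(counts, [1.0, 1.0], [1.0, 1.0], cfg)
        assert s.p0_hat_1 == pytest.approx(counts.x1 / counts.n_blind, abs=1e-9)
        assert s.p1_hat_1 == pytest.approx(s.p0_hat_1, abs=1e-12)

    def test_unequal_ors_rejected(self):
        counts = PooledCounts(400, 800, x1=300, x2=250, x_star=450)
        cfg = DesignConfig(pi=1 / 3, n_arms=2)
        with pytest.raises(UnsupportedConfigurationError):
            multiarm_blinded_pool(counts, [0.6, 0.8], [0.75, 0.75], cfg)

    def test_forward_map_roundtrip(self):
        """Reconstructed mixture reproduces the pooled rate (solver contract)."""
        counts = PooledCounts(400, 800, x1=300, x2=250, x_star=450)
        cfg = DesignConfig(pi=1 / 3, n_arms=2)
        s = multiarm_blinded_pool(counts, 0.6, 0.75, cfg)
        pi = 1 / 3
        forward = pi * s.p0_hat_1 + (1 - pi) * s.p1_hat_1
        assert forward == pytest.approx(counts.x1 / counts.n_blind, abs=1e-10)


class TestDecisionSummaryInvariants:
    def test_na_at_least_recruited_and_planned_when_omega_one(self, cfg, rng):
        """With selection at the planned end the size can only stay or grow."""
        for _ in range(10):
            p10, p20 = rng.uniform(0.1, 0.6, size=2)
            or1, or2 = rng.uniform(0.5, 0.9, size=2)
            e1, e2 = EndpointMarginals(p10, or1), EndpointMarginals(p20, or2)
            b = joint_bounds_both_arms(e1, e2)
            rho = rng.uniform(0.0, max(b.upper - 0.02, 0.01))
            n_planned = ss_binary(p10, or1, cfg).n_total
            s = estimate_from_rates(*pooled_rates(p10, p20, or1, or2, rho), or1, or2)
            out = select_and_reassess(s, or1, or2, cfg, n_recruited=n_planned)
            assert out.n_a >= n_planned
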