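"""Mean-field hierarchy: conservation, closed forms, Poisson steady state."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from damseg import (
    MeanFieldState,
    Mode,
    ModelParams,
    analytic_steady_state,
    compare_modes,
    integrate_to_steady,
    poisson_pmf,
    post_collapse_state,
    rhs,
)
from damseg.meanfield import damage_levels

P = ModelParams(n=100, epsilon=0.1, p=0.1, delta=0.2)


def make_state(x, mode):
    x = np.asarray(x, dtype=float)
    return MeanFieldState(x, len(x) - 1, Mode(mode))


class TestRhs:
    @pytest.mark.parametrize("mode", ["symmetric", "asymmetric"])
    def test_point_mass_without_mutation_is_stationary(self, mode):
        params = P.replace(p=0.0)
        x = np.zeros(10)
        x[0] = 1.0
        assert np.all(rhs(make_state(x, mode), params) == 0.0)

    @given(
        mode=st.sampled_from(list(Mode)),
        raw=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30).filter(
            lambda v: sum(v) > 1e-6
        ),
        p=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_conserves_total_fraction(self, mode, raw, p):
        """Homeostasis: every death is balanced by a birth, so the rates of
        change of the class fractions always sum to zero (for states that
        respect the truncation-adequacy invariant of an empty top class)."""
        x = np.append(np.array(raw) / sum(raw), 0.0)
        params = P.replace(p=p)
        assert abs(rhs(make_state(x, mode), params).sum()) < 1e-12

    def test_two_class_symmetric_rhs_matches_hand_expansion(self):
        # x = (0.9, 0.1): d = (0.1, 0.2), <d> = 0.11
        # dx0 = x0 (-d0 + (1-2p)<d>) ; dx1 = x1 (-d1 + (1-2p)<d>) + 2p<d> x0
        x = np.array([0.9, 0.1, 0.0])
        d = damage_levels(P, Mode.SYMMETRIC, 2)
        mean_d = float(d @ x)
        expected0 = 0.9 * (-0.1 + 0.8 * mean_d)
        expected1 = 0.1 * (-0.2 + 0.8 * mean_d) + 2 * 0.1 * mean_d * 0.9
        expected2 = 2 * 0.1 * mean_d * 0.1
        out = rhs(make_state(x, "symmetric"), P)
        assert out == pytest.approx([expected0, expected1, expected2])


class TestAnalyticSteadyState:
    @pytest.mark.parametrize("mode", ["symmetric", "asymmetric"])
    def test_no_mutation_keeps_initial_level(self, mode):
        ss = analytic_steady_state(P.replace(p=0.0), mode)
        assert ss.exists
        assert ss.d_star == pytest.approx(0.1)
        assert ss.lam == 0.0
        assert ss.x0 == 1.0

    def test_symmetric_closed_form(self):
        ss = analytic_steady_state(P, "symmetric")
        assert ss.d_star == pytest.approx(0.125)
        assert ss.lam == pytest.approx(0.25)
        assert ss.x0 == pytest.approx(math.exp(-0.25))

    def test_asymmetric_closed_form(self):
        ss = analytic_steady_state(P, "asymmetric")
        assert ss.d_star == pytest.approx(1 / 9)
        assert ss.lam == pytest.approx(0.1 * (1 / 9) / 0.2)  # p d*/delta
        assert ss.x0 == pytest.approx(math.exp(-ss.lam))

    @pytest.mark.parametrize(
        "mode,p", [("symmetric", 0.5), ("symmetric", 0.6), ("asymmetric", 1.0)]
    )
    def test_nonexistence_beyond_validity_region(self, mode, p):
        ss = analytic_steady_state(P.replace(p=p), mode)
        assert not ss.exists

    def test_nonexistence_when_d_star_exceeds_one(self):
        ss = analytic_steady_state(P.replace(epsilon=0.9, p=0.3), "symmetric")
        assert not ss.exists  # 0.9 / 0.4 > 1

    @given(
        eps=st.floats(0.01, 0.3),
        p=st.floats(0.0, 0.45),
        delta=st.floats(0.05, 1.0),
        mode=st.sampled_from(list(Mode)),
    )
    @settings(max_examples=200, deadline=None)
    def test_self_consistency_of_closed_form(self, eps, p, delta, mode):
        """d* = epsilon + s * lambda and x0 = exp(-lambda) wherever the
        steady state exists."""
        params = P.replace(epsilon=eps, p=p, delta=delta, mode=mode)
        ss = analytic_steady_state(params)
        if not ss.exists:
            return
        s = params.increment_step
        assert ss.d_star == pytest.approx(eps + s * ss.lam, abs=1e-12)
        assert ss.x0 == pytest.approx(math.exp(-ss.lam), abs=1e-12)


class TestIntegrateToSteady:
    def test_no_mutation_returns_point_mass(self):
        state = integrate_to_steady(P.replace(p=0.0), "symmetric", k_max=10)
        assert state.x[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["symmetric", "asymmetric"])
    def test_agrees_with_closed_form_distribution(self, mode):
        """Long integration of the hierarchy reproduces the Poisson steady
        state: same mean damage and sup-norm distance < 1e-6."""
        state = integrate_to_steady(P, mode, k_max=40)
        ss = analytic_steady_state(P, mode)
        assert state.mean_damage(P) == pytest.approx(ss.d_star, abs=1e-7)
        pois = poisson_pmf(ss.lam, 40)
        assert np.max(np.abs(state.x - pois)) < 1e-6
        assert abs(state.x.sum() - 1.0) < 1e-9

    def test_divergent_parameters_flagged(self):
        with pytest.raises(ValueError, match="steady state"):
            integrate_to_steady(
                P.replace(p=0.6), "symmetric", k_max=10, max_time=50.0
            )


class TestPoissonPmf:
    def test_zero_mean_is_point_mass(self):
        pmf = poisson_pmf(0.0, 10)
        assert pmf[0] == 1.0 and pmf[1:].sum() == 0.0

    def test_closed_form_and_normalization(self):
        pmf = poisson_pmf(0.25, 30)
        assert pmf[0] == pytest.approx(math.exp(-0.25))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)


class TestPostCollapse:
    def test_generation_zero_is_identity(self):
        assert post_collapse_state(P, "symmetric", 0) == analytic_steady_state(
            P, "symmetric"
        )

    def test_one_extinction_shifts_base_level(self):
        shifted = post_collapse_state(P, "symmetric", 1)
        direct = analytic_steady_state(P.replace(epsilon=0.2), "symmetric")
        assert shifted.d_star == pytest.approx(direct.d_star)
        assert shifted.lam == pytest.approx(direct.lam)

    def test_successive_states_less_stable(self):
        """Each extinction of the lowest class raises lambda, so the
        successor steady states decay ever faster."""
        lams = []
        for g in range(4):
            ss = post_collapse_state(P, "asymmetric", g)
            if ss.exists:
                lams.append(ss.lam)
        assert len(lams) >= 2
        assert all(b > a for a, b in zip(lams, lams[1:]))


class TestCompareModes:
    def test_asymmetric_dominates_at_reference_point(self):
        rep = compare_modes(P)
        assert rep.asym_less_damaged and rep.asym_more_pristine

    def test_modes_equal_without_mutation(self):
        rep = compare_modes(P.replace(p=0.0))
        assert rep.d_star_sym == rep.d_star_asym == pytest.approx(0.1)
        assert rep.x0_sym == rep.x0_asym == 1.0
        assert not rep.asym_less_damaged  # strict inequality fails at p = 0

    def test_symmetric_d_star_invariant_to_split_reading(self):
        """The symmetric steady-state mean damage depends only on the total
        new damage per mutated division, not on how it is split: treating
        the per-daughter increment as delta instead of delta/2 (i.e. total
        2*delta, matching a doubled fragility on the lattice) leaves d*
        unchanged and exactly halves lambda."""
        ss_half = analytic_steady_state(P, "symmetric")
        ss_full = analytic_steady_state(P.replace(delta=0.4), "symmetric")
        assert ss_full.d_star == pytest.approx(ss_half.d_star, abs=1e-12)
        assert ss_full.lam == pytest.approx(ss_half.lam / 2, abs=1e-12)
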