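"""Rate equations, frame quadratics, validity domains and the min rule."""

import math

import numpy as np
import pytest

from fvcbgeom import (
    DomainError,
    Frame,
    FvCBParams,
    LimitationState,
    ParameterError,
    PoleError,
    derive_kco,
    net_rate,
    net_rate_curve,
    quadratic_in_frame,
    rate_cc,
    rate_in_frame,
    valid_domain,
)
from fvcbgeom.params import KcoConstraintWarning

from conftest import random_params

STATES = [LimitationState.c, LimitationState.j, LimitationState.p]


class TestParams:
    def test_rejects_nonpositive_rates(self, worked_params):
        with pytest.raises(ParameterError):
            worked_params.replace(Vcmax=-1.0)
        with pytest.raises(ParameterError):
            worked_params.replace(rm=-0.1)
        with pytest.raises(ParameterError):
            worked_params.replace(alpha=1.5)

    def test_kco_constraint_is_warning_not_error(self, worked_params):
        with pytest.warns(KcoConstraintWarning):
            p = worked_params.replace(Kco=7.0)  # below 2*Gamma_star = 7.48
        assert p.Kco == 7.0

    def test_unknown_keys_rejected(self):
        with pytest.raises(ParameterError, match="Jmax"):
            FvCBParams.from_mapping({"Vcmax": 100, "Jmax": 150})

    @pytest.mark.parametrize(
        "kc,ko,o,expected",
        [(40.0, 28000.0, 21000.0, 70.0), (5.0, 100.0, 0.0, 5.0), (1.0, 1.0, 1.0, 2.0)],
    )
    def test_derive_kco(self, kc, ko, o, expected):
        assert derive_kco(kc, ko, o) == pytest.approx(expected, rel=1e-12)

    def test_derive_kco_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            derive_kco(-1.0, 100.0, 10.0)


class TestRateCc:
    def test_worked_rubisco_value(self, worked_params):
        # 100·(30 − 3.74)/(30 + 62.1) − 2, hand-evaluated
        assert rate_cc("c", worked_params, 30.0) == pytest.approx(26.51249, abs=1e-5)

    @pytest.mark.parametrize("state", ["c", "j"])
    def test_all_curves_pass_through_compensation_point(self, worked_params, state):
        assert rate_cc(state, worked_params, 3.74) == pytest.approx(-2.0, abs=1e-12)

    def test_p_curve_passes_through_compensation_point_when_alpha_positive(
        self, ap_params
    ):
        p = ap_params.replace(alpha=0.1)
        assert rate_cc("p", p, 3.74) == pytest.approx(-2.0, abs=1e-12)

    def test_p_horizontal_asymptote(self, ap_params):
        # 3·Tp − Rd = 34 as Cc → ∞
        assert rate_cc("p", ap_params, 1e6) == pytest.approx(34.0, abs=1e-3)

    @pytest.mark.parametrize(
        "state,pole_of",
        [("c", lambda p: -p.Kco),
         ("j", lambda p: -2 * p.Gamma_star),
         ("p", lambda p: (1 + 3 * p.alpha) * p.Gamma_star)],
    )
    def test_pole_raises_with_location(self, worked_params, state, pole_of):
        pole = pole_of(worked_params)
        with pytest.raises(PoleError) as err:
            rate_cc(state, worked_params, pole)
        assert err.value.pole == pytest.approx(pole)
        assert err.value.state == LimitationState(state)


class TestQuadraticInFrame:
    def test_zero_resistance_degenerates_to_rectangular(self, worked_params):
        p = worked_params.replace(rm=0.0)
        q = quadratic_in_frame("c", p, Frame.CI, 30.0)
        assert q.a2 == 0.0
        assert q.roots()[0] == pytest.approx(rate_cc("c", p, 30.0), rel=1e-12)

    def test_a2_equals_total_resistance(self, worked_params):
        assert quadratic_in_frame("c", worked_params, Frame.CI, 10.0).a2 == 0.45
        assert quadratic_in_frame("c", worked_params, Frame.CA, 10.0).a2 == pytest.approx(0.85)
        assert quadratic_in_frame("c", worked_params, Frame.CC, 10.0).a2 == 0.0

    def test_forward_mapped_root(self, worked_params):
        # image of the A/Cc worked value under Ci = Cc + rm·A
        a_cc = rate_cc("c", worked_params, 30.0)
        ci = 30.0 + 0.45 * a_cc
        q = quadratic_in_frame("c", worked_params, Frame.CI, ci)
        assert q.a2 * a_cc**2 + q.a1 * a_cc + q.a0 == pytest.approx(0.0, abs=1e-9)
        assert rate_in_frame("c", worked_params, Frame.CI, ci) == pytest.approx(
            a_cc, rel=1e-9
        )

    def test_p_discriminant_negative_on_interior_interval(self, ap_params):
        p = ap_params.replace(alpha=0.1)
        dom = valid_domain("p", p, Frame.CI)
        lo, hi = dom.excluded
        mid = 0.5 * (lo + hi)
        assert quadratic_in_frame("p", p, Frame.CI, mid).discriminant() < 0
        assert rate_in_frame("p", p, Frame.CI, mid) is None
        # just outside the interval the rate is real again
        assert rate_in_frame("p", p, Frame.CI, hi + 0.5) is not None


class TestFrameConsistency:
    def test_cc_ci_ca_roundtrip_residual(self):
        """Forward map (Cc, A) → Ci/Ca and recover A to 1e-9 relative."""
        rng = np.random.default_rng(20260927)
        for _ in range(200):
            p = random_params(rng)
            cc = rng.uniform(p.Gamma_star + 0.5, 120.0)
            for state in STATES:
                if state is LimitationState.p and cc <= (1 + 3 * p.alpha) * p.Gamma_star:
                    continue
                a = rate_cc(state, p, cc)
                for frame, r in ((Frame.CI, p.rm), (Frame.CA, p.rm + p.rs)):
                    got = rate_in_frame(state, p, frame, cc + r * a)
                    assert got == pytest.approx(a, rel=1e-9, abs=1e-9)

    def test_negative_root_at_domain_bound_is_minus_rd(self, worked_params):
        c0 = worked_params.Gamma_star - worked_params.rm * worked_params.Rd
        a = rate_in_frame("c", worked_params, Frame.CI, c0)
        assert a == pytest.approx(-worked_params.Rd, rel=1e-9)

    def test_j_horizontal_limit(self, worked_params):
        # J/4 − Rd = 35.5 as Ci → ∞
        a = rate_in_frame("j", worked_params, Frame.CI, 1e6)
        assert a == pytest.approx(35.5, abs=1e-2)


class TestBranchShape:
    def test_negative_root_monotone_nondecreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_params(rng)
            lo = p.Gamma_star - p.rm * p.Rd
            grid = np.linspace(lo + 1e-6, 500.0, 400)
            for state in ("c", "j"):
                a = np.array([rate_in_frame(state, p, Frame.CI, c) for c in grid])
                assert np.all(np.diff(a) >= -1e-9)

    def test_terminal_slope_nonnegative(self):
        """No negative horizontal asymptote: slope at Ci = 1e6 is ≥ −1e−9."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = random_params(rng, alpha_max=0.3)
            for state in STATES:
                a1 = rate_in_frame(state, p, Frame.CI, 1e6)
                a2 = rate_in_frame(state, p, Frame.CI, 1e6 + 1.0)
                assert a2 - a1 >= -1e-9

    def test_ap_right_branch_decreases_when_alpha_positive(self, ap_params):
        p = ap_params.replace(alpha=0.1)
        hi = valid_domain("p", p, Frame.CI).excluded[1]
        grid = np.linspace(hi + 0.1, 500.0, 200)
        a = np.array([rate_in_frame("p", p, Frame.CI, c) for c in grid])
        assert np.all(np.diff(a) < 0)


class TestValidDomain:
    def test_lower_bound_with_resistance(self, worked_params):
        dom = valid_domain("c", worked_params, Frame.CI)
        assert dom.lower == pytest.approx(3.74 - 0.45 * 2.0, rel=1e-12)  # 2.84 Pa

    def test_lower_bound_rectangular_limit(self, worked_params):
        p = worked_params.replace(rm=0.0)
        assert valid_domain("c", p, Frame.CI).lower == pytest.approx(3.74)

    def test_excluded_interval_only_for_alpha_positive(self, ap_params):
        assert valid_domain("p", ap_params, Frame.CI).excluded is None
        dom = valid_domain("p", ap_params.replace(alpha=0.1), Frame.CI)
        lo, hi = dom.excluded
        assert lo < hi
        # the edges are exactly where the discriminant vanishes
        for edge in (lo, hi):
            q = quadratic_in_frame("p", ap_params.replace(alpha=0.1), Frame.CI, edge)
            assert q.discriminant() == pytest.approx(0.0, abs=1e-6)


class TestNetRate:
    def test_rubisco_limited_at_low_c(self, worked_params):
        assert net_rate(worked_params, Frame.CI, 8.0).state == LimitationState.c

    def test_j_limited_at_high_c_when_j_plateau_lower(self, worked_params):
        # J/4 = 37.5 < Vcmax = 100 so state j wins at large Ci
        assert net_rate(worked_params, Frame.CI, 400.0).state == LimitationState.j

    def test_all_states_tie_at_compensation_point(self, worked_tp12):
        p = worked_tp12.replace(alpha=0.05)
        res = net_rate(p, Frame.CC, p.Gamma_star)
        assert res.A == pytest.approx(-p.Rd, rel=1e-12)
        assert res.state == LimitationState.c  # alphabetical tie-break
        assert res.tie

    def test_domain_error_cites_bound(self, worked_params):
        with pytest.raises(DomainError, match="2.84"):
            net_rate(worked_params, Frame.CI, 0.0)

    def test_vectorised_curve_matches_scalar(self, worked_tp12):
        grid = np.linspace(5.0, 300.0, 40)
        a_vec, states = net_rate_curve(worked_tp12, Frame.CI, grid)
        for c, a, s in zip(grid, a_vec, states):
            res = net_rate(worked_tp12, Frame.CI, c)
            assert a == pytest.approx(res.A, rel=1e-12)
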