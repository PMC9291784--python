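"""Forward-model unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acifit.model_core import (
    NOT_LIMITING,
    KineticConstants,
    LimitationState,
    PhotoParams,
    a_min,
    a_rubisco,
    a_rubp_regen,
    a_tpu,
    predict_curve,
    solve_point,
)

from conftest import BERNACCHI_25, bisect_solve, random_params


def pp(**kw) -> PhotoParams:
    base = dict(vcmax=100.0, j=100.0, tpu=10.0, gm=math.inf, rl=1.0)
    base.update(kw)
    return PhotoParams(**base)


class TestCandidateRates:
    def test_rubisco_at_photocompensation_point_equals_minus_rl(self, kinetics_25):
        assert a_rubisco(kinetics_25.gamma_star, pp(rl=1.7), kinetics_25) == pytest.approx(-1.7)

    def test_rubisco_hand_evaluated_value(self, kinetics_25):
        # Vcmax=100, RL=1, Cc=27.5 Pa with Bernacchi-25 constants
        assert a_rubisco(27.5, pp(), kinetics_25) == pytest.approx(22.571016, abs=1e-5)

    def test_rubisco_saturates_at_vcmax_minus_rl(self, kinetics_25):
        # Michaelis-Menten deficit below the asymptote is (Km+G*)/(Cc+Km) exactly
        k = kinetics_25
        a4 = a_rubisco(1e4, pp(), kinetics_25)
        deficit = (k.km_effective + k.gamma_star) / (1e4 + k.km_effective)
        assert a4 + 1.0 == pytest.approx(100.0 * (1 - deficit), rel=1e-6)
        assert a_rubisco(1e6, pp(), kinetics_25) == pytest.approx(99.0, rel=1e-4)

    def test_rubp_regen_at_photocompensation_point_equals_minus_rl(self, kinetics_25):
        assert a_rubp_regen(kinetics_25.gamma_star, pp(), kinetics_25) == pytest.approx(-1.0)

    def test_rubp_regen_classical_hand_value(self, kinetics_25):
        # alphas 0: J*(Cc-G*)/(4Cc+8G*) - RL = 100*25.725/154.2 - 1
        assert a_rubp_regen(30.0, pp(), kinetics_25) == pytest.approx(100 * 25.725 / 154.2 - 1, abs=1e-9)
        assert a_rubp_regen(30.0, pp(), kinetics_25) == pytest.approx(15.68, abs=5e-3)

    def test_rubp_regen_saturates_at_j_over_4_minus_rl(self, kinetics_25):
        assert a_rubp_regen(1e4, pp(), kinetics_25) == pytest.approx(24.0, rel=2e-3)
        assert a_rubp_regen(1e6, pp(), kinetics_25) == pytest.approx(24.0, rel=1e-4)

    def test_tpu_flat_line_without_export(self, kinetics_25):
        for cc in (5.0, 30.0, 120.0):
            assert a_tpu(cc, pp(), kinetics_25) == pytest.approx(3 * 10.0 - 1.0)

    def test_tpu_reverse_sensitivity_with_glycine_export(self, kinetics_25):
        p = pp(alpha_g=0.3)
        a60 = a_tpu(60.0, p, kinetics_25)
        a80 = a_tpu(80.0, p, kinetics_25)
        # frozen from direct evaluation: 30*55.725/51.8775 - 1
        assert a60 == pytest.approx(31.2250, abs=1e-3)
        assert a80 < a60  # declining A with rising CO2

    def test_tpu_pole_returns_not_limiting(self, kinetics_25):
        p = pp(alpha_g=0.3, alpha_s=0.1)
        pole = kinetics_25.gamma_star * (1 + 3 * 0.3 + 4 * 0.1)
        assert a_tpu(pole, p, kinetics_25) is NOT_LIMITING
        assert a_tpu(pole * 0.9, p, kinetics_25) is NOT_LIMITING

    def test_tpu_disabled_raises(self, kinetics_25):
        with pytest.raises(ValueError, match="TPU disabled"):
            a_tpu(30.0, pp(tpu=None), kinetics_25)

    @pytest.mark.parametrize("fn", [a_rubisco, a_rubp_regen, a_tpu])
    @pytest.mark.parametrize("cc", [-1.0, 0.0, math.nan, math.inf])
    def test_bad_cc_raises(self, fn, cc, kinetics_25):
        with pytest.raises(ValueError):
            fn(cc, pp(), kinetics_25)

    @given(cc=st.floats(5.0, 500.0), dcc=st.floats(0.01, 50.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rubisco_and_rubp_strictly_increase_in_cc(self, cc, dcc):
        k = BERNACCHI_25
        p = pp()
        assert a_rubisco(cc + dcc, p, k) > a_rubisco(cc, p, k)
        assert a_rubp_regen(cc + dcc, p, k) > a_rubp_regen(cc, p, k)

    @given(cc=st.floats(1.0, 500.0), ag=st.floats(0.0, 0.6), as_=st.floats(0.0, 0.4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_alpha_zero_reduces_to_classical_forms(self, cc, ag, as_):
        """With zero export the extended forms collapse to the classical
        FvCB expressions; a_tpu becomes constant in Cc."""
        k = BERNACCHI_25
        p0 = pp()
        classical = p0.j * (cc - k.gamma_star) / (4 * cc + 8 * k.gamma_star) - p0.rl
        assert a_rubp_regen(cc, p0, k) == pytest.approx(classical, rel=1e-12)
        v = a_tpu(max(cc, k.gamma_star + 1e-6), p0, k)
        if v is not NOT_LIMITING:
            assert v == pytest.approx(3 * p0.tpu - p0.rl, rel=1e-12)


class TestMinimumRule:
    def test_argmin_selects_rubisco(self, kinetics_25):
        # low Cc: rubisco-limited
        pred = a_min(8.0, pp(vcmax=50, j=300, tpu=30), kinetics_25)
        assert pred.state is LimitationState.RUBISCO
        assert pred.a == min(pred.a_c, pred.a_j, pred.a_p)

    def test_minimum_not_above_any_candidate(self, kinetics_25):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_params(rng)
            cc = rng.uniform(1.0, 200.0)
            pred = a_min(cc, p, kinetics_25)
            assert pred.a <= pred.a_c + 1e-12
            assert pred.a <= pred.a_j + 1e-12
            if isinstance(pred.a_p, float):
                assert pred.a <= pred.a_p + 1e-12

    def test_exact_tie_breaks_to_rubisco(self, kinetics_25):
        # engineer A_c == A_j by matching the two rational forms at one Cc
        k = kinetics_25
        cc = 30.0
        p = pp(vcmax=100.0)
        ac = a_rubisco(cc, p, k)
        # pick J so that a_rubp_regen(cc) == ac exactly
        j = (ac + p.rl) * (4 * cc + 8 * k.gamma_star) / (cc - k.gamma_star)
        p2 = pp(vcmax=100.0, j=j, tpu=None)
        pred = a_min(cc, p2, k)
        assert pred.a_c == pytest.approx(pred.a_j, abs=1e-12)
        assert pred.state is LimitationState.RUBISCO

    def test_tpu_disabled_min_of_two(self, kinetics_25):
        pred = a_min(30.0, pp(tpu=None), kinetics_25)
        assert pred.a_p is None
        assert pred.a == min(pred.a_c, pred.a_j)


class TestSolvePoint:
    def test_infinite_gm_reduces_to_a_min_at_ci(self, kinetics_25):
        p = pp(gm=math.inf)
        pred = solve_point(30.0, p, kinetics_25)
        ref = a_min(30.0, p, kinetics_25)
        assert pred.a == pytest.approx(ref.a, abs=1e-12)
        assert pred.cc == 30.0
        assert pred.state is ref.state

    def test_self_consistency_of_returned_root(self, kinetics_25):
        p = pp(gm=5.0, vcmax=100, j=150, tpu=12, rl=1.0)
        pred = solve_point(30.0, p, kinetics_25)
        assert pred.cc == pytest.approx(30.0 - pred.a / 5.0, abs=1e-9)
        assert pred.cc > 0

    def test_matches_bisection_oracle_on_reference_case(self, kinetics_25):
        p = pp(gm=5.0, vcmax=100, j=150, tpu=12, rl=1.0)
        a_oracle, state_oracle = bisect_solve(30.0, p, kinetics_25)
        pred = solve_point(30.0, p, kinetics_25)
        assert pred.a == pytest.approx(a_oracle, abs=1e-6)
        assert pred.state is state_oracle

    def test_matches_bisection_oracle_on_random_draws(self, kinetics_25):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_params(rng)
            ci = rng.uniform(2.0, 200.0)
            pred = solve_point(ci, p, kinetics_25)
            if pred.flag:
                continue
            a_oracle, _ = bisect_solve(ci, p, kinetics_25)
            assert pred.a == pytest.approx(a_oracle, abs=1e-6)

    def test_large_gm_continuity(self, kinetics_25):
        p_inf = pp(gm=math.inf)
        p_big = pp(gm=1e9)
        for ci in (10.0, 40.0, 120.0):
            assert solve_point(ci, p_big, kinetics_25).a == pytest.approx(
                solve_point(ci, p_inf, kinetics_25).a, abs=1e-6)

    @pytest.mark.parametrize("ci", [-5.0, 0.0, math.nan])
    def test_bad_ci_raises(self, ci, kinetics_25):
        with pytest.raises(ValueError):
            solve_point(ci, pp(), kinetics_25)


class TestPredictCurve:
    def test_empty_and_single(self, kinetics_25):
        assert predict_curve([], pp(), kinetics_25) == []
        out = predict_curve([30.0], pp(), kinetics_25)
        assert len(out) == 1
        assert out[0].a == pytest.approx(solve_point(30.0, pp(), kinetics_25).a)

    def test_states_partition_curve_in_ci_order(self, kinetics_25):
        """On a noiseless three-regime curve the limitation sequence is
        RUBISCO block, then RUBP_REGEN block, then TPU block."""
        p = pp(vcmax=120, j=160, tpu=11, gm=8.0, rl=1.2)
        ci = np.geomspace(5, 150, 25)
        states = [pr.state for pr in predict_curve(ci, p, kinetics_25)]
        order = [LimitationState.RUBISCO, LimitationState.RUBP_REGEN,
                 LimitationState.TPU_LIMITED]
        seen = [states[0]]
        for s in states[1:]:
            if s is not seen[-1]:
                seen.append(s)
        assert seen == order

    def test_per_point_kinetics_length_mismatch_raises(self, kinetics_25):
        with pytest.raises(ValueError):
            predict_curve([10.0, 20.0], pp(), [kinetics_25])
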