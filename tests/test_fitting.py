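"""Fitting tests: initial guess quality, limitation assignment, exact
recovery, nesting, fixed parameters, determinism, bootstrap, comparison."""

import numpy as np
import pytest

from acifit import (
    ACiCurve,
    FitOptions,
    FitResult,
    GasExchangePoint,
    LimitationState,
    PhotoParams,
    assign_limitations,
    bootstrap_uncertainty,
    compare_fits,
    fit_curve,
    generate_curve,
    initial_guess,
    kinetics_at,
    preset,
)


def noiseless(name="tpu_transition", seed=0, **kw):
    return generate_curve(preset(name, seed=seed, noise_a=0.0, noise_phi=0.0, **kw))


class TestInitialGuess:
    def test_within_factor_two_of_truth_on_noiseless_curves(self):
        for seed in range(10):
            name = ("tpu_transition", "classic_three_regime")[seed % 2]
            curve, truth = noiseless(name, seed=seed)
            g = initial_guess(curve, FitOptions())
            for attr in ("vcmax", "j", "tpu"):
                t, v = getattr(truth.params, attr), getattr(g, attr)
                assert 0.5 * t <= v <= 2.0 * t, (seed, attr, t, v)

    def test_degenerate_identical_a_values_no_crash(self):
        pts = [GasExchangePoint(a_obs=10.0, ci=float(c)) for c in (5, 10, 20, 40, 80, 160)]
        g = initial_guess(ACiCurve(points=pts), FitOptions())
        assert np.isfinite(g.vcmax) and g.vcmax > 0

    def test_too_few_points_rejected(self):
        pts = [GasExchangePoint(a_obs=5.0, ci=float(c)) for c in (5, 10, 20, 40)]
        with pytest.raises(ValueError, match=">= 5"):
            initial_guess(ACiCurve(points=pts), FitOptions())

    def test_guess_respects_bounds(self):
        curve, _ = noiseless()
        opts = FitOptions(bounds={**dict(FitOptions().bounds), "tpu": (0.0, 5.0)})
        assert initial_guess(curve, opts).tpu <= 5.0


class TestAssignLimitations:
    def test_tpu_disabled_never_assigns_tpu(self):
        curve, _ = noiseless()
        p = PhotoParams(vcmax=120, j=160, tpu=None, gm=8.0, rl=1.2)
        states = assign_limitations(curve, p, kinetics_at(25.0))
        assert LimitationState.TPU_LIMITED not in states

    def test_exact_recovery_of_designed_states(self):
        scen = preset("tpu_transition", noise_a=0.0, noise_phi=0.0)
        curve, truth = generate_curve(scen)
        k = kinetics_at(scen.tleaf, {"o2": scen.o2})
        assert assign_limitations(curve, scen.truth, k) == truth.states

    def test_single_point_curve(self):
        c = ACiCurve(points=[GasExchangePoint(a_obs=5.0, ci=10.0)])
        states = assign_limitations(c, PhotoParams(vcmax=50, j=300, tpu=30, rl=1.0),
                                    kinetics_at(25.0))
        assert states == [LimitationState.RUBISCO]


class TestFitCurve:
    def test_noiseless_exact_recovery(self):
        curve, truth = noiseless(seed=0)
        res = fit_curve(curve, FitOptions(rng_seed=0))
        assert res.ssr < 1e-8
        for attr in ("vcmax", "j", "tpu", "gm", "rl"):
            t = getattr(truth.params, attr)
            assert getattr(res.params, attr) == pytest.approx(t, rel=0.01), attr
        assert res.states == truth.states
        assert res.converged

    def test_nesting_ssr_with_tpu_never_worse(self):
        for seed in (0, 1):
            curve, _ = generate_curve(preset("tpu_transition", seed=seed))
            w = fit_curve(curve, FitOptions(rng_seed=seed, multistart_n=4))
            wo = fit_curve(curve, FitOptions(include_tpu=False, rng_seed=seed,
                                             multistart_n=4))
            assert w.ssr <= wo.ssr + 1e-6

    def test_fixed_parameters_are_never_perturbed(self):
        curve, _ = generate_curve(preset("tpu_transition", seed=3))
        opts = FitOptions(fixed={"gm": 12.4, "rl": 1.82}, rng_seed=3, multistart_n=3)
        res = fit_curve(curve, opts)
        assert res.params.gm == 12.4
        assert res.params.rl == 1.82
        assert "gm" not in res.free_names and "rl" not in res.free_names
        assert res.fixed == {"gm": 12.4, "rl": 1.82}

    def test_without_tpu_excludes_tpu_branch(self):
        curve, _ = generate_curve(preset("tpu_transition", seed=2))
        res = fit_curve(curve, FitOptions(include_tpu=False, rng_seed=2,
                                          multistart_n=3))
        assert res.params.tpu is None
        assert res.params.alpha_g == 0.0 and res.params.alpha_s == 0.0
        assert set(res.free_names) == {"vcmax", "j", "gm", "rl"}
        assert LimitationState.TPU_LIMITED not in res.states

    def test_determinism_identical_summary(self):
        curve, _ = generate_curve(preset("classic_three_regime", seed=6))
        opts = FitOptions(rng_seed=6, multistart_n=3)
        r1 = fit_curve(curve, opts)
        r2 = fit_curve(curve, opts)
        assert r1.summary_json() == r2.summary_json()

    def test_ssr_equals_sum_of_squared_residuals(self):
        curve, _ = generate_curve(preset("tpu_transition", seed=7))
        res = fit_curve(curve, FitOptions(rng_seed=7, multistart_n=2))
        assert res.ssr == pytest.approx(float(np.sum(res.residuals ** 2)), rel=1e-12)
        assert len(res.states) == res.n_points == len(curve)

    def test_underdetermined_limitation_flagged(self):
        """With no RuBP-regeneration-limited points (rubisco hands straight
        to TPU), J is only a minimum estimate and must be flagged."""
        curve, _ = noiseless("no_j_segment", seed=1)
        res = fit_curve(curve, FitOptions(rng_seed=1, multistart_n=4))
        if res.states.count(LimitationState.RUBP_REGEN) < 2:
            assert "j_underdetermined" in res.flags

    def test_result_round_trips_through_dict(self):
        curve, _ = generate_curve(preset("no_tpu", seed=8))
        res = fit_curve(curve, FitOptions(rng_seed=8, multistart_n=2))
        back = FitResult.from_dict(res.to_dict())
        assert back.summary_json() == res.summary_json()


class TestCompareFits:
    @pytest.mark.parametrize("ssr0, ssr1, expect", [
        (174.4, 16.9, 90.3),   # printed with/without SSR pair, rep 2
        (19.0, 1.2, 93.7),     # rep 3
    ])
    def test_published_ssr_reductions(self, ssr0, ssr1, expect):
        wo = _stub(ssr0, ("vcmax", "j", "gm", "rl"))
        w = _stub(ssr1, ("vcmax", "j", "tpu", "gm", "rl", "alpha_g", "alpha_s"))
        comp = compare_fits(wo, w)
        assert comp.pct_reduction == pytest.approx(expect, abs=0.05)
        assert comp.delta_free_params == 3
        assert comp.f_stat > 0 and comp.df_den == 15 - 7

    def test_identical_fits_zero_reduction(self):
        r = _stub(5.0, ("vcmax", "j", "gm", "rl"))
        comp = compare_fits(r, r)
        assert comp.pct_reduction == 0.0
        assert comp.delta_ssr == 0.0


def _stub(ssr, free):
    return FitResult(
        params=PhotoParams(vcmax=200, j=200, tpu=12 if "tpu" in free else None,
                           gm=8.0, rl=1.0),
        states=[LimitationState.RUBISCO] * 15, ssr=ssr, n_assign_iter=1,
        converged=True, residuals=np.zeros(15), n_points=15,
        free_names=tuple(free), fixed={},
    )


class TestBootstrap:
    def test_b_zero_returns_empty(self):
        curve, _ = generate_curve(preset("tpu_transition", seed=0))
        assert bootstrap_uncertainty(curve, FitOptions(rng_seed=0), 0, seed=1) == {}

    def test_deterministic_and_sane_intervals(self):
        curve, truth = generate_curve(preset("classic_three_regime", seed=5))
        opts = FitOptions(rng_seed=5, multistart_n=2,
                          fixed={"alpha_g": 0.0, "alpha_s": 0.0})
        iv1 = bootstrap_uncertainty(curve, opts, b=12, seed=99)
        iv2 = bootstrap_uncertainty(curve, opts, b=12, seed=99)
        assert iv1 == iv2
        assert set(iv1) == set(opts.free_names())
        lo, hi = iv1["tpu"]
        assert lo <= hi
        assert lo <= truth.params.tpu * 1.3 and hi >= truth.params.tpu * 0.7
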