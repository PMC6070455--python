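import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from fmisokin import models as M
from fmisokin.tac import FrameSchedule

from conftest import random_params


def ode_tissue_curve(params, input_fn, t_eval_min, rtol=1e-10):
    """Independent oracle: integrate the chain ODE against the interpolated input."""
    A, b = M._rate_matrix(params.model.n_tissue, params.rates)
    knots = input_fn.knots_s / 60.0
    vals = input_fn.knot_values

    def rhs(t, y):
        return A @ y + b * np.interp(t, knots, vals)

    sol = solve_ivp(
        rhs,
        (0.0, float(np.max(t_eval_min)) + 1e-9),
        np.zeros(params.model.n_tissue),
        t_eval=t_eval_min,
        rtol=rtol,
        atol=1e-12,
        max_step=2.0,
    )
    return sol.y.sum(axis=0)


class TestImpulseResponse:
    def test_all_zero_rates_give_zero_kernel(self):
        spec = M.model_spec("2C3K")
        p = M.KineticParameters(spec, 0.0, np.zeros(4))
        h = M.impulse_response(spec, p)
        assert np.allclose(h(np.linspace(0, 100, 11)), 0.0)

    def test_chain_truncation_matches_one_tissue_form(self):
        # 2C3K with k3 = 0 collapses to K1*exp(-k2 t)
        spec = M.model_spec("2C3K")
        p = M.KineticParameters(spec, 0.0, np.array([0.4, 0.25, 0.0, 0.0]))
        h = M.impulse_response(spec, p)
        t = np.linspace(0.0, 60.0, 200)
        np.testing.assert_allclose(h(t), 0.4 * np.exp(-0.25 * t), rtol=1e-12, atol=1e-15)

    @pytest.mark.parametrize("name", M.MODEL_NAMES)
    def test_kernel_matches_ode_oracle(self, name, input_fn):
        rng = np.random.default_rng(11)
        p = random_params(name, rng)
        t = np.array([1.0, 5.0, 20.0, 44.0, 125.0, 240.0])
        h = M.impulse_response(p.model, p)
        assert not h.degenerate
        conv = M.expconv_eval(
            np.ascontiguousarray(input_fn.knots_s / 60.0),
            np.ascontiguousarray(input_fn.knot_values),
            np.ascontiguousarray(h.alphas),
            t,
        )
        mine = conv @ h.amps
        oracle = ode_tissue_curve(p, input_fn, t)
        assert np.max(np.abs(mine - oracle)) < 1e-3 * np.max(np.abs(oracle))

    def test_irreversible_kernel_has_single_trapping_term(self):
        rng = np.random.default_rng(3)
        p = random_params("3C5K", rng)
        h = M.impulse_response(p.model, p)
        assert np.sum(h.alphas == 0.0) == 1
        assert np.all(h.alphas >= 0.0)


class TestModelTac:
    def test_zero_input_gives_zero_tac(self, tumor_schedule):
        from fmisokin.synthetic import generate_input_function

        zero = generate_input_function(amplitude=0.0)
        p = random_params("3C5K", np.random.default_rng(0))
        tac = M.model_tac(p.model, p, zero, tumor_schedule)
        assert np.allclose(tac.activity, 0.0)

    def test_pure_blood_limit(self, input_fn, tumor_schedule):
        # all rates 0, vB = 1: model TAC equals the frame-averaged blood curve
        spec = M.model_spec("2C3K")
        p = M.KineticParameters(spec, 1.0, np.zeros(4))
        tac = M.model_tac(spec, p, input_fn, tumor_schedule)
        t = np.linspace(0, 1, 4001)
        for i in np.r_[0:4, 20:24, 40:42]:
            lo, hi = tumor_schedule.start_s[i], tumor_schedule.end_s[i]
            ref = np.mean(input_fn(lo + t * (hi - lo)))
            assert tac.activity[i] == pytest.approx(ref, abs=2e-3 * input_fn.tac.activity.max())

    def test_frame_average_against_numeric_convolution(self, input_fn):
        # brute-force fine-grid convolution oracle for the frame values
        p = random_params("3C5K", np.random.default_rng(5))
        sched = FrameSchedule(np.array([0.0, 30.0, 300.0, 1800.0]), np.array([30.0, 60.0, 300.0, 600.0]))
        tac = M.model_tac(p.model, p, input_fn, sched)
        dt = 0.002
        tf = np.arange(0.0, 41.0, dt)
        cb = np.interp(tf, input_fn.knots_s / 60.0, input_fn.knot_values)
        h = M.impulse_response(p.model, p)
        kern = np.einsum("j,tj->t", h.amps, np.exp(-np.outer(tf, h.alphas)))
        conv = np.convolve(cb, kern)[: tf.size] * dt
        total = (1 - p.v_b) * conv + p.v_b * cb
        peak = total.max()
        for i in range(sched.n_frames):
            lo, hi = sched.start_s[i] / 60.0, sched.end_s[i] / 60.0
            mask = (tf >= lo) & (tf <= hi)
            ref = total[mask].mean()
            assert abs(tac.activity[i] - ref) < 1e-3 * peak

    def test_preinjection_frames_are_zero(self, input_fn):
        sched = FrameSchedule(np.array([-60.0, -30.0, 0.0]), np.array([30.0, 30.0, 30.0]))
        p = random_params("2C4K", np.random.default_rng(1))
        tac = M.model_tac(p.model, p, input_fn, sched)
        assert tac.activity[0] == 0.0
        assert tac.activity[1] == 0.0
        assert tac.activity[2] > 0.0

    def test_nonnegative_for_nonnegative_input(self, input_fn, tumor_schedule):
        rng = np.random.default_rng(17)
        for name in M.MODEL_NAMES:
            p = random_params(name, rng)
            tac = M.model_tac(p.model, p, input_fn, tumor_schedule)
            assert np.all(tac.activity >= -1e-12)

    def test_nesting_reproduces_submodel(self, input_fn, tumor_schedule):
        # 3C6K with k6=0 == 3C5K; 3C5K with k4=k5=0 == 2C3K with matched rates
        r5 = np.array([0.3, 0.25, 0.06, 0.04, 0.02, 0.0])
        p6 = M.KineticParameters(M.model_spec("3C6K"), 0.1, r5)
        p5 = M.KineticParameters(M.model_spec("3C5K"), 0.1, r5)
        a6 = M.model_tac(p6.model, p6, input_fn, tumor_schedule).activity
        a5 = M.model_tac(p5.model, p5, input_fn, tumor_schedule).activity
        np.testing.assert_allclose(a6, a5, rtol=1e-10)

        r3 = np.array([0.3, 0.25, 0.06, 0.0, 0.0, 0.0])
        p5b = M.KineticParameters(M.model_spec("3C5K"), 0.1, r3)
        p2 = M.KineticParameters(M.model_spec("2C3K"), 0.1, np.array([0.3, 0.25, 0.06, 0.0]))
        a5b = M.model_tac(p5b.model, p5b, input_fn, tumor_schedule).activity
        a2 = M.model_tac(p2.model, p2, input_fn, tumor_schedule).activity
        np.testing.assert_allclose(a5b, a2, rtol=1e-9, atol=1e-12)

    def test_frame_average_converges_to_midpoint(self, input_fn):
        p = random_params("3C5K", np.random.default_rng(9))
        mid = 600.0
        vals = []
        for dur in (300.0, 30.0, 1.0):
            sched = FrameSchedule(np.array([mid - dur / 2]), np.array([dur]))
            vals.append(M.model_tac(p.model, p, input_fn, sched).activity[0])
        point = FrameSchedule(np.array([mid - 0.005]), np.array([0.01]))
        ref = M.model_tac(p.model, p, input_fn, point).activity[0]
        errs = np.abs(np.array(vals) - ref)
        assert errs[-1] < errs[0]
        assert errs[-1] < 1e-4 * abs(ref)


class TestFluxConstants:
    def test_two_tissue_flux_examples(self):
        assert M.k_flux_2c(0.0, 0.1, 0.1) == 0.0
        assert M.k_flux_2c(0.2, 0.1, 0.1) == pytest.approx(0.1)
        with pytest.raises(M.FluxUndefinedError):
            M.k_flux_2c(0.2, 0.0, 0.0)

    def test_three_tissue_flux_examples(self):
        assert M.k_flux_3c(0.0, 0.1, 0.1, 0.1, 0.1) == 0.0
        # k4=0 reduces to the two-tissue form
        assert M.k_flux_3c(0.3, 0.2, 0.1, 0.0, 0.05) == pytest.approx(M.k_flux_2c(0.3, 0.2, 0.1))
        assert M.k_flux_3c(0.2, 0.1, 0.1, 0.1, 0.1) == pytest.approx(0.0667, abs=5e-5)

    def test_flux_never_exceeds_k1(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            K1, k2, k3 = rng.uniform(0.01, 2.0, 3)
            assert M.k_flux_2c(K1, k2, k3) <= K1

    def test_trapping_coefficient_equals_closed_form(self):
        rng = np.random.default_rng(8)
        for name, closed in (("2C3K", M.k_flux_2c), ("3C5K", None)):
            for _ in range(20):
                p = random_params(name, rng)
                r = p.rates
                expected = (
                    M.k_flux_2c(r[0], r[1], r[2])
                    if name == "2C3K"
                    else M.k_flux_3c(r[0], r[1], r[2], r[3], r[4])
                )
                got = M.steady_flux_equivalence(p.model, p)
                assert got == pytest.approx(expected, rel=1e-10)

    def test_zero_terminal_rate_gives_zero_flux(self):
        spec = M.model_spec("3C5K")
        p = M.KineticParameters(spec, 0.05, np.array([0.3, 0.2, 0.1, 0.1, 0.0, 0.0]))
        assert M.steady_flux_equivalence(spec, p) == pytest.approx(0.0, abs=1e-12)

    def test_reversible_model_rejected(self):
        p = random_params("3C6K", np.random.default_rng(1))
        with pytest.raises(ValueError):
            M.steady_flux_equivalence(p.model, p)

    def test_bound_compartment_monotone_for_irreversible(self, input_fn):
        # the trapped compartment never loses tracer
        p = random_params("3C5K", np.random.default_rng(21))
        A, b = M._rate_matrix(3, p.rates)
        knots = input_fn.knots_s / 60.0
        vals = input_fn.knot_values

        def rhs(t, y):
            return A @ y + b * np.interp(t, knots, vals)

        sol = solve_ivp(rhs, (0, 240), np.zeros(3), rtol=1e-9, atol=1e-12, max_step=2.0,
                        t_eval=np.linspace(0, 240, 400))
        assert np.all(np.diff(sol.y[-1]) >= -1e-10)


rate = st.floats(1e-5, 2.0, allow_nan=False)


class TestFluxProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(K1=rate, k2=rate, k3=rate)
    def test_two_tissue_flux_bounded_by_k1(self, K1, k2, k3):
        flux = M.k_flux_2c(K1, k2, k3)
        assert 0.0 <= flux <= K1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(K1=rate, k2=rate, k3=rate, k4=rate, k5=rate)
    def test_three_tissue_flux_bounded_and_consistent(self, K1, k2, k3, k4, k5):
        flux = M.k_flux_3c(K1, k2, k3, k4, k5)
        assert 0.0 <= flux <= K1
        # adding a return path (k4 > 0) can only reduce trapping
        assert flux <= M.k_flux_3c(K1, k2, k3, 0.0, k5) + 1e-15


def test_f18_decay_constant_consistent():
    assert M.LAMBDA_F18_PER_MIN == pytest.approx(np.log(2) / M.F18_HALF_LIFE_MIN)
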