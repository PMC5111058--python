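import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import runpause as rp

from .conftest import random_rates


class TestMsdSingle:
    def test_never_pausing_walker_is_purely_ballistic(self, unit_steps, motion_start):
        series = rp.msd_single(rp.TransitionRates(0.0, 1.0), motion_start, unit_steps, 20)
        np.testing.assert_allclose(series.msd, np.arange(1, 21) ** 2, rtol=1e-14)

    def test_instant_pause_never_moves(self, unit_steps, motion_start):
        # the first transition precedes the first displacement
        series = rp.msd_single(rp.TransitionRates(1.0, 0.0), motion_start, unit_steps, 10)
        np.testing.assert_array_equal(series.msd, 0.0)

    def test_slow_restart_first_two_steps(self, slow_restart_rates, motion_start, unit_steps):
        series = rp.msd_single(slow_restart_rates, motion_start, unit_steps, 2)
        assert series.msd[0] == pytest.approx(0.9, abs=1e-14)
        assert series.msd[1] == pytest.approx(3.3301, abs=1e-12)

    def test_half_half_closed_form(self, unit_steps, motion_start):
        # kappa_w = kappa_m = 1/2 gives MSD(n) = n(n+1)/4 exactly
        n = np.arange(1, 200)
        series = rp.msd_single(rp.TransitionRates(0.5, 0.5), motion_start, unit_steps, 199)
        np.testing.assert_allclose(series.msd, 0.25 * n * (n + 1), rtol=1e-13)

    def test_matches_enumeration_oracle(self, unit_steps):
        rng = np.random.default_rng(17)
        for _ in range(25):
            rates = random_rates(rng, include_boundaries=True)
            init = rp.InitialState(rng.random())
            steps = rp.custom_steps(1.0, rng.uniform(1.0, 3.0))
            analytic = rp.msd_single(rates, init, steps, 10).msd
            for n in (1, 4, 7, 10):
                brute = rp.enumerate_msd_single(rates, init, steps, n)
                assert analytic[n - 1] == pytest.approx(brute, abs=1e-12)

    def test_monotone_in_n_and_in_rates(self, unit_steps, motion_start):
        rng = np.random.default_rng(23)
        for _ in range(20):
            rates = random_rates(rng)
            series = rp.msd_single(rates, motion_start, unit_steps, 500)
            assert np.all(np.diff(series.msd) >= -1e-12)
        # pointwise monotone: growing kappa_m helps, growing kappa_w hurts
        base = rp.msd_single(rp.TransitionRates(0.3, 0.2), motion_start, unit_steps, 300).msd
        more_restart = rp.msd_single(rp.TransitionRates(0.3, 0.4), motion_start, unit_steps, 300).msd
        more_pause = rp.msd_single(rp.TransitionRates(0.5, 0.2), motion_start, unit_steps, 300).msd
        assert np.all(more_restart >= base - 1e-12)
        assert np.all(more_pause <= base + 1e-12)

    def test_bounded_by_ballistic_envelope(self, motion_start):
        steps = rp.constant_steps(2.0)
        series = rp.msd_single(rp.TransitionRates(0.2, 0.7), motion_start, steps, 100)
        n = np.arange(1, 101)
        assert np.all(series.msd <= (2.0 * n) ** 2 + 1e-9)

    def test_rejects_bad_horizon(self, unit_steps, motion_start):
        with pytest.raises(rp.ParameterError):
            rp.msd_single(rp.TransitionRates(0.1, 0.1), motion_start, unit_steps, 0)


class TestInitialExponentSingle:
    def test_ballistic_limit(self, unit_steps, motion_start):
        alpha = rp.initial_exponent_single(rp.TransitionRates(0.0, 1.0), motion_start, unit_steps)
        assert alpha == pytest.approx(2.0, abs=1e-12)

    def test_slow_restart_motion_start(self, slow_restart_rates, motion_start, unit_steps):
        alpha = rp.initial_exponent_single(slow_restart_rates, motion_start, unit_steps)
        assert alpha == pytest.approx(np.log2(3.3301 / 0.9), abs=1e-10)

    def test_waiting_start_exceeds_ballistic(self, unit_steps, waiting_start):
        # all-waiting start with no pausing: injection makes alpha* > 2
        alpha = rp.initial_exponent_single(
            rp.TransitionRates(0.0, 0.001), waiting_start, unit_steps
        )
        assert alpha == pytest.approx(np.log2(0.004999 / 0.001), abs=1e-9)
        assert alpha > 2.3

    def test_undefined_when_first_step_cannot_move(self, unit_steps, motion_start):
        with pytest.raises(rp.UndefinedExponentError):
            rp.initial_exponent_single(rp.TransitionRates(1.0, 0.0), motion_start, unit_steps)


class TestAsymptoticPrefactor:
    def test_no_pausing_is_fastest_propagation(self, unit_steps):
        assert rp.asymptotic_msd_prefactor_single(
            rp.TransitionRates(0.0, 0.5), unit_steps
        ) == pytest.approx(1.0)

    def test_symmetric_rates(self, unit_steps):
        assert rp.asymptotic_msd_prefactor_single(
            rp.TransitionRates(0.3, 0.3), unit_steps
        ) == pytest.approx(0.25)

    def test_slow_restart_value(self, slow_restart_rates, unit_steps):
        c = rp.asymptotic_msd_prefactor_single(slow_restart_rates, unit_steps)
        assert c == pytest.approx((0.001 / 0.101) ** 2, rel=1e-12)

    def test_engine_approaches_prefactor(self, unit_steps, motion_start):
        rates = rp.TransitionRates(0.3, 0.2)
        series = rp.msd_single(rates, motion_start, unit_steps, 100_000)
        c = rp.asymptotic_msd_prefactor_single(rates, unit_steps)
        assert series.msd[-1] / 1e10 == pytest.approx(c, rel=1e-2)


class TestWaitingStartContinuous:
    def test_closed_form_matches_quadrature(self):
        from scipy.integrate import quad

        for kappa, v, t in [(1.0, 1.0, 1.0), (0.5, 2.0, 3.0), (2.0, 0.7, 0.4)]:
            num, _ = quad(lambda t0: kappa * np.exp(-kappa * t0) * v**2 * (t - t0) ** 2, 0, t)
            assert rp.waiting_start_msd_continuous(kappa, v, t) == pytest.approx(num, rel=1e-10)

    def test_reference_value(self):
        assert rp.waiting_start_msd_continuous(1.0, 1.0, 1.0) == pytest.approx(
            1 - 2 + 2 - 2 / np.e, rel=1e-12
        )

    def test_small_t_cubic_leading_term(self):
        # MSD ~ (v^2 kappa / 3) t^3 as t -> 0
        for kappa, v in [(1.0, 1.0), (0.3, 2.0)]:
            t = 1e-5
            lead = v**2 * kappa / 3.0 * t**3
            assert rp.waiting_start_msd_continuous(kappa, v, t) == pytest.approx(lead, rel=1e-2)

    def test_local_exponent_limits(self):
        assert rp.waiting_start_local_exponent(1.0, 1.0, 1e-4) == pytest.approx(3.0, abs=1e-3)
        assert rp.waiting_start_local_exponent(1.0, 1.0, 1e4) == pytest.approx(2.0, abs=1e-3)

    def test_rejects_negative_inputs(self):
        with pytest.raises(rp.ParameterError):
            rp.waiting_start_msd_continuous(-1.0, 1.0, 1.0)
        with pytest.raises(rp.ParameterError):
            rp.waiting_start_msd_continuous(1.0, 1.0, -0.5)


class TestSuperBallisticTransient:
    def test_waiting_deficit_produces_exponent_above_two(self, unit_steps):
        # ensembles injected from the waiting state accelerate: alpha > 2
        rates = rp.TransitionRates(0.0, 0.001)
        series = rp.msd_single(rates, rp.InitialState(0.0), unit_steps, 2000)
        alpha = rp.alpha_series(series)
        assert alpha.alpha.max() > 2.5

    def test_stationary_start_never_exceeds_two(self, unit_steps):
        for kw, km in [(0.1, 0.001), (0.5, 0.5), (0.2, 0.7)]:
            rates = rp.TransitionRates(kw, km)
            init = rp.InitialState(rates.stationary_motion)
            alpha = rp.alpha_series(rp.msd_single(rates, init, unit_steps, 2000))
            assert alpha.alpha.max() <= 2.0 + 1e-9


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    kw=st.floats(0.0, 1.0), km=st.floats(0.0, 1.0), q0=st.floats(0.0, 1.0),
    lam=st.floats(1.0, 3.0), n=st.integers(1, 8),
)
def test_engine_equals_oracle_property(kw, km, q0, lam, n):
    """The correlation-sum engine and the 2^n enumeration agree everywhere."""
    rates = rp.TransitionRates(kw, km)
    init = rp.InitialState(q0)
    steps = rp.custom_steps(1.0, lam)
    analytic = rp.msd_single(rates, init, steps, n).msd[-1]
    assert analytic == pytest.approx(rp.enumerate_msd_single(rates, init, steps, n), abs=1e-12)
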