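import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import runpause as rp

from .conftest import random_rates


def single_state_rates():
    return rp.TransitionRates(0.0, 1.0)


class TestMsdNetwork:
    def test_isotropic_single_state_is_diffusive(self, unit_steps, motion_start):
        model = rp.persistence_model(single_state_rates(), motion_start, unit_steps, 0.0)
        series = rp.msd_network(model, 50)
        np.testing.assert_allclose(series.msd, np.arange(1, 51), rtol=1e-13)

    def test_half_persistence_first_steps(self, unit_steps, motion_start):
        model = rp.persistence_model(single_state_rates(), motion_start, unit_steps, 0.5)
        series = rp.msd_network(model, 3)
        assert series.msd[1] == pytest.approx(3.0, abs=1e-13)
        assert series.msd[2] == pytest.approx(5.5, abs=1e-13)

    def test_full_persistence_reduces_to_single_filament(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            rates = random_rates(rng)
            init = rp.InitialState(rng.random())
            steps = rp.custom_steps(1.0, rng.uniform(1.0, 2.5))
            model = rp.make_network_model(rates, init, steps, rp.delta_turns(0.0), 0.0)
            np.testing.assert_allclose(
                rp.msd_network(model, 150).msd,
                rp.msd_single(rates, init, steps, 150).msd,
                atol=1e-12, rtol=1e-12,
            )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            rates = random_rates(rng, include_boundaries=True)
            init = rp.InitialState(rng.random())
            steps = rp.custom_steps(1.0, rng.uniform(1.0, 3.0))
            model = rp.persistence_model(rates, init, steps, rng.random())
            analytic = rp.msd_network(model, 8).msd
            for n in (1, 3, 5, 8):
                brute = rp.enumerate_msd_network(model, n)
                assert analytic[n - 1] == pytest.approx(brute, abs=1e-12)

    def test_msd_depends_on_turns_only_through_mean_cosine(self, unit_steps, motion_start):
        rates = rp.TransitionRates(0.2, 0.6)
        lattice = rp.make_network_model(
            rates, motion_start, unit_steps,
            rp.discrete_turns([0.0, np.pi / 2, -np.pi / 2]), 0.0,
        )
        wrapped = rp.make_network_model(
            rates, motion_start, unit_steps,
            rp.wrapped_normal_turns(np.sqrt(-2 * np.log(1 / 3))), 0.0,
        )
        assert lattice.persistence == pytest.approx(wrapped.persistence, abs=1e-14)
        np.testing.assert_allclose(
            rp.msd_network(lattice, 100).msd, rp.msd_network(wrapped, 100).msd, rtol=1e-12
        )

    def test_long_time_dynamics_diffusive_for_all_subballistic_persistence(
        self, unit_steps, motion_start
    ):
        for A in (0.0, 0.5, 0.9):
            model = rp.persistence_model(
                rp.TransitionRates(0.3, 0.4), motion_start, unit_steps, A
            )
            alpha = rp.alpha_series(rp.msd_network(model, 30_000))
            assert abs(alpha.alpha[-1] - 1.0) < 1e-3


class TestInitialExponentNetwork:
    def test_isotropic_non_processive_is_diffusive(self, unit_steps, motion_start):
        model = rp.persistence_model(single_state_rates(), motion_start, unit_steps, 0.0)
        assert rp.initial_exponent_network(model) == pytest.approx(1.0, abs=1e-13)

    def test_ballistic_limit(self, unit_steps, motion_start):
        model = rp.persistence_model(single_state_rates(), motion_start, unit_steps, 1.0)
        assert rp.initial_exponent_network(model) == pytest.approx(2.0, abs=1e-13)

    def test_square_lattice_lower_bound_of_exponent_range(self, unit_steps, motion_start):
        model = rp.make_network_model(
            single_state_rates(), motion_start, unit_steps,
            rp.discrete_turns([0.0, np.pi / 2, -np.pi / 2]), 0.0,
        )
        alpha = rp.initial_exponent_network(model)
        assert alpha == pytest.approx(np.log2(8.0 / 3.0), abs=1e-13)
        assert round(alpha, 2) in (1.41, 1.42)  # prints as 1.41 truncated

    def test_single_state_closed_form(self, motion_start):
        # log2(2 + 2A/lambda) for kappa_w=0, kappa_m=1
        for A, lam in [(0.3, 1.0), (0.7, 2.0), (0.2, 1.5)]:
            steps = rp.custom_steps(1.0, lam)
            model = rp.persistence_model(single_state_rates(), motion_start, steps, A)
            assert rp.initial_exponent_network(model) == pytest.approx(
                np.log2(2.0 + 2.0 * A / lam), abs=1e-12
            )


class TestGammaScale:
    def test_uncorrelated_steps_give_heterogeneity(self):
        assert rp.gamma_scale(1.0, 0.0) == 1.0
        assert rp.gamma_scale(2.3, 0.0) == 2.3

    def test_reference_value(self):
        assert rp.gamma_scale(1.0, 0.5) == pytest.approx(3.0)

    def test_diverges_towards_ballistic_limit(self):
        assert rp.gamma_scale(1.0, 0.999) > 1000
        with pytest.raises(rp.BallisticDivergenceError):
            rp.gamma_scale(1.0, 1.0)


class TestAsymptoticDiffusion:
    def test_reference_value_isotropic_symmetric(self, unit_steps, motion_start):
        model = rp.persistence_model(
            rp.TransitionRates(0.25, 0.25), motion_start, unit_steps, 0.0
        )
        assert rp.asymptotic_diffusion(model, v=1.0) == pytest.approx(1.0 / 8.0)

    def test_vanishing_restart_localizes(self, unit_steps, motion_start):
        values = [
            rp.asymptotic_diffusion(
                rp.persistence_model(rp.TransitionRates(0.3, km), motion_start, unit_steps, 0.0),
                v=1.0,
            )
            for km in (0.3, 0.03, 0.003)
        ]
        assert values[0] > values[1] > values[2]
        assert values[2] < 0.01

    def test_independent_of_initial_conditions(self, unit_steps):
        rates = rp.TransitionRates(0.4, 0.3)
        d0 = rp.asymptotic_diffusion(
            rp.persistence_model(rates, rp.InitialState(0.0), unit_steps, 0.5), v=2.0
        )
        d1 = rp.asymptotic_diffusion(
            rp.persistence_model(rates, rp.InitialState(1.0), unit_steps, 0.5), v=2.0
        )
        assert d0 == d1

    def test_engine_slope_matches_formula(self, motion_start):
        steps = rp.custom_steps(1.0, 2.0)
        model = rp.persistence_model(rp.TransitionRates(0.3, 0.2), motion_start, steps, 0.5)
        n = 100_000
        slope = rp.msd_network(model, n).msd[-1] / n
        assert slope == pytest.approx(rp.asymptotic_msd_slope(model), rel=1e-2)

    def test_ballistic_persistence_rejected(self, unit_steps, motion_start):
        model = rp.persistence_model(rp.TransitionRates(0.3, 0.2), motion_start, unit_steps, 1.0)
        with pytest.raises(rp.BallisticDivergenceError):
            rp.asymptotic_diffusion(model, v=1.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    kw=st.floats(0.0, 1.0), km=st.floats(0.0, 1.0), q0=st.floats(0.0, 1.0),
    A=st.floats(0.0, 1.0), lam=st.floats(1.0, 3.0), n=st.integers(1, 7),
)
def test_network_engine_equals_oracle_property(kw, km, q0, A, lam, n):
    """Transfer-matrix correlation sums agree with 2^n enumeration."""
    model = rp.persistence_model(
        rp.TransitionRates(kw, km), rp.InitialState(q0), rp.custom_steps(1.0, lam), A
    )
    analytic = rp.msd_network(model, n).msd[-1]
    assert analytic == pytest.approx(rp.enumerate_msd_network(model, n), abs=1e-12)
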