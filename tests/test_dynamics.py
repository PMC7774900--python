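"""Unit and property tests for the per-step model rules."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovulesim import (
    DegenerateAllocationError,
    ModelParams,
    NumericalInstabilityError,
    PinAllocation,
    TissueState,
    auxin_derivative,
    divide_cells,
    euler_step,
    grow_cells,
    pin_allocation,
    quasi_steady_pins,
)

from _oracles import scalar_euler_step, scalar_pins


@pytest.fixture
def params():
    return ModelParams()


class TestModelParams:
    def test_published_defaults(self, params):
        assert params.dt == 5e-4
        assert params.D_a == 0.5
        assert params.p == 1.0
        assert params.E_p == 1.0
        assert params.G_a == 0.1
        assert params.l_div == 4.0
        assert params.r == 0.01
        assert params.N0 == 50
        assert (params.base_level, params.grad_amp, params.noise_amp) \
            == (0.95, 0.03, 0.02)

    @pytest.mark.parametrize("bad", [
        {"dt": 0.0}, {"dt": -1e-3}, {"l_div": 1.0}, {"N0": 2}, {"n": 3},
        {"G_a": -0.1}, {"mode": "bogus"}, {"growth_law": "cubic"},
        {"T_end": 0.0},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)


class TestTissueState:
    def test_requires_three_cells_and_positive_lengths(self):
        with pytest.raises(ValueError):
            TissueState(0.0, [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            TissueState(0.0, [1.0, 1.0, 1.0], [1.0, 0.0, 1.0])

    def test_totals_and_midpoints(self):
        s = TissueState(0.0, [1.0, 2.0, 3.0], [1.0, 2.0, 1.0])
        assert s.total_length == 4.0
        assert s.total_auxin == 1.0 + 4.0 + 3.0
        assert np.allclose(s.midpoints(), [0.5, 2.0, 3.5])


class TestPinAllocation:
    def test_symmetric_neighbours_split_equally(self, params):
        assert pin_allocation(1.0, 1.0, params) == (1.0, 1.0)

    def test_three_to_one_ratio(self, params):
        # direct evaluation of the allocation rule with phi(a) = a
        assert pin_allocation(3.0, 1.0, params) == (1.5, 0.5)

    def test_dead_neighbours_raise(self, params):
        with pytest.raises(DegenerateAllocationError):
            pin_allocation(0.0, 0.0, params)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            pin_allocation(-1.0, 1.0, params)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_membrane_sum_is_np(self, a_left, a_right):
        """The two membrane densities always sum to n*p exactly."""
        p_l, p_r = pin_allocation(a_left, a_right, ModelParams())
        assert p_l >= 0 and p_r >= 0
        assert abs((p_l + p_r) - 2.0) <= 1e-12

    def test_ring_allocation_matches_scalar_loops(self, params, rng):
        a = rng.uniform(0.1, 3.0, size=17)
        pins = quasi_steady_pins(a, params)
        p_l, p_r = scalar_pins(list(a), params.n, params.p)
        np.testing.assert_allclose(pins.p_left, p_l, rtol=0, atol=1e-15)
        np.testing.assert_allclose(pins.p_right, p_r, rtol=0, atol=1e-15)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            PinAllocation([-0.1, 1.0], [1.0, 1.0])


class TestAuxinDerivative:
    def test_uniform_equilibrium_has_zero_rate(self, params):
        s = TissueState(0.0, np.ones(10), np.ones(10))
        rate = auxin_derivative(s, quasi_steady_pins(s.a, params), params)
        np.testing.assert_allclose(rate, 0.0, atol=1e-15)

    def test_three_cell_hand_computed_rates(self):
        # a = (1, 2, 1) ring with transport off: only diffusion and
        # reaction terms remain and can be evaluated by hand
        p = ModelParams(E_p=0.0, D_a=0.5, A=0.1, G_a=0.1)
        s = TissueState(0.0, [1.0, 2.0, 1.0], [1.0, 1.0, 1.0])
        rate = auxin_derivative(s, quasi_steady_pins(s.a, p), p)
        np.testing.assert_allclose(rate, [0.5, -1.1, 0.5], atol=1e-14)
        assert abs(rate.sum() - (3 * 0.1 - 0.1 * 4.0)) <= 1e-14

    def test_transport_and_diffusion_conserve_total(self, rng):
        p = ModelParams(A=0.0, G_a=0.0)
        a = rng.uniform(0.2, 2.0, size=23)
        s = TissueState(0.0, a, np.ones(23))
        rate = auxin_derivative(s, quasi_steady_pins(a, p), p)
        assert abs(rate.sum()) <= 1e-12

    def test_rate_sum_identity(self, params, rng):
        """sum(rate) == N*A - G_a*sum(a) whatever the transport does."""
        a = rng.uniform(0.2, 2.0, size=11)
        s = TissueState(0.0, a, np.ones(11))
        rate = auxin_derivative(s, quasi_steady_pins(a, params), params)
        expected = 11 * params.A - params.G_a * a.sum()
        assert abs(rate.sum() - expected) <= 1e-12

    def test_mismatched_pins_rejected(self, params):
        s = TissueState(0.0, np.ones(5), np.ones(5))
        pins = quasi_steady_pins(np.ones(6), params)
        with pytest.raises(ValueError):
            auxin_derivative(s, pins, params)


class TestEulerStep:
    def test_uniform_state_unchanged_except_time(self, params):
        s = TissueState(0.0, np.ones(8), np.ones(8))
        out = euler_step(s, params)
        assert out.t == params.dt
        np.testing.assert_array_equal(out.a, s.a)

    def test_hand_computed_single_step(self):
        p = ModelParams(E_p=0.0, D_a=0.5, A=0.1, G_a=0.1)
        s = TissueState(0.0, [1.0, 2.0, 1.0], [1.0, 1.0, 1.0])
        out = euler_step(s, p)
        assert out.a[0] == pytest.approx(1.0 + 5e-4 * 0.5, abs=1e-15)

    def test_nonpositive_dt_rejected(self, params):
        s = TissueState(0.0, np.ones(5), np.ones(5))
        params.dt = -1.0  # bypass constructor validation deliberately
        with pytest.raises(ValueError):
            euler_step(s, params)

    def test_negative_overshoot_clamped_with_warning(self, caplog):
        # transport off, diffusion cranked up so the middle cell overshoots
        p = ModelParams(E_p=0.0, D_a=2.0, A=0.1, G_a=0.1, dt=1.0)
        s = TissueState(0.0, [0.1, 4.0, 0.1], [1.0, 1.0, 1.0])
        with caplog.at_level(logging.WARNING, logger="ovulesim.dynamics"):
            out = euler_step(s, p)
        assert out.a[1] == 0.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_overflow_raises_instability_error(self):
        p = ModelParams(E_p=0.0, D_a=1e308, A=0.0, G_a=0.0, dt=1e308)
        s = TissueState(0.0, [1.0, 2.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(NumericalInstabilityError) as err, \
                np.errstate(over="ignore"):
            euler_step(euler_step(s, p), p)
        assert err.value.cell_index is not None

    def test_matches_scalar_loop_oracle(self, params, rng):
        """Vectorised step equals the independent scalar loops term by term."""
        for _ in range(20):
            a = rng.uniform(0.2, 2.0, size=5)
            s = TissueState(0.0, a, np.ones(5))
            out = euler_step(s, params)
            expected, _ = scalar_euler_step(list(a), params)
            np.testing.assert_allclose(out.a, expected, rtol=0, atol=1e-15)


class TestGrowth:
    def test_zero_rate_is_identity(self):
        p = ModelParams(r=0.0)
        s = TissueState(0.0, np.ones(5), np.full(5, 1.7))
        np.testing.assert_array_equal(grow_cells(s, p).l, s.l)

    def test_exponential_single_step(self):
        p = ModelParams(r=0.01)
        s = TissueState(0.0, np.ones(3), np.ones(3))
        assert grow_cells(s, p).l[0] == pytest.approx(1.000005, abs=1e-12)

    def test_linear_single_step(self):
        p = ModelParams(r=0.01, growth_law="linear")
        s = TissueState(0.0, np.ones(3), np.full(3, 2.0))
        assert grow_cells(s, p).l[0] == pytest.approx(2.0 + 5e-6, abs=1e-12)

    def test_auxin_coupled_growth_scales_with_relative_auxin(self):
        p = ModelParams(r=0.01, auxin_coupled_growth=True)
        s = TissueState(0.0, [2.0, 1.0, 0.0], [1.0, 1.0, 1.0])
        out = grow_cells(s, p)
        dl = out.l - 1.0
        assert dl[0] == pytest.approx(2.0 * dl[1], rel=1e-12)
        assert dl[2] == 0.0

    def test_discrete_steps_reach_division_length_at_log4_over_r(self):
        """Accumulated exponential steps hit l_div=4 at ~ln(4)/r = 138.63."""
        p = ModelParams()
        n_steps = int(np.ceil(np.log(4.0) / np.log1p(p.r * p.dt)))
        t_div = n_steps * p.dt
        assert t_div == pytest.approx(np.log(4.0) / p.r, rel=1e-4)


class TestDivision:
    def test_below_threshold_is_identity(self, params):
        s = TissueState(0.0, np.ones(4), np.full(4, 3.9))
        out = divide_cells(s, params)
        assert out.n_cells == 4
        np.testing.assert_array_equal(out.l, s.l)

    def test_exactly_at_threshold_does_not_divide(self, params):
        s = TissueState(0.0, np.ones(3), np.full(3, 4.0))
        assert divide_cells(s, params).n_cells == 3  # strict '>' comparison

    def test_single_division_shares_auxin_and_halves_length(self, params):
        s = TissueState(0.0, [0.9, 1.0, 1.0], [4.2, 1.0, 1.0],
                        np.array(["1", "2", "3"], dtype=object))
        out = divide_cells(s, params)
        assert out.n_cells == 4
        assert list(out.l[:2]) == [2.1, 2.1]
        assert list(out.a[:2]) == [0.9, 0.9]
        assert list(out.lineage[:2]) == ["1.1", "1.2"]
        assert out.total_length == pytest.approx(6.2, abs=1e-12)

    def test_synchronized_division_doubles_cell_count(self, params):
        s = TissueState(0.0, np.linspace(0.5, 1.5, 6), np.full(6, 4.5))
        assert divide_cells(s, params).n_cells == 12

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_division_conserves_length_and_auxin_amount(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        s = TissueState(0.0, rng.uniform(0.1, 2.0, n),
                        rng.uniform(0.5, 6.0, n))
        out = divide_cells(s, ModelParams())
        assert abs(out.total_length - s.total_length) <= 1e-12
        assert abs(out.total_auxin - s.total_auxin) <= 1e-12


class TestConservation:
    def test_closed_system_mass_balance_over_many_steps(self, rng):
        """Without synthesis, turnover or growth, total auxin is invariant."""
        p = ModelParams(A=0.0, G_a=0.0, r=0.0)
        s = TissueState(0.0, rng.uniform(0.5, 1.5, 10), np.ones(10))
        total0 = s.a.sum()
        for _ in range(500):
            s = euler_step(s, p)
        assert abs(s.a.sum() - total0) / total0 <= 1e-12
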