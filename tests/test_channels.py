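"""Channel currents, gate kinetics and population sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pallidalnet.channels import (
    CHANNEL_NAMES,
    DEFAULT_GMAX,
    GATE_EXPONENTS,
    REVERSAL_POTENTIALS,
    ChannelSpec,
    channel_current,
    default_channels,
)
from pallidalnet.kinetics import GateKinetics, boltzmann, load_kinetics
from pallidalnet.neuron import gate_derivative, sample_population


class TestGateKinetics:
    def test_time_constants_positive_over_operating_range(self, channels):
        """tau(V) must stay strictly positive over [-100, +60] mV for
        every gate of every channel."""
        v = np.linspace(-100.0, 60.0, 321)
        for spec in channels.values():
            for role, kin in spec.gates.items():
                assert np.all(kin.time_constant(v) > 0), (spec.name, role)

    def test_steady_state_is_bounded_and_monotone(self, channels):
        v = np.linspace(-120.0, 70.0, 400)
        for spec in channels.values():
            for kin in spec.gates.values():
                x = kin.steady_state(v)
                assert np.all((x >= 0) & (x <= 1))
                diffs = np.diff(x)
                assert np.all(diffs >= 0) if kin.slope > 0 else np.all(diffs <= 0)

    def test_derivative_zero_at_steady_state(self):
        kin = GateKinetics(v_half=-40.0, slope=5.0, tau_min=2.0, tau_max=2.0)
        x_inf = kin.steady_state(-50.0)
        assert gate_derivative(kin, float(x_inf), -50.0) == pytest.approx(0.0)

    def test_derivative_formula(self):
        """x = 0, x_inf = 1, tau = 2 ms -> dx/dt = 0.5 /ms."""
        kin = GateKinetics(v_half=-40.0, slope=5.0, tau_min=2.0, tau_max=2.0)
        # far above v_half the steady state saturates at 1
        assert gate_derivative(kin, 0.0, 60.0) == pytest.approx(0.5, rel=1e-6)

    def test_derivative_rejects_out_of_range_gate(self):
        kin = GateKinetics(v_half=-40.0, slope=5.0, tau_min=2.0, tau_max=2.0)
        with pytest.raises(ValueError):
            gate_derivative(kin, 1.5, -50.0)

    def test_nonpositive_time_constant_rejected(self):
        with pytest.raises(ValueError):
            GateKinetics(v_half=-40.0, slope=5.0, tau_min=0.0, tau_max=2.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        v=st.floats(-100, 60),
        x0=st.floats(0, 1),
    )
    def test_relaxation_converges_to_steady_state(self, v, x0):
        """Euler-integrating the gate ODE from any start converges to
        x_inf(V) and never leaves [0, 1]."""
        kin = GateKinetics(v_half=-45.0, slope=6.0, tau_min=1.0, tau_max=20.0,
                           v_tau=-50.0, k_tau=8.0)
        x = x0
        dt = 0.1
        for _ in range(5000):
            x = x + dt * gate_derivative(kin, x, v)
            assert -1e-9 <= x <= 1 + 1e-9
            x = min(max(x, 0.0), 1.0)
        assert x == pytest.approx(float(kin.steady_state(v)), abs=1e-4)


class TestChannelCurrent:
    def test_zero_at_reversal_potential(self, channels):
        for spec in channels.values():
            gates = {r: 0.5 for r in spec.gates}
            assert channel_current(spec, gates, spec.e_rev) == pytest.approx(0.0)

    def test_kv3_hand_example(self, channels):
        """Kv3 with m = 0.5, h = 1 at V = -60: 0.5^4 * 590 * (-20) = -737.5 pA."""
        spec = channels["Kv3"]
        current = channel_current(spec, {"m": 0.5, "h": 1.0}, -60.0)
        assert current == pytest.approx(0.5**4 * 590.0 * (-80.0 + 60.0))
        assert current == pytest.approx(-737.5)

    def test_hcn_depolarizes_below_reversal(self, channels):
        """HCN_fast fully open at V = -80: 177 * 50 = 8850 pA, positive."""
        spec = channels["HCN_fast"]
        current = channel_current(spec, {"m": 1.0}, -80.0)
        assert current == pytest.approx(8850.0)
        assert current > 0

    def test_gate_out_of_range_rejected(self, channels):
        with pytest.raises(ValueError):
            channel_current(channels["NaF"], {"m": 1.2, "h": 0.5, "s": 0.5}, -60.0)

    def test_unknown_channel_name_rejected(self):
        with pytest.raises(ValueError):
            ChannelSpec(name="SK", g_max=1.0, e_rev=-80.0,
                        exponents=(1, 0, 0), gates={})


class TestChannelTable:
    def test_stoichiometry_and_reversals(self, channels):
        """Every channel carries its tabulated gate exponents, reversal
        potential by ion, and mean maximal conductance."""
        for name in CHANNEL_NAMES:
            spec = channels[name]
            assert spec.exponents == GATE_EXPONENTS[name]
            assert spec.e_rev == REVERSAL_POTENTIALS[name]
            assert spec.g_max == DEFAULT_GMAX[name]

    def test_wrong_exponents_rejected(self, channels):
        with pytest.raises(ValueError):
            ChannelSpec(name="KCNQ", g_max=1.77, e_rev=-80.0,
                        exponents=(3, 1, 0), gates=channels["KCNQ"].gates)


class TestPopulationSampling:
    def test_single_neuron_uses_exact_means(self):
        sample = sample_population(1, seed=0)
        for i, name in enumerate(CHANNEL_NAMES):
            assert sample.gmax[i, 0] == DEFAULT_GMAX[name]

    def test_sample_mean_converges(self):
        sample = sample_population(10_000, seed=1)
        g_nap = sample.row("NaP")
        # truncation at zero biases the mean slightly upward; allow for it
        se = 0.5 * 17.7 / np.sqrt(10_000)
        assert abs(g_nap.mean() - 17.7) < 3 * se + 0.35
        assert np.all(sample.gmax >= 0)

    def test_same_seed_reproduces(self):
        a = sample_population(100, seed=7)
        b = sample_population(100, seed=7)
        np.testing.assert_array_equal(a.gmax, b.gmax)

    def test_invalid_population_size(self):
        with pytest.raises(ValueError):
            sample_population(0, seed=1)

    def test_hcn_zeroing(self):
        sample = sample_population(10, seed=3).without_hcn()
        assert np.all(sample.row("HCN_fast") == 0)
        assert np.all(sample.row("HCN_slow") == 0)
        assert np.all(sample.row("NaP") == sample_population(10, seed=3).row("NaP"))
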