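"""Membrane equation, calcium dynamics, spike detection and
isolated-neuron simulation."""

import numpy as np
import pytest

from pallidalnet.channels import default_channels
from pallidalnet.engine import GPNeuronGroup, NumericalDivergenceError
from pallidalnet.neuron import (
    CalciumParams,
    MembraneParams,
    NeuronState,
    calcium_rhs,
    detect_spikes,
    make_group,
    membrane_rhs,
    pacemaking_summary,
    sample_population,
    simulate_isolated,
    simulate_population,
)


def leak_only_group(v0=-40.0, dt=0.05):
    """A group whose channels all have zero conductance: pure RC membrane."""
    channels = {
        name: spec.with_gmax(0.0) for name, spec in default_channels().items()
    }
    group = GPNeuronGroup(channels, 1, dt=dt)
    group.reset(v0)
    return group


class TestMembraneEquation:
    def test_rest_at_leak_reversal(self):
        assert membrane_rhs(-60.0, []) == pytest.approx(0.0)

    def test_leak_only_hand_value(self):
        """V = -70 with leak only: 4.012 * 10 / 141.6 = 0.2833 mV/ms."""
        assert membrane_rhs(-70.0, []) == pytest.approx(4.012 * 10 / 141.6)
        assert membrane_rhs(-70.0, []) == pytest.approx(0.2833, abs=2e-4)

    def test_leak_only_analytic_solution(self):
        """The passive membrane must follow
        V(t) = E_leak + (V0 - E_leak) exp(-g_leak t / C) to 1e-6 mV."""
        group = leak_only_group(v0=-40.0)
        p = MembraneParams()
        times = []
        vs = []
        for _ in range(4000):  # 200 ms
            group.step()
            times.append(group.t)
            vs.append(group.v[0])
        times = np.asarray(times)
        analytic = p.e_leak + (-40.0 - p.e_leak) * np.exp(
            -p.g_leak * times / p.c_m
        )
        np.testing.assert_allclose(vs, analytic, atol=1e-6)

    def test_membrane_params_invariants(self):
        with pytest.raises(ValueError):
            MembraneParams(c_m=0.0)
        with pytest.raises(ValueError):
            MembraneParams(g_leak=-1.0)


class TestCalcium:
    def test_fixed_point(self):
        p = CalciumParams()
        assert calcium_rhs(7.5 / p.pump_rate, 7.5, p) == pytest.approx(0.0)

    def test_decay_formula(self):
        """I_hva = 0, Ca = 1: d[Ca]/dt = -1e-4 * 15 = -1.5e-3."""
        assert calcium_rhs(1.0, 0.0) == pytest.approx(-1.5e-3)

    def test_steady_state_under_constant_current(self):
        """Constant I_hva = 7.5 drives [Ca] to 7.5/15 = 0.5 (the
        half-downregulation level), via an independent scalar ODE
        integration."""
        p = CalciumParams()
        ca, dt = 0.0, 0.5
        for _ in range(400_000):  # 200 s
            ca += dt * calcium_rhs(ca, 7.5, p)
        assert ca == pytest.approx(0.5, abs=1e-6)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            calcium_rhs(-0.1, 0.0)

    def test_neuron_state_invariants(self):
        with pytest.raises(ValueError):
            NeuronState(v=-60.0, gates={"NaF": {"m": 1.2}})
        with pytest.raises(ValueError):
            NeuronState(v=-60.0, gates={}, ca=-1.0)


class TestSpikeDetection:
    def test_subthreshold_trace_has_no_spikes(self):
        t = np.arange(0.0, 100.0, 1.0)
        train = detect_spikes(t, np.full_like(t, -60.0))
        assert len(train) == 0

    def test_linear_interpolation(self):
        """Samples (1, -10) and (2, +10) put the crossing at t = 1.5."""
        train = detect_spikes([0.0, 1.0, 2.0], [-30.0, -10.0, 10.0])
        assert train.times == pytest.approx([1.5])

    def test_sine_wave_counts_upward_crossings(self):
        t = np.arange(0.0, 1000.0, 0.1)
        v = 30.0 * np.sin(2 * np.pi * t / 100.0) - 10.0
        train = detect_spikes(t, v)
        assert len(train) == 10

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes([], [])


class TestIsolatedNeuron:
    def test_gates_remain_bounded_along_trajectory(self):
        group = make_group(None, 1)
        for _ in range(20_000):  # 1 s of pacemaking
            group.step()
            assert np.all((group.x >= 0.0) & (group.x <= 1.0))

    def test_hcn_current_depolarizing_below_reversal(self, channels):
        """Total HCN current is positive whenever V < E_hcn and the
        activation gates are open."""
        group = make_group(None, 1)
        group.reset(-80.0)
        hcn_rows = [group.channel_names.index(n) for n in ("HCN_fast", "HCN_slow")]
        g = group._channel_conductances()
        current = sum(g[r] * (-30.0 - group.v) for r in hcn_rows)
        assert current[0] > 0

    def test_mean_neuron_pacemakes_in_target_range(self):
        """The mean-parameter neuron fires regularly at roughly 22 Hz
        with no input."""
        train, _ = simulate_isolated([(3000.0, 0.0)], record_v=False)
        window = train.slice(500.0, 3000.0)
        assert 18.0 < window.rate < 28.0
        isis = np.diff(window.times)
        assert np.std(isis) / np.mean(isis) < 0.1  # regular

    def test_firing_rate_monotone_in_depolarizing_current(self):
        """Rate is non-decreasing over a grid of depolarizing currents,
        reaching the fast-firing regime (~200 Hz) at strong drive."""
        rates = []
        for i_ext in (0.0, 100.0, 300.0, 600.0, 1200.0, 2000.0):
            train, _ = simulate_isolated([(1500.0, i_ext)], record_v=False)
            rates.append(train.slice(500.0, 1500.0).rate)
        assert all(b >= a - 1.0 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 180.0

    def test_sag_and_rebound_require_hcn(self):
        """Hyperpolarizing current produces a sag (recovery toward rest
        during the step) with HCN present; zeroing HCN abolishes the sag
        and delays the post-inhibitory rebound spike."""
        protocol = [(1000.0, 0.0), (1000.0, -200.0), (1000.0, 0.0)]
        sample = sample_population(1, seed=0)

        def run(s):
            train, (ts, v) = simulate_isolated(protocol, sample=s)
            seg = (ts >= 1100.0) & (ts < 2000.0)
            sag = v[seg][-1] - v[seg].min()
            rebound = train.times[train.times > 2000.0]
            first = rebound[0] - 2000.0 if len(rebound) else np.inf
            return sag, first

        sag_intact, rebound_intact = run(sample)
        sag_blocked, rebound_blocked = run(sample.without_hcn())
        assert sag_intact > 1.0
        assert sag_blocked < 0.25
        assert rebound_blocked > 2.0 * rebound_intact

    def test_hcn_knockout_slows_population_pacemaking(self):
        sample = sample_population(40, seed=5)
        intact = simulate_population(sample, 2500.0)
        blocked = simulate_population(sample.without_hcn(), 2500.0)
        pm_i, rates_i = pacemaking_summary(intact)
        pm_b, rates_b = pacemaking_summary(blocked)
        assert np.nanmean(rates_b[pm_b]) < np.nanmean(rates_i[pm_i])

    def test_divergence_guard_raises_with_diagnostics(self):
        group = leak_only_group(v0=-40.0)
        group.v[0] = -500.0
        with pytest.raises(NumericalDivergenceError) as err:
            group.check_guard()
        assert err.value.neuron == 0

    def test_dt_halving_preserves_firing_rate(self):
        """Exponential-Euler rates at dt = 0.05 and 0.025 ms agree
        within 2%."""
        rates = []
        for dt in (0.05, 0.025):
            train, _ = simulate_isolated([(2000.0, 0.0)], dt=dt, record_v=False)
            rates.append(train.slice(500.0, 2000.0).rate)
        assert rates[0] == pytest.approx(rates[1], rel=0.02)
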