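"""Vectorized fixed-step integrator for populations of GP neurons.

All state equations of the model are linear in their own variable given
the others: each gate relaxes toward ``x_inf(V)`` with time constant
``tau(V)``; the membrane equation is linear in V given the gates and
synaptic conductances; calcium relaxes toward ``I_hva / k_ca``.  The
integrator exploits this by advancing every variable with its locally
exact exponential update (exponential Euler), which is unconditionally
stable, exact for the passive membrane, and accurate at the default
0.05 ms step (convergence under step halving is covered by the tests).

Spikes are upward crossings of 0 mV, timed by linear interpolation
between the bracketing steps.
"""

from __future__ import annotations

import numpy as np

from .channels import CHANNEL_NAMES, ChannelSpec

__all__ = ["NumericalDivergenceError", "GPNeuronGroup"]

DEFAULT_DT = 0.05  # ms
SPIKE_THRESHOLD = 0.0  # mV, positive-going crossing
V_GUARD = (-120.0, 70.0)  # mV operating range; leaving it is a blow-up


class NumericalDivergenceError(RuntimeError):
    """Raised when a membrane potential leaves the plausible range."""

    def __init__(self, neuron: int, time: float, v: float):
        self.neuron = int(neuron)
        self.time = float(time)
        self.v = float(v)
        super().__init__(
            f"membrane potential of neuron {neuron} diverged to "
            f"{v:.1f} mV at t = {time:.3f} ms"
        )


class GPNeuronGroup:
    """A population of GP neurons sharing gate kinetics.

    Heterogeneity across neurons lives entirely in the per-neuron
    maximal conductances ``gmax`` (shape ``(n_channels, n)``); the HCN
    rows are mutable so that activity-dependent downregulation can
    adjust them between integration steps.

    Parameters
    ----------
    channels : dict[str, ChannelSpec]
        Template channel set (kinetics and reversal potentials); the
        template ``g_max`` values are used for any channel not
        overridden in ``gmax``.
    n : int
        Number of neurons.
    gmax : array or None
        Optional ``(n_channels, n)`` per-neuron maximal conductances (nS).
    c_m, g_leak, e_leak : float
        Passive membrane parameters (pF, nS, mV).
    ca_epsilon, ca_pump_rate : float
        Calcium buffering scale and pump rate.
    e_ampa, e_gaba : float
        Synaptic reversal potentials (mV) used for the excitatory and
        inhibitory conductance inputs to :meth:`step`.
    """

    def __init__(
        self,
        channels: dict[str, ChannelSpec],
        n: int,
        gmax=None,
        *,
        c_m: float = 141.6,
        g_leak: float = 4.012,
        e_leak: float = -60.0,
        ca_epsilon: float = 1e-4,
        ca_pump_rate: float = 15.0,
        e_ampa: float = 0.0,
        e_gaba: float = -80.0,
        dt: float = DEFAULT_DT,
    ):
        if n < 1:
            raise ValueError("need at least one neuron")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.n = int(n)
        self.dt = float(dt)
        self.c_m = float(c_m)
        self.g_leak = float(g_leak)
        self.e_leak = float(e_leak)
        self.ca_epsilon = float(ca_epsilon)
        self.ca_pump_rate = float(ca_pump_rate)
        self.e_ampa = float(e_ampa)
        self.e_gaba = float(e_gaba)
        self.channel_names = list(CHANNEL_NAMES)
        self._compile(channels)
        if gmax is None:
            gmax = np.repeat(self._template_gmax[:, None], n, axis=1)
        gmax = np.asarray(gmax, dtype=float)
        if gmax.shape != (len(self.channel_names), n):
            raise ValueError("gmax must have shape (n_channels, n)")
        if np.any(gmax < 0):
            raise ValueError("maximal conductances must be non-negative")
        self.gmax = gmax.copy()
        self.t = 0.0
        self.reset(self.e_leak)

    # ------------------------------------------------------------------
    def _compile(self, channels: dict[str, ChannelSpec]) -> None:
        vhalf, slope, tmin, tmax, vtau, ktau = [], [], [], [], [], []
        gate_exp: list[int] = []
        per_channel_gates: list[list[int]] = []
        template_gmax = []
        e_rev = []
        idx = 0
        for name in self.channel_names:
            spec = channels[name]
            template_gmax.append(spec.g_max)
            e_rev.append(spec.e_rev)
            rows = []
            for role, exponent in zip("mhs", spec.exponents):
                if exponent == 0:
                    continue
                kin = spec.gates[role]
                vhalf.append(kin.v_half)
                slope.append(kin.slope)
                tmin.append(kin.tau_min)
                tmax.append(kin.tau_max)
                vtau.append(kin.v_tau)
                ktau.append(kin.k_tau)
                gate_exp.append(exponent)
                rows.append(idx)
                idx += 1
            per_channel_gates.append(rows)
        self.n_gates = idx
        col = lambda a: np.asarray(a, dtype=float)[:, None]
        self._vhalf = col(vhalf)
        self._slope = col(slope)
        self._tmin = col(tmin)
        self._tmax = col(tmax)
        self._vtau = col(vtau)
        self._ktau = col(ktau)
        self._gate_exp = np.asarray(gate_exp, dtype=float)[:, None]
        self._per_channel_gates = per_channel_gates
        self._template_gmax = np.asarray(template_gmax, dtype=float)
        self._e_rev = np.asarray(e_rev, dtype=float)[:, None]
        self._hva_index = self.channel_names.index("HVA")
        self._e_ca = channels["HVA"].e_rev

    # ------------------------------------------------------------------
    def gate_steady_state(self, v):
        """x_inf for every gate at per-neuron voltages ``v`` -> (n_gates, n)."""
        v = np.atleast_1d(np.asarray(v, dtype=float))
        return 1.0 / (1.0 + np.exp((self._vhalf - v[None, :]) / self._slope))

    def gate_time_constant(self, v):
        v = np.atleast_1d(np.asarray(v, dtype=float))
        return self._tmin + (self._tmax - self._tmin) / (
            1.0 + np.exp((v[None, :] - self._vtau) / self._ktau)
        )

    def reset(self, v0=None) -> None:
        """Initialize V, gates at steady state for V, and Ca at its fixed point."""
        if v0 is None:
            v0 = self.e_leak
        self.v = np.full(self.n, float(v0)) if np.isscalar(v0) else np.asarray(
            v0, dtype=float
        ).copy()
        self.x = self.gate_steady_state(self.v)
        i_hva = self._channel_conductances()[self._hva_index] * (
            self._e_ca - self.v
        )
        self.ca = np.maximum(i_hva, 0.0) / self.ca_pump_rate
        self.t = 0.0

    def _channel_conductances(self) -> np.ndarray:
        """Effective conductance g_max * m^mu h^rho s^phi -> (n_channels, n)."""
        powered = self.x ** self._gate_exp
        g = np.empty((len(self.channel_names), self.n))
        for c, rows in enumerate(self._per_channel_gates):
            prod = powered[rows[0]]
            for r in rows[1:]:
                prod = prod * powered[r]
            g[c] = prod
        return g * self.gmax

    @property
    def hva_current(self) -> np.ndarray:
        """Instantaneous HVA calcium current (pA, depolarizing positive)."""
        return self._channel_conductances()[self._hva_index] * (self._e_ca - self.v)

    # ------------------------------------------------------------------
    def step(self, g_exc=0.0, g_inh=0.0, i_ext=0.0):
        """Advance one step of ``dt`` ms.

        ``g_exc``/``g_inh`` are per-neuron total synaptic conductances
        (nS) at the AMPA/GABA reversal potentials; ``i_ext`` is an
        injected current (pA).  Returns ``(spiked, frac)`` where
        ``spiked`` is a boolean mask of threshold crossings during the
        step and ``frac`` the interpolated crossing position in [0, 1).
        """
        dt = self.dt
        v_prev = self.v
        # gates: locally exact relaxation at the pre-step voltage
        x_inf = self.gate_steady_state(v_prev)
        tau = self.gate_time_constant(v_prev)
        self.x = x_inf + (self.x - x_inf) * np.exp(-dt / tau)
        # membrane: linear in V given gates and synapses
        g_chan = self._channel_conductances()
        g_total = self.g_leak + g_chan.sum(axis=0) + g_exc + g_inh
        drive = (
            self.g_leak * self.e_leak
            + (g_chan * self._e_rev).sum(axis=0)
            + g_exc * self.e_ampa
            + g_inh * self.e_gaba
            + i_ext
        )
        v_inf = drive / g_total
        self.v = v_inf + (v_prev - v_inf) * np.exp(-g_total * dt / self.c_m)
        # calcium: relaxes toward I_hva / k_ca
        i_hva = g_chan[self._hva_index] * (self._e_ca - self.v)
        ca_inf = i_hva / self.ca_pump_rate
        self.ca = ca_inf + (self.ca - ca_inf) * np.exp(
            -self.ca_epsilon * self.ca_pump_rate * dt
        )
        self.t += dt
        spiked = (v_prev < SPIKE_THRESHOLD) & (self.v >= SPIKE_THRESHOLD)
        if spiked.any():
            dv = self.v - v_prev
            frac = np.where(spiked, (SPIKE_THRESHOLD - v_prev) / np.where(dv == 0, 1, dv), 0.0)
        else:
            frac = np.zeros(self.n)
        return spiked, frac

    def check_guard(self) -> None:
        """Raise `NumericalDivergenceError` if any V left the guard range."""
        bad = (self.v < V_GUARD[0]) | (self.v > V_GUARD[1])
        if bad.any():
            i = int(np.argmax(bad))
            raise NumericalDivergenceError(i, self.t, self.v[i])

    # ------------------------------------------------------------------
    def run(
        self,
        duration: float,
        *,
        i_ext=0.0,
        record_v: bool = False,
        record_stride: int = 4,
        guard_interval: float = 10.0,
        callback=None,
        callback_interval: float = 1.0,
    ):
        """Integrate for ``duration`` ms with constant external current.

        ``callback(group)``, if given, is invoked every
        ``callback_interval`` ms between steps (used for HCN
        downregulation control steps).  Returns ``(spikes, trace)``:
        ``spikes`` is a list of per-neuron spike-time arrays (ms,
        relative to the group clock at entry) and ``trace`` a
        ``(times, V)`` pair or ``None``.
        """
        n_steps = int(round(duration / self.dt))
        spike_lists: list[list[float]] = [[] for _ in range(self.n)]
        guard_every = max(1, int(round(guard_interval / self.dt)))
        cb_every = max(1, int(round(callback_interval / self.dt)))
        times, vs = [], []
        for k in range(n_steps):
            t0 = self.t
            spiked, frac = self.step(i_ext=i_ext)
            if spiked.any():
                for i in np.nonzero(spiked)[0]:
                    spike_lists[i].append(t0 + frac[i] * self.dt)
            if record_v and k % record_stride == 0:
                times.append(self.t)
                vs.append(self.v.copy())
            if (k + 1) % guard_every == 0:
                self.check_guard()
            if callback is not None and (k + 1) % cb_every == 0:
                callback(self)
        spikes = [np.asarray(s) for s in spike_lists]
        trace = (np.asarray(times), np.asarray(vs).T) if record_v else None
        return spikes, trace
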