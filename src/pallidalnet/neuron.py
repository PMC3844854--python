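"""Single-compartment conductance-based GP neuron.

The membrane equation sums a leak current, ten voltage-gated channel
currents, synaptic current and injected current over a single
compartment:

    C dV/dt = g_leak (E_leak - V) + sum_X m^mu h^rho s^phi g_X (E_X - V)
              + I_syn + I_ext

with units pF, nS, mV, pA and ms throughout.  Intracellular calcium
follows the HVA current,

    d[Ca]/dt = epsilon (I_hva - k_Ca [Ca]),

and is a dimensionless activity sensor used by the HCN downregulation
rule.  Population heterogeneity applies Gaussian noise to the NaP
conductance (50% CV) and both HCN conductances (30% CV), truncated at
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (
    CHANNEL_NAMES,
    DEFAULT_GMAX,
    HETEROGENEOUS_CV,
    ChannelSpec,
    channel_current,
    default_channels,
)
from .engine import DEFAULT_DT, GPNeuronGroup
from .kinetics import GateKinetics
from .seeding import stream_rng
from .spiketrain import SpikeTrain

__all__ = [
    "MembraneParams",
    "CalciumParams",
    "NeuronState",
    "PopulationSample",
    "membrane_rhs",
    "calcium_rhs",
    "gate_derivative",
    "detect_spikes",
    "sample_population",
    "make_group",
    "simulate_isolated",
    "simulate_population",
    "pacemaking_summary",
]

BURN_IN_MS = 500.0  # transient excluded from rate statistics


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane: capacitance (pF), leak conductance (nS), leak
    reversal (mV)."""

    c_m: float = 141.6
    g_leak: float = 4.012
    e_leak: float = -60.0

    def __post_init__(self):
        if self.c_m <= 0:
            raise ValueError("capacitance must be positive")
        if self.g_leak < 0:
            raise ValueError("leak conductance must be non-negative")


@dataclass(frozen=True)
class CalciumParams:
    """Calcium buffering scale and pump rate (dimensionless model units)."""

    epsilon: float = 1e-4
    pump_rate: float = 15.0

    def __post_init__(self):
        if self.epsilon <= 0 or self.pump_rate <= 0:
            raise ValueError("calcium parameters must be positive")


@dataclass
class NeuronState:
    """Dynamic state of one GP neuron."""

    v: float
    gates: dict[str, dict[str, float]]
    ca: float = 0.0
    g_hcn_fast: float = DEFAULT_GMAX["HCN_fast"]
    g_hcn_slow: float = DEFAULT_GMAX["HCN_slow"]

    def __post_init__(self):
        for channel, roles in self.gates.items():
            for role, x in roles.items():
                if not 0.0 <= x <= 1.0:
                    raise ValueError(
                        f"gate {channel}.{role} = {x} outside [0, 1]"
                    )
        if self.ca < 0:
            raise ValueError("calcium must be non-negative")
        if self.g_hcn_fast < 0 or self.g_hcn_slow < 0:
            raise ValueError("HCN conductances must be non-negative")


@dataclass(frozen=True)
class PopulationSample:
    """Per-neuron maximal conductances for a heterogeneous population.

    ``gmax`` has shape ``(n_channels, n)`` ordered as `CHANNEL_NAMES`;
    only NaP and the two HCN rows vary across neurons.
    """

    gmax: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.gmax.shape[1]

    def row(self, channel: str) -> np.ndarray:
        return self.gmax[CHANNEL_NAMES.index(channel)]

    def without_hcn(self) -> "PopulationSample":
        """The same sample with both HCN conductances zeroed (simulated
        channel blockade)."""
        gmax = self.gmax.copy()
        gmax[CHANNEL_NAMES.index("HCN_fast")] = 0.0
        gmax[CHANNEL_NAMES.index("HCN_slow")] = 0.0
        return PopulationSample(gmax, self.seed)


# ----------------------------------------------------------------------
# Right-hand sides (reference scalar forms; the engine vectorizes them)

def membrane_rhs(
    v: float,
    channel_currents,
    params: MembraneParams = MembraneParams(),
    i_syn: float = 0.0,
    i_ext: float = 0.0,
) -> float:
    """dV/dt (mV/ms) given the already-evaluated channel currents (pA)."""
    total = params.g_leak * (params.e_leak - v) + i_syn + i_ext
    total += float(np.sum(channel_currents))
    return total / params.c_m


def calcium_rhs(ca: float, i_hva: float, params: CalciumParams = CalciumParams()) -> float:
    """d[Ca]/dt = epsilon * (I_hva - k_Ca * [Ca])."""
    if ca < 0:
        raise ValueError("calcium must be non-negative")
    return params.epsilon * (i_hva - params.pump_rate * ca)


def gate_derivative(kin: GateKinetics, x: float, v: float) -> float:
    """First-order gate relaxation d(gate)/dt = (x_inf(V) - x)/tau(V)."""
    return float(kin.derivative(x, v))


# ----------------------------------------------------------------------

def detect_spikes(times, v, unit: int = 0) -> SpikeTrain:
    """Spike times from a voltage trace: positive-going 0 mV crossings,
    linearly interpolated between the bracketing samples."""
    times = np.asarray(times, dtype=float)
    v = np.asarray(v, dtype=float)
    if times.size == 0:
        raise ValueError("empty voltage trace")
    if times.size != v.size:
        raise ValueError("times and voltages must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    up = np.nonzero((v[:-1] < 0.0) & (v[1:] >= 0.0))[0]
    frac = -v[up] / (v[up + 1] - v[up])
    spikes = times[up] + frac * (times[up + 1] - times[up])
    return SpikeTrain(unit, spikes, times[0], times[-1] + 1e-9)


def sample_population(
    n: int,
    seed: int,
    *,
    means: dict[str, float] | None = None,
) -> PopulationSample:
    """Draw per-neuron conductances: NaP ~ N(mean, 50% CV), HCN fast and
    slow ~ N(mean, 30% CV), truncated at zero; all other channels fixed
    at their population means.  Reproducible from ``seed``."""
    if n < 1:
        raise ValueError("population size must be at least 1")
    means = {**DEFAULT_GMAX, **(means or {})}
    rng = stream_rng(seed, "population")
    gmax = np.empty((len(CHANNEL_NAMES), n))
    for i, name in enumerate(CHANNEL_NAMES):
        mean = means[name]
        cv = HETEROGENEOUS_CV.get(name)
        if cv is None or n == 1:
            gmax[i] = mean
        else:
            gmax[i] = np.maximum(0.0, rng.normal(mean, cv * mean, size=n))
    return PopulationSample(gmax, int(seed))


def make_group(
    sample: PopulationSample | None = None,
    n: int = 1,
    *,
    channels: dict[str, ChannelSpec] | None = None,
    membrane: MembraneParams = MembraneParams(),
    calcium: CalciumParams = CalciumParams(),
    dt: float = DEFAULT_DT,
    kinetics_path=None,
) -> GPNeuronGroup:
    """Build the vectorized integrator for a (possibly heterogeneous)
    population.  With no sample, all neurons use the mean conductances."""
    channels = channels or default_channels(kinetics_path)
    gmax = sample.gmax if sample is not None else None
    if sample is not None:
        n = sample.n
    return GPNeuronGroup(
        channels,
        n,
        gmax,
        c_m=membrane.c_m,
        g_leak=membrane.g_leak,
        e_leak=membrane.e_leak,
        ca_epsilon=calcium.epsilon,
        ca_pump_rate=calcium.pump_rate,
        dt=dt,
    )


def simulate_isolated(
    protocol,
    *,
    sample: PopulationSample | None = None,
    channels: dict[str, ChannelSpec] | None = None,
    dt: float = DEFAULT_DT,
    record_v: bool = True,
    record_stride: int = 4,
    kinetics_path=None,
):
    """Simulate one isolated neuron through a current-injection protocol.

    ``protocol`` is a sequence of ``(duration_ms, i_ext_pA)`` steps.
    Returns ``(train, trace)`` where ``trace`` is ``(times, v)``.
    """
    group = make_group(sample, n=1, channels=channels, dt=dt,
                       kinetics_path=kinetics_path)
    all_spikes: list[float] = []
    times_parts, v_parts = [], []
    total = 0.0
    for duration, i_ext in protocol:
        if duration <= 0:
            raise ValueError("protocol step durations must be positive")
        spikes, trace = group.run(
            duration, i_ext=i_ext, record_v=record_v, record_stride=record_stride
        )
        all_spikes.extend(spikes[0].tolist())
        if record_v:
            times_parts.append(trace[0])
            v_parts.append(trace[1][0])
        total += duration
    train = SpikeTrain(0, np.asarray(all_spikes), 0.0, total)
    trace = (
        (np.concatenate(times_parts), np.concatenate(v_parts)) if record_v else None
    )
    return train, trace


def simulate_population(
    sample: PopulationSample,
    duration: float,
    *,
    i_ext: float = 0.0,
    dt: float = DEFAULT_DT,
    channels: dict[str, ChannelSpec] | None = None,
    kinetics_path=None,
) -> list[SpikeTrain]:
    """Simulate every neuron of a sample in isolation (vectorized)."""
    group = make_group(sample, channels=channels, dt=dt, kinetics_path=kinetics_path)
    spikes, _ = group.run(duration, i_ext=i_ext)
    return [SpikeTrain(i, s, 0.0, duration) for i, s in enumerate(spikes)]


def pacemaking_summary(trains: list[SpikeTrain], burn_in: float = BURN_IN_MS):
    """Persistent-pacemaker statistics for isolated-neuron runs.

    A neuron counts as a persistent pacemaker if, after the burn-in, it
    fires at least two spikes and keeps firing to the end of the window
    (its final silent gap is no longer than three times its median
    inter-spike interval, with a 500 ms floor).  Returns
    ``(is_pacemaking, rates_hz)`` arrays; rates are NaN for
    non-pacemakers.
    """
    n = len(trains)
    pacemaking = np.zeros(n, dtype=bool)
    rates = np.full(n, np.nan)
    for i, train in enumerate(trains):
        window = train.slice(burn_in, train.t_stop)
        if len(window) < 2:
            continue
        isis = np.diff(window.times)
        tail_gap = window.t_stop - window.times[-1]
        if tail_gap > max(3.0 * np.median(isis), 500.0):
            continue
        pacemaking[i] = True
        rates[i] = window.rate
    return pacemaking, rates
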