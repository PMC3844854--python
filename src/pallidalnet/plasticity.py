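"""Activity-dependent downregulation of HCN maximal conductance.

GP neurons that burst at high rates accumulate intracellular calcium
through their HVA channels.  When the calcium sensor exceeds a threshold
``t_hcn``, the maximal conductance of both HCN channels is decremented
between integration control steps by a sigmoid function of calcium:

    g(t + dt) = max(0, g(t) - k_hcn * dt / (1 + exp((theta - Ca)/sigma)))

The rule only ever decreases conductance (no recovery is modelled), so
``g_hcn`` is non-increasing along any trajectory and constant whenever
calcium stays at or below threshold.

The decrement ceiling ``k_hcn`` is 6e-4 uS/ms (0.6 nS/ms): with the
update applied at 1 ms control intervals a strongly bursting neuron
loses its HCN conductance over a few seconds of elevated calcium, while
tonically pacemaking neurons sit below threshold and are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DownregulationParams", "apply_downregulation", "make_control_callback"]


@dataclass(frozen=True)
class DownregulationParams:
    """Parameters of the calcium-gated HCN downregulation rule.

    ``t_hcn``: calcium threshold above which downregulation occurs;
    ``k_hcn``: maximum conductance decrement per unit time (nS/ms,
    equal to 6e-4 uS/ms); ``theta``: calcium level of half-maximal
    decrement; ``sigma``: sigmoid slope; ``update_interval``: control
    interval between discrete adjustments (ms).
    """

    t_hcn: float = 0.2
    k_hcn: float = 0.6
    theta: float = 0.5
    sigma: float = 0.1
    update_interval: float = 1.0
    enabled: bool = True

    def __post_init__(self):
        for name in ("t_hcn", "k_hcn", "theta", "sigma", "update_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def apply_downregulation(g_hcn, ca, params: DownregulationParams = DownregulationParams()):
    """One discrete downregulation update of an HCN maximal conductance.

    Vectorized over neurons.  Below threshold (or when disabled) the
    conductance is returned unchanged; above threshold it is decremented
    by ``k_hcn * dt`` scaled by the calcium sigmoid, clamped at zero.
    """
    g_hcn = np.asarray(g_hcn, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(g_hcn < 0):
        raise ValueError("g_hcn must be non-negative")
    if np.any(ca < 0):
        raise ValueError("calcium must be non-negative")
    if not params.enabled:
        return g_hcn.copy() if g_hcn.ndim else float(g_hcn)
    decrement = (
        params.k_hcn
        * params.update_interval
        / (1.0 + np.exp((params.theta - ca) / params.sigma))
    )
    updated = np.where(ca > params.t_hcn, np.maximum(0.0, g_hcn - decrement), g_hcn)
    return updated if updated.ndim else float(updated)


def measure_post_downregulation_pacemaking(
    result,
    *,
    duration: float = 3000.0,
    min_run: float = 6500.0,
):
    """Intrinsic pacemaking after a network run: freeze the (possibly
    downregulated) conductances, sever all synapses and simulate every
    neuron in isolation.

    ``result`` is a `network.SimulationResult`.  Returns
    ``(mean_rate_hz, rates, is_pacemaking)`` where the mean is taken
    over neurons that still pacemake.  Raises if the network run was
    shorter than the downregulation window ``min_run``.
    """
    from .neuron import PopulationSample, pacemaking_summary, simulate_population

    if result.config.duration < min_run:
        raise ValueError(
            f"network run ({result.config.duration} ms) shorter than the "
            f"downregulation window ({min_run} ms)"
        )
    frozen = PopulationSample(result.final_gmax.copy(), result.config.seed)
    trains = simulate_population(frozen, duration, dt=result.config.dt)
    pacemaking, rates = pacemaking_summary(trains)
    mean_rate = float(np.nanmean(rates[pacemaking])) if pacemaking.any() else float("nan")
    return mean_rate, rates, pacemaking


def make_control_callback(params: DownregulationParams):
    """Callback for the integrator: decrement both HCN rows of a
    `GPNeuronGroup` from its per-neuron calcium at each control step."""
    def _callback(group):
        if not params.enabled:
            return
        for name in ("HCN_fast", "HCN_slow"):
            row = group.channel_names.index(name)
            group.gmax[row] = apply_downregulation(group.gmax[row], group.ca, params)
    return _callback
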