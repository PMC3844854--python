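"""Wiring and whole-network simulation of the STN-driven GP population.

The standard network has 100 conductance-based GP neurons, each
inhibiting ``gp_fanout`` = 20 randomly chosen other GP neurons (no
self-connections), and 50 stochastic STN units each exciting
``stn_fanout`` = 2 randomly chosen GP neurons.  The Parkinsonian
condition makes exactly three changes: the STN active-phase rate rises
from 30 to 60 Hz, the mean STN->GP conductance doubles (0.1 -> 0.2 nS)
and the mean GP->GP conductance doubles (0.5 -> 1.0 nS).  Scaling
presets enlarge the populations at constant fan-out, and a beta variant
drives the network with a 70 ms (~14 Hz) cycle instead of the 1300 ms
slow wave.

All randomness (population heterogeneity, wiring, unitary conductance
draws, STN spike trains) flows from the config seed through named
streams, so a simulation is bit-reproducible from its config echo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import DEFAULT_DT
from .neuron import (
    CalciumParams,
    MembraneParams,
    PopulationSample,
    make_group,
    sample_population,
)
from .plasticity import DownregulationParams, make_control_callback
from .seeding import stream_rng, stream_seed
from .spiketrain import SpikeTrain
from .stn import IFGeneratorParams, SWAProtocol, generate_stn_population
from .synapses import SynapseParams, draw_unitary_conductances

__all__ = [
    "NetworkConfig",
    "ConnectivityGraph",
    "ResolvedCondition",
    "SimulationResult",
    "build_connectivity",
    "apply_condition",
    "simulate_network",
    "run_trial_battery",
]

CONDITIONS = ("healthy", "parkinsonian")


@dataclass(frozen=True)
class NetworkConfig:
    """Full specification of one network simulation."""

    n_gp: int = 100
    n_stn: int = 50
    gp_fanout: int = 20
    stn_fanout: int = 2
    condition: str = "healthy"
    beta: bool = False
    beta_high_inhibition: bool = False
    duration: float = 13000.0
    analysis_window_start: float = 6500.0
    downregulation: DownregulationParams = field(default_factory=DownregulationParams)
    generator: IFGeneratorParams = field(default_factory=IFGeneratorParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    dt: float = DEFAULT_DT
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0 < self.gp_fanout < self.n_gp:
            raise ValueError("gp_fanout must be positive and below n_gp")
        if self.stn_fanout < 1 or self.stn_fanout > self.n_gp:
            raise ValueError("stn_fanout out of range")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.analysis_window_start < self.duration:
            raise ValueError("analysis window must start inside the run")

    @classmethod
    def scaled(cls, n_gp: int, condition: str = "parkinsonian", **kw) -> "NetworkConfig":
        """Scaling presets: population grows, per-neuron fan-outs stay
        constant (100 GP/50 STN, 200/100, 300/150)."""
        return cls(n_gp=n_gp, n_stn=n_gp // 2, condition=condition, **kw)


@dataclass(frozen=True)
class ResolvedCondition:
    """Concrete protocol and synapse presets implied by a config."""

    protocol: SWAProtocol
    gp_gp: SynapseParams
    stn_gp: SynapseParams


def apply_condition(cfg: NetworkConfig) -> ResolvedCondition:
    """Resolve condition (and beta variant) to protocol + synapse presets.

    healthy -> 30 Hz active STN, g_SG 0.1 nS, g_GG 0.5 nS;
    parkinsonian -> 60 Hz, 0.2 nS, 1.0 nS.  The beta variant swaps in
    the 70 ms cycle; with ``beta_high_inhibition`` the GP->GP mean
    conductance is raised to 3.0 nS.
    """
    if cfg.beta:
        protocol = SWAProtocol.beta(
            active_rate=60.0 if cfg.condition == "parkinsonian" else 30.0
        )
        syn_label = "beta_high_inhibition" if cfg.beta_high_inhibition else cfg.condition
        return ResolvedCondition(
            protocol,
            SynapseParams.gp_gp(syn_label),
            SynapseParams.stn_gp(cfg.condition),
        )
    protocol = (
        SWAProtocol.parkinsonian()
        if cfg.condition == "parkinsonian"
        else SWAProtocol.healthy()
    )
    return ResolvedCondition(
        protocol,
        SynapseParams.gp_gp(cfg.condition),
        SynapseParams.stn_gp(cfg.condition),
    )


@dataclass(frozen=True)
class ConnectivityGraph:
    """Directed GP->GP and STN->GP edges with per-edge conductances.

    ``gp_targets[i]`` lists the ``gp_fanout`` distinct GP neurons
    inhibited by GP neuron ``i`` (never ``i`` itself);
    ``stn_targets[j]`` lists the GP neurons excited by STN unit ``j``.
    ``gp_g``/``stn_g`` hold the corresponding unitary conductances (nS).
    """

    gp_targets: np.ndarray
    gp_g: np.ndarray
    stn_targets: np.ndarray
    stn_g: np.ndarray

    def __post_init__(self):
        n_gp = self.gp_targets.shape[0]
        for i in range(n_gp):
            row = self.gp_targets[i]
            if len(set(row.tolist())) != len(row) or i in row:
                raise ValueError("GP targets must be distinct and exclude self")
        if np.any(self.gp_g < 0) or np.any(self.stn_g < 0):
            raise ValueError("conductances must be non-negative")

    def edge_table(self) -> list[tuple[int, int, str, float]]:
        """(pre, post, kind, g_syn) rows for delimited-text export."""
        rows = []
        for i, (targets, gs) in enumerate(zip(self.gp_targets, self.gp_g)):
            rows += [(i, int(t), "gp_gp", float(g)) for t, g in zip(targets, gs)]
        for j, (targets, gs) in enumerate(zip(self.stn_targets, self.stn_g)):
            rows += [(j, int(t), "stn_gp", float(g)) for t, g in zip(targets, gs)]
        return rows


def build_connectivity(cfg: NetworkConfig, seed: int | None = None) -> ConnectivityGraph:
    """Draw the random wiring: per GP neuron, ``gp_fanout`` distinct
    targets uniformly at random excluding itself; per STN unit,
    ``stn_fanout`` GP targets.  Unitary conductances are Gaussian with
    30% CV, truncated at zero."""
    resolved = apply_condition(cfg)
    rng = stream_rng(cfg.seed if seed is None else seed, "connectivity")
    gp_targets = np.empty((cfg.n_gp, cfg.gp_fanout), dtype=int)
    for i in range(cfg.n_gp):
        others = np.delete(np.arange(cfg.n_gp), i)
        gp_targets[i] = rng.choice(others, size=cfg.gp_fanout, replace=False)
    stn_targets = rng.integers(0, cfg.n_gp, size=(cfg.n_stn, cfg.stn_fanout))
    gp_g = draw_unitary_conductances(
        gp_targets.size, resolved.gp_gp, rng
    ).reshape(gp_targets.shape)
    stn_g = draw_unitary_conductances(
        stn_targets.size, resolved.stn_gp, rng
    ).reshape(stn_targets.shape)
    return ConnectivityGraph(gp_targets, gp_g, stn_targets, stn_g)


@dataclass
class SimulationResult:
    """Output of one network simulation."""

    config: NetworkConfig
    resolved: ResolvedCondition
    sub_seeds: dict[str, int]
    sample: PopulationSample
    graph: ConnectivityGraph
    stn_trains: list[SpikeTrain]
    gp_trains: list[SpikeTrain]
    final_gmax: np.ndarray
    initial_gmax: np.ndarray

    @property
    def analysis_window(self) -> tuple[float, float]:
        return (self.config.analysis_window_start, self.config.duration)


def simulate_network(
    cfg: NetworkConfig,
    *,
    record_v: bool = False,
    disable_synapses: bool = False,
) -> SimulationResult:
    """Run one full network simulation.

    GP neurons are integrated with the vectorized exponential-Euler
    engine; STN spikes arrive as conductance-increment events through
    the drawn wiring; GP spikes feed back through the inhibitory
    collaterals one step later; HCN downregulation control steps are
    applied every ``downregulation.update_interval`` ms.
    """
    resolved = apply_condition(cfg)
    sub_seeds = {
        name: stream_seed(cfg.seed, name)
        for name in ("population", "connectivity", "stn")
    }
    sample = sample_population(cfg.n_gp, seed=sub_seeds["population"])
    graph = build_connectivity(cfg, seed=sub_seeds["connectivity"])
    stn_trains = generate_stn_population(
        cfg.n_stn, cfg.duration, resolved.protocol, cfg.generator,
        seed=sub_seeds["stn"],
    )
    group = make_group(
        sample, membrane=cfg.membrane, calcium=cfg.calcium, dt=cfg.dt
    )
    initial_gmax = group.gmax.copy()

    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    # STN spike events flattened to (step, target, weight), sorted by step
    ev_step, ev_target, ev_weight = [], [], []
    if not disable_synapses:
        for j, train in enumerate(stn_trains):
            steps = np.minimum((train.times / dt).astype(int), n_steps - 1)
            for t_idx, w in zip(graph.stn_targets[j], graph.stn_g[j]):
                ev_step.append(steps)
                ev_target.append(np.full(steps.size, t_idx, dtype=int))
                ev_weight.append(np.full(steps.size, w))
    if ev_step:
        ev_step = np.concatenate(ev_step)
        order = np.argsort(ev_step, kind="stable")
        ev_step = ev_step[order]
        ev_target = np.concatenate(ev_target)[order]
        ev_weight = np.concatenate(ev_weight)[order]
    else:
        ev_step = np.empty(0, dtype=int)
        ev_target = np.empty(0, dtype=int)
        ev_weight = np.empty(0)

    dec_o_g = np.exp(-dt / resolved.gp_gp.tau_o)
    dec_c_g = np.exp(-dt / resolved.gp_gp.tau_c)
    dec_o_s = np.exp(-dt / resolved.stn_gp.tau_o)
    dec_c_s = np.exp(-dt / resolved.stn_gp.tau_c)
    o_gaba = np.zeros(cfg.n_gp)
    c_gaba = np.zeros(cfg.n_gp)
    o_ampa = np.zeros(cfg.n_gp)
    c_ampa = np.zeros(cfg.n_gp)

    downreg = make_control_callback(cfg.downregulation)
    control_every = max(1, int(round(cfg.downregulation.update_interval / dt)))
    guard_every = int(round(10.0 / dt))
    spike_lists: list[list[float]] = [[] for _ in range(cfg.n_gp)]
    traces = ([], []) if record_v else None

    ptr = 0
    for k in range(n_steps):
        # exact decay of the aggregated synaptic variables
        o_gaba *= dec_o_g
        c_gaba *= dec_c_g
        o_ampa *= dec_o_s
        c_ampa *= dec_c_s
        # STN events due this step
        while ptr < ev_step.size and ev_step[ptr] == k:
            o_ampa[ev_target[ptr]] += ev_weight[ptr]
            c_ampa[ev_target[ptr]] += ev_weight[ptr]
            ptr += 1
        g_inh = c_gaba - o_gaba
        g_exc = c_ampa - o_ampa
        t0 = group.t
        spiked, frac = group.step(g_exc=g_exc, g_inh=g_inh)
        if spiked.any():
            idx = np.nonzero(spiked)[0]
            for i in idx:
                spike_lists[i].append(t0 + frac[i] * dt)
            if not disable_synapses:
                for i in idx:
                    np.add.at(o_gaba, graph.gp_targets[i], graph.gp_g[i])
                    np.add.at(c_gaba, graph.gp_targets[i], graph.gp_g[i])
        if (k + 1) % control_every == 0:
            downreg(group)
        if (k + 1) % guard_every == 0:
            group.check_guard()
        if record_v and k % 20 == 0:
            traces[0].append(group.t)
            traces[1].append(group.v.copy())

    gp_trains = [
        SpikeTrain(i, np.asarray(s), 0.0, cfg.duration)
        for i, s in enumerate(spike_lists)
    ]
    result = SimulationResult(
        config=cfg,
        resolved=resolved,
        sub_seeds=sub_seeds,
        sample=sample,
        graph=graph,
        stn_trains=stn_trains,
        gp_trains=gp_trains,
        final_gmax=group.gmax.copy(),
        initial_gmax=initial_gmax,
    )
    if record_v:
        result.v_trace = (np.asarray(traces[0]), np.asarray(traces[1]).T)
    return result


def run_trial_battery(cfg: NetworkConfig, n_trials: int = 12) -> list[SimulationResult]:
    """Independent trials: fresh connectivity, STN trains and parameter
    noise per trial, all derived from the master seed."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    results = []
    for trial in range(n_trials):
        trial_cfg = replace(cfg, seed=stream_seed(cfg.seed, "trial", trial))
        results.append(simulate_network(trial_cfg))
    return results
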