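"""Voltage-gated channel gate kinetics.

Each gate of each channel relaxes with first-order dynamics

    dx/dt = (x_inf(V) - x) / tau(V)

where the steady state is a Boltzmann function of membrane potential and
the time constant varies sigmoidally between two limits.  The parameters
of every gate are data, not code: the package ships a calibrated set in
``data/gate_kinetics.yaml`` and a user holding an alternative
parameterization (e.g. from the multicompartmental literature) can load
their own file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "GateKinetics",
    "boltzmann",
    "load_kinetics",
    "default_kinetics_path",
]


@dataclass(frozen=True)
class GateKinetics:
    """First-order gate: Boltzmann steady state, sigmoidal time constant.

    Parameters
    ----------
    v_half : float
        Half-activation (or half-inactivation) voltage (mV).
    slope : float
        Boltzmann slope factor (mV).  Positive for gates that open with
        depolarization (activation), negative for gates that open with
        hyperpolarization (inactivation, and HCN activation).
    tau_min, tau_max : float
        Limits of the voltage-dependent time constant (ms); both must be
        strictly positive so trajectories stay in [0, 1].
    v_tau, k_tau : float
        Midpoint (mV) and slope (mV) of the sigmoid interpolating between
        ``tau_max`` (hyperpolarized side for ``k_tau > 0``) and
        ``tau_min``.  Irrelevant when ``tau_min == tau_max``.
    """

    v_half: float
    slope: float
    tau_min: float
    tau_max: float
    v_tau: float = 0.0
    k_tau: float = 10.0

    def __post_init__(self) -> None:
        if self.tau_min <= 0 or self.tau_max <= 0:
            raise ValueError("gate time constants must be strictly positive")
        if self.slope == 0:
            raise ValueError("Boltzmann slope must be non-zero")
        if self.k_tau == 0:
            raise ValueError("tau slope must be non-zero")

    def steady_state(self, v):
        """x_inf(V) = 1 / (1 + exp((v_half - V)/slope))."""
        return boltzmann(v, self.v_half, self.slope)

    def time_constant(self, v):
        """tau(V), guaranteed positive over any voltage range."""
        v = np.asarray(v, dtype=float)
        return self.tau_min + (self.tau_max - self.tau_min) / (
            1.0 + np.exp((v - self.v_tau) / self.k_tau)
        )

    def derivative(self, x, v):
        """d(gate)/dt at gate value ``x`` and membrane potential ``v``."""
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError("gate value outside [0, 1]")
        return (self.steady_state(v) - x) / self.time_constant(v)


def boltzmann(v, v_half: float, slope: float):
    """Two-state Boltzmann steady state 1/(1 + exp((v_half - v)/slope))."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v_half - v) / slope))


def default_kinetics_path() -> Path:
    """Path of the calibrated gate-kinetics file shipped with the package."""
    return Path(resources.files("pallidalnet").joinpath("data/gate_kinetics.yaml"))


def load_kinetics(path: str | Path | None = None) -> dict[str, dict[str, GateKinetics]]:
    """Load gate kinetics from a YAML file.

    The file maps channel name -> gate role (``m`` activation, ``h``
    inactivation, ``s`` slow inactivation) -> the `GateKinetics` fields.
    Returns a nested dict ``{channel: {role: GateKinetics}}``.
    """
    if path is None:
        path = default_kinetics_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, dict[str, GateKinetics]] = {}
    for channel, gates in raw.items():
        out[channel] = {}
        for role, params in gates.items():
            if role not in ("m", "h", "s"):
                raise ValueError(f"unknown gate role {role!r} for channel {channel}")
            out[channel][role] = GateKinetics(**params)
    return out
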