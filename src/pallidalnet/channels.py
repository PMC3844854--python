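"""Voltage-gated channel definitions for the GP neuron model.

The ten channels, their gate stoichiometries (mu activation, rho
inactivation, phi slow-inactivation gating molecules) and their maximal
conductances and reversal potentials follow the single-compartment GP
neuron parameterization: fast and persistent sodium (NaF, NaP), delayed
rectifiers (Kv2, Kv3), A-type potassium (Kv4_fast, Kv4_slow), M-type
potassium (KCNQ), high-voltage-activated calcium (HVA), and fast and
slow HCN channels.  SK channels are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import GateKinetics, load_kinetics

__all__ = [
    "CHANNEL_NAMES",
    "GATE_EXPONENTS",
    "REVERSAL_POTENTIALS",
    "DEFAULT_GMAX",
    "ChannelSpec",
    "default_channels",
    "channel_current",
]

CHANNEL_NAMES = (
    "NaF",
    "NaP",
    "Kv2",
    "Kv3",
    "Kv4_fast",
    "Kv4_slow",
    "KCNQ",
    "HVA",
    "HCN_fast",
    "HCN_slow",
)

#: (mu, rho, phi) gating-molecule counts per channel.
GATE_EXPONENTS: dict[str, tuple[int, int, int]] = {
    "NaF": (3, 1, 1),
    "NaP": (3, 1, 1),
    "Kv2": (4, 1, 0),
    "Kv3": (4, 1, 0),
    "Kv4_fast": (4, 1, 0),
    "Kv4_slow": (4, 1, 0),
    "KCNQ": (4, 0, 0),
    "HVA": (1, 0, 0),
    "HCN_fast": (1, 0, 0),
    "HCN_slow": (1, 0, 0),
}

#: Ionic reversal potentials (mV): E_k, E_na, E_ca, E_hcn.
REVERSAL_POTENTIALS: dict[str, float] = {
    "NaF": 55.0,
    "NaP": 55.0,
    "Kv2": -80.0,
    "Kv3": -80.0,
    "Kv4_fast": -80.0,
    "Kv4_slow": -80.0,
    "KCNQ": -80.0,
    "HVA": 120.0,
    "HCN_fast": -30.0,
    "HCN_slow": -30.0,
}

#: Population-mean maximal conductances (nS).
DEFAULT_GMAX: dict[str, float] = {
    "NaF": 5900.0,
    "NaP": 17.7,
    "Kv2": 590.0,
    "Kv3": 590.0,
    "Kv4_fast": 590.0,
    "Kv4_slow": 590.0,
    "KCNQ": 1.77,
    "HVA": 1.77,
    "HCN_fast": 177.0,
    "HCN_slow": 177.0,
}

#: Channels whose maximal conductance is heterogeneous across the
#: population, with the stated coefficient of variation.
HETEROGENEOUS_CV: dict[str, float] = {
    "NaP": 0.5,
    "HCN_fast": 0.3,
    "HCN_slow": 0.3,
}


@dataclass(frozen=True)
class ChannelSpec:
    """One voltage-gated channel of one neuron.

    ``gates`` maps the present gate roles (``m``/``h``/``s``) to their
    kinetics; roles whose exponent is zero must be absent.
    """

    name: str
    g_max: float
    e_rev: float
    exponents: tuple[int, int, int]
    gates: dict[str, GateKinetics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel name {self.name!r}")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if self.exponents != GATE_EXPONENTS[self.name]:
            raise ValueError(
                f"gate exponents {self.exponents} do not match the "
                f"stoichiometry of {self.name}"
            )
        mu, rho, phi = self.exponents
        expected = {r for r, e in zip("mhs", (mu, rho, phi)) if e > 0}
        if set(self.gates) != expected:
            raise ValueError(
                f"channel {self.name} requires gates {sorted(expected)}, "
                f"got {sorted(self.gates)}"
            )

    def with_gmax(self, g_max: float) -> "ChannelSpec":
        return replace(self, g_max=g_max)


def default_channels(kinetics_path=None) -> dict[str, ChannelSpec]:
    """The ten channels with mean conductances and calibrated kinetics."""
    kin = load_kinetics(kinetics_path)
    out = {}
    for name in CHANNEL_NAMES:
        mu, rho, phi = GATE_EXPONENTS[name]
        roles = [r for r, e in zip("mhs", (mu, rho, phi)) if e > 0]
        try:
            gates = {r: kin[name][r] for r in roles}
        except KeyError as exc:  # pragma: no cover - config error path
            raise ValueError(f"kinetics file missing gate for {name}") from exc
        out[name] = ChannelSpec(
            name=name,
            g_max=DEFAULT_GMAX[name],
            e_rev=REVERSAL_POTENTIALS[name],
            exponents=(mu, rho, phi),
            gates=gates,
        )
    return out


def channel_current(spec: ChannelSpec, gates: dict[str, float], v) -> float:
    """Instantaneous channel current m^mu * h^rho * s^phi * g * (E - V), in pA.

    Positive current depolarizes the neuron.  Gates with exponent zero
    contribute a factor of one and need not be supplied.
    """
    mu, rho, phi = spec.exponents
    product = 1.0
    for role, exponent in zip("mhs", (mu, rho, phi)):
        if exponent == 0:
            continue
        x = gates[role]
        if np.any((np.asarray(x) < 0) | (np.asarray(x) > 1)):
            raise ValueError(f"gate {role!r} of {spec.name} outside [0, 1]")
        product = product * np.asarray(x, dtype=float) ** exponent
    return product * spec.g_max * (spec.e_rev - np.asarray(v, dtype=float))
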