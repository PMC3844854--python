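"""SWA-modulated STN spike-train generation.

STN neurons are not modelled at conductance level; each unit is an
independent stochastic spike generator whose firing alternates between a
slow-irregular process (the SWA "inactive" phase) and a fast-irregular
process (the "active" phase).  The generator is an enhanced leaky
integrate-and-fire unit with membrane accumulation, Gaussian noise, an
exponentially decaying (adapting) threshold and an absolute refractory
period.  The per-phase drive is calibrated by bisection so that the
realized phase rates match the protocol rates; the shipped calibration
covers the preset rates and is recomputed transparently for any other
rate.

Phase convention: SWA phase 0 lies at each active-phase onset and
advances linearly with time, so the active phase occupies
``[0, 2*pi*active_duration/period)`` and the inactive phase the
remainder of the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .seeding import stream_rng
from .spiketrain import SpikeTrain

__all__ = [
    "SWAProtocol",
    "IFGeneratorParams",
    "swa_phase",
    "active_windows",
    "calibrate_drive",
    "generate_stn_train",
    "generate_stn_population",
    "cross_check_independence",
]

GEN_DT = 0.25  # ms, internal step of the spike generator


@dataclass(frozen=True)
class SWAProtocol:
    """Slow-wave cycle geometry and phase-specific STN rates.

    Each cycle starts with ``active_duration`` ms at ``active_rate`` Hz
    followed by ``inactive_duration`` ms at ``inactive_rate`` Hz.
    """

    period: float = 1300.0
    active_duration: float = 500.0
    inactive_duration: float = 800.0
    active_rate: float = 30.0
    inactive_rate: float = 0.5
    label: str = "healthy"

    def __post_init__(self):
        if abs(self.active_duration + self.inactive_duration - self.period) > 1e-9:
            raise ValueError("active + inactive durations must equal the period")
        if self.active_rate < 0 or self.inactive_rate < 0:
            raise ValueError("rates must be non-negative")

    @classmethod
    def healthy(cls) -> "SWAProtocol":
        return cls()

    @classmethod
    def parkinsonian(cls) -> "SWAProtocol":
        return cls(active_rate=60.0, label="parkinsonian")

    @classmethod
    def beta(cls, active_rate: float = 60.0) -> "SWAProtocol":
        """~14 Hz modulation: 70 ms period, 30 ms active + 40 ms inactive."""
        return cls(
            period=70.0,
            active_duration=30.0,
            inactive_duration=40.0,
            active_rate=active_rate,
            label="beta",
        )

    @property
    def mean_rate(self) -> float:
        """Cycle-averaged firing rate (Hz) implied by the phase rates."""
        return (
            self.active_rate * self.active_duration
            + self.inactive_rate * self.inactive_duration
        ) / self.period


@dataclass(frozen=True)
class IFGeneratorParams:
    """Enhanced integrate-and-fire spike generator.

    The unit accumulates ``dv = (drive - v/membrane_tau) dt + noise`` and
    spikes when v crosses an adaptive threshold that jumps by
    ``threshold_jump`` at each spike and decays back with
    ``threshold_decay``; spiking is suppressed during the absolute
    ``refractory`` period.
    """

    membrane_tau: float = 10.0
    threshold_base: float = 1.0
    threshold_jump: float = 2.0
    threshold_decay: float = 20.0
    noise_amplitude: float = 0.3
    refractory: float = 2.0

    def __post_init__(self):
        if self.refractory <= 0:
            raise ValueError("refractory period must be positive")
        if self.membrane_tau <= 0 or self.threshold_decay <= 0:
            raise ValueError("time constants must be positive")


def swa_phase(t, protocol: SWAProtocol):
    """SWA phase in [0, 2*pi): 0 at active-phase onset, linear in time."""
    t = np.asarray(t, dtype=float)
    phase = 2.0 * np.pi * np.mod(t, protocol.period) / protocol.period
    return phase if phase.ndim else float(phase)


def active_phase_width(protocol: SWAProtocol) -> float:
    """Angular width of the active phase, 2*pi*active_duration/period."""
    return 2.0 * np.pi * protocol.active_duration / protocol.period


def active_windows(protocol: SWAProtocol, t0: float, t1: float) -> np.ndarray:
    """Active-phase windows [start, stop) intersecting [t0, t1), as an
    (n, 2) array clipped to the interval."""
    first = np.floor(t0 / protocol.period)
    starts = np.arange(first, np.ceil(t1 / protocol.period) + 1) * protocol.period
    wins = np.stack([starts, starts + protocol.active_duration], axis=1)
    wins = np.clip(wins, t0, t1)
    return wins[wins[:, 1] > wins[:, 0]]


# ----------------------------------------------------------------------
# drive calibration

_DRIVE_CACHE: dict[tuple, float] = {}

#: Pre-calibrated drives for the default generator at the preset phase
#: rates (Hz -> drive), computed by high-precision bisection/secant
#: refinement of `calibrate_drive`; realized rates agree with the
#: targets to well within 2%.
SHIPPED_DRIVES: dict[float, float] = {
    0.5: -0.114159,
    30.0: 0.111170,
    60.0: 0.304067,
}


def _simulate_constant(
    drive: float,
    gen: IFGeneratorParams,
    duration: float,
    n_units: int,
    rng: np.random.Generator,
) -> float:
    """Realized rate (Hz) of the generator at constant drive."""
    n_steps = int(round(duration / GEN_DT))
    v = np.zeros(n_units)
    th = np.full(n_units, gen.threshold_base)
    refr = np.zeros(n_units)
    count = 0
    sq = gen.noise_amplitude * np.sqrt(GEN_DT)
    for _ in range(n_steps):
        noise = rng.standard_normal(n_units) * sq
        v += (drive - v / gen.membrane_tau) * GEN_DT + noise
        th = gen.threshold_base + (th - gen.threshold_base) * np.exp(
            -GEN_DT / gen.threshold_decay
        )
        refr -= GEN_DT
        spiking = (v >= th) & (refr <= 0)
        if spiking.any():
            count += int(spiking.sum())
            v[spiking] = 0.0
            th[spiking] += gen.threshold_jump
            refr[spiking] = gen.refractory
    return 1000.0 * count / (duration * n_units)


def calibrate_drive(
    rate: float,
    gen: IFGeneratorParams = IFGeneratorParams(),
    *,
    tolerance: float = 0.02,
    seed: int = 424242,
) -> float:
    """Drive that realizes ``rate`` Hz at stationarity, by bisection.

    The realized rate is monotone in the drive; bisection terminates
    when the relative error is below ``tolerance``.  Results are cached
    per (rate, generator) within the process.  A fixed internal seed
    keeps the calibration deterministic and independent of simulation
    seeds.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0.0:
        return -1e9  # infinitely hyperpolarizing: never fires
    key = (round(rate, 6), gen)
    if key in _DRIVE_CACHE:
        return _DRIVE_CACHE[key]
    if gen == IFGeneratorParams() and round(rate, 6) in SHIPPED_DRIVES:
        return SHIPPED_DRIVES[round(rate, 6)]
    duration = 60000.0 if rate < 5.0 else 16000.0
    rng = stream_rng(seed, "stn-calibration", round(rate, 6))
    lo, hi = -1.0, 2.0
    # expand until bracketing
    while _simulate_constant(hi, gen, duration / 4, 8, rng) < rate:
        hi *= 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        realized = _simulate_constant(mid, gen, duration, 8, rng)
        if abs(realized - rate) <= tolerance * rate:
            break
        if realized < rate:
            lo = mid
        else:
            hi = mid
    else:  # pragma: no cover - bisection failed to converge
        raise RuntimeError(f"drive calibration did not converge for {rate} Hz")
    _DRIVE_CACHE[key] = mid
    return mid


# ----------------------------------------------------------------------
# train generation

def generate_stn_population(
    n_units: int,
    duration: float,
    protocol: SWAProtocol = SWAProtocol(),
    gen: IFGeneratorParams = IFGeneratorParams(),
    seed: int = 0,
) -> list[SpikeTrain]:
    """Generate ``n_units`` independent SWA-modulated STN spike trains.

    Within each SWA cycle the drive switches between the calibrated
    active- and inactive-phase values; generator state (membrane,
    threshold, refractory clock) is carried across phase boundaries.
    Trains with different unit ids (and different seeds) are
    statistically independent; the same seed reproduces the same trains.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    drives = (
        calibrate_drive(protocol.active_rate, gen),   # fast intermediate train
        calibrate_drive(protocol.inactive_rate, gen),  # slow intermediate train
    )
    rng = stream_rng(seed, "stn-trains", protocol.label)
    n_steps = int(round(duration / GEN_DT))
    sq = gen.noise_amplitude * np.sqrt(GEN_DT)
    decay = np.exp(-GEN_DT / gen.threshold_decay)
    # two stationary intermediate generators per unit, sampled alternately
    v = [np.zeros(n_units), np.zeros(n_units)]
    th = [np.full(n_units, gen.threshold_base) for _ in range(2)]
    refr = [np.zeros(n_units), np.zeros(n_units)]
    spikes: list[list[float]] = [[] for _ in range(n_units)]
    for k in range(n_steps):
        t = k * GEN_DT
        current = 0 if np.mod(t, protocol.period) < protocol.active_duration else 1
        for g in (0, 1):
            v[g] += (drives[g] - v[g] / gen.membrane_tau) * GEN_DT + (
                rng.standard_normal(n_units) * sq
            )
            th[g] = gen.threshold_base + (th[g] - gen.threshold_base) * decay
            refr[g] -= GEN_DT
            spiking = (v[g] >= th[g]) & (refr[g] <= 0)
            if spiking.any():
                if g == current:
                    for i in np.nonzero(spiking)[0]:
                        spikes[i].append(t)
                v[g][spiking] = 0.0
                th[g][spiking] += gen.threshold_jump
                refr[g][spiking] = gen.refractory
    out = []
    for i, s in enumerate(spikes):
        times = np.asarray(s)
        if times.size:  # enforce the absolute refractory period across
            # the splice points between the two intermediate trains
            keep = np.concatenate([[True], np.diff(times) >= gen.refractory])
            times = times[keep]
        out.append(SpikeTrain(i, times, 0.0, duration))
    return out


def generate_stn_train(
    protocol: SWAProtocol = SWAProtocol(),
    gen: IFGeneratorParams = IFGeneratorParams(),
    duration: float = 13000.0,
    seed: int = 0,
    unit: int = 0,
) -> SpikeTrain:
    """One SWA-modulated STN spike train (see `generate_stn_population`)."""
    trains = generate_stn_population(unit + 1, duration, protocol, gen, seed)
    return trains[unit]


def phase_windowed_rates(train: SpikeTrain, protocol: SWAProtocol) -> tuple[float, float]:
    """Realized (active_rate, inactive_rate) in Hz over the train."""
    wins = active_windows(protocol, train.t_start, train.t_stop)
    active_time = float(np.sum(wins[:, 1] - wins[:, 0]))
    in_active = np.zeros(len(train), dtype=bool)
    for a, b in wins:
        in_active |= (train.times >= a) & (train.times < b)
    n_active = int(in_active.sum())
    n_inactive = len(train) - n_active
    inactive_time = train.duration - active_time
    return (
        1000.0 * n_active / active_time if active_time > 0 else np.nan,
        1000.0 * n_inactive / inactive_time if inactive_time > 0 else np.nan,
    )


def _concatenate_active(train: SpikeTrain, protocol: SWAProtocol) -> SpikeTrain:
    """Remap active-phase spikes onto concatenated active-window time."""
    wins = active_windows(protocol, train.t_start, train.t_stop)
    out = []
    offset = 0.0
    for a, b in wins:
        sel = (train.times >= a) & (train.times < b)
        out.append(train.times[sel] - a + offset)
        offset += b - a
    times = np.concatenate(out) if out else np.empty(0)
    return SpikeTrain(train.unit, times, 0.0, max(offset, 1e-9))


def cross_check_independence(
    a: SpikeTrain,
    b: SpikeTrain,
    protocol: SWAProtocol,
    *,
    short_bin: float = 3.0,
    short_bins: int = 30,
    long_bin: float = 20.0,
    long_bins: int = 400,
):
    """Fig-2-style independence check for a pair of STN trains.

    Returns ``(short, long)`` correlograms: the short-lag one is
    computed on active-phase-concatenated time (within-burst activity
    should be flat at 1 inside the 95% band), the long-lag one on the
    full trains (it should oscillate at the SWA period because of the
    common rate modulation).
    """
    from .analysis import correlogram  # local import to avoid a cycle

    short = correlogram(
        _concatenate_active(a, protocol),
        _concatenate_active(b, protocol),
        bin_width=short_bin,
        n_bins=short_bins,
    )
    long = correlogram(a, b, bin_width=long_bin, n_bins=long_bins)
    return short, long
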