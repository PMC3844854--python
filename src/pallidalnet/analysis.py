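"""Phase-locking categorization and correlogram analysis of GP activity.

Each neuron's spikes are mapped to SWA phase and summed as unit phasors:

    omega = sum_s exp(i * theta(s)),    c = |omega| / n_spikes

``c`` is the phase confidence (1 = perfect locking, 0 = uniform
phases).  Neurons firing fewer than one spike per SWA cycle are QU
(quiet); neurons with c < 0.1 are NM (not modulated); the rest are TA
or TI according to whether the mean phase falls in the active or
inactive part of the cycle (phase 0 at active onset).

Cross- and auto-correlograms use the Brillinger normalization
X' = T*X/(2*h*N_A*N_B), which equals 1 in expectation for independent
stationary trains, with 95% confidence bounds from the Poisson count
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiketrain import SpikeTrain
from .stn import SWAProtocol, active_phase_width, swa_phase

__all__ = [
    "PhaseVector",
    "CategoryReport",
    "Correlogram",
    "phase_vector",
    "categorize",
    "firing_stats",
    "correlogram",
    "phase_histogram",
    "group_summary",
    "categorize_population",
]

CONFIDENCE_THRESHOLD = 0.1
LABELS = ("TA", "TI", "NM", "QU")


@dataclass(frozen=True)
class PhaseVector:
    """Resultant of per-spike unit phasors over the SWA cycle."""

    omega: complex
    n_spikes: int

    @property
    def confidence(self) -> float:
        """|omega|/n in [0, 1]; 0 for an empty train."""
        if self.n_spikes == 0:
            return 0.0
        return abs(self.omega) / self.n_spikes

    @property
    def mean_phase(self) -> float:
        """arg(omega) in [0, 2*pi); NaN when undefined (no spikes)."""
        if self.n_spikes == 0 or abs(self.omega) == 0:
            return float("nan")
        return float(np.angle(self.omega)) % (2.0 * np.pi)


@dataclass(frozen=True)
class CategoryReport:
    """Label and statistics of one neuron over the analysis window."""

    unit: int
    label: str
    phase: PhaseVector
    rate: float
    cv: float  # NaN when fewer than two in-window ISIs


@dataclass(frozen=True)
class Correlogram:
    """Brillinger-normalized lag histogram between two spike trains."""

    edges: np.ndarray  # bin edges (ms), symmetric about zero lag
    counts: np.ndarray  # normalized X'_i
    raw_counts: np.ndarray
    ci_low: float
    ci_high: float
    half_width: float
    total_time: float
    n_a: int
    n_b: int

    @property
    def lags(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def phase_vector(train: SpikeTrain, protocol: SWAProtocol) -> PhaseVector:
    """Sum of exp(i*theta(s)) over the train's spikes."""
    if len(train) == 0:
        return PhaseVector(0j, 0)
    omega = np.exp(1j * swa_phase(train.times, protocol)).sum()
    return PhaseVector(complex(omega), len(train))


def categorize(
    train: SpikeTrain,
    protocol: SWAProtocol,
    window: tuple[float, float] | None = None,
) -> CategoryReport:
    """Classify one neuron as TA / TI / NM / QU over the window.

    The window defaults to the latter half of the observation interval.
    QU takes precedence: fewer than one spike per SWA cycle on average.
    Then c < 0.1 is NM, and the mean phase decides TA (active part of
    the cycle) versus TI (inactive part).
    """
    if window is None:
        mid = train.t_start + 0.5 * (train.t_stop - train.t_start)
        window = (mid, train.t_stop)
    windowed = train.slice(*window)
    vec = phase_vector(windowed, protocol)
    rate, cv = firing_stats(windowed)
    n_cycles = windowed.duration / protocol.period
    if len(windowed) < n_cycles:
        label = "QU"
    elif vec.confidence < CONFIDENCE_THRESHOLD:
        label = "NM"
    else:
        label = "TA" if vec.mean_phase < active_phase_width(protocol) else "TI"
    return CategoryReport(train.unit, label, vec, rate, cv)


def firing_stats(train: SpikeTrain, window: tuple[float, float] | None = None):
    """(rate in Hz, ISI coefficient of variation) over the window.

    CV uses the sample standard deviation (n-1); it is NaN when fewer
    than three spikes (two ISIs) are available, never silently zero.
    """
    if window is not None:
        train = train.slice(*window)
    rate = train.rate
    if len(train) >= 3:
        isis = np.diff(train.times)
        cv = float(np.std(isis, ddof=1) / np.mean(isis))
    else:
        cv = float("nan")
    return rate, cv


def correlogram(
    a: SpikeTrain,
    b: SpikeTrain,
    bin_width: float,
    n_bins: int,
) -> Correlogram:
    """Cross-correlogram (auto- when ``a is b``) over lags spanning
    ``n_bins`` bins of ``bin_width`` ms, symmetric about zero.

    Counts are normalized as X' = T*X/(2*h*N_A*N_B) with h half the bin
    width, so independent stationary trains give 1 in expectation; the
    95% band is 1 +/- 1.96/sqrt(E[X]) with E[X] = 2*h*N_A*N_B/T.  For
    auto-correlograms the zero-lag self-pairs are excluded.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot correlate empty spike trains")
    t0 = max(a.t_start, b.t_start)
    t1 = min(a.t_stop, b.t_stop)
    if t1 <= t0:
        raise ValueError("spike trains do not overlap in time")
    total_time = t1 - t0
    half_span = 0.5 * n_bins * bin_width
    edges = np.linspace(-half_span, half_span, n_bins + 1)
    auto = a is b or (a.unit == b.unit and a.times is b.times)
    ta, tb = a.times, b.times
    counts = np.zeros(n_bins)
    # enumerate pairs within the lag span via a sliding window
    lo = np.searchsorted(tb, ta - half_span, side="left")
    hi = np.searchsorted(tb, ta + half_span, side="right")
    for i, t in enumerate(ta):
        if hi[i] <= lo[i]:
            continue
        lags = tb[lo[i]:hi[i]] - t
        if auto:
            lags = lags[lags != 0.0]
        counts += np.histogram(lags, bins=edges)[0]
    h = 0.5 * bin_width
    n_a, n_b = len(a), len(b)
    expected = 2.0 * h * n_a * n_b / total_time
    normalized = total_time * counts / (2.0 * h * n_a * n_b)
    band = 1.96 / np.sqrt(expected)
    return Correlogram(
        edges=edges,
        counts=normalized,
        raw_counts=counts,
        ci_low=1.0 - band,
        ci_high=1.0 + band,
        half_width=h,
        total_time=total_time,
        n_a=n_a,
        n_b=n_b,
    )


def phase_histogram(
    reports: list[CategoryReport],
    trains: list[SpikeTrain],
    protocol: SWAProtocol,
    label: str,
    *,
    bin_width_ms: float = 65.0,
    window: tuple[float, float] | None = None,
):
    """Pooled spike counts by SWA phase bin for one category label.

    Returns ``(edges_ms, counts, mean_phase, mean_confidence)`` where
    ``edges_ms`` partitions the cycle into 65 ms bins (by default) and
    the mean-phase bar length is the average confidence of the group.
    """
    members = [r.unit for r in reports if r.label == label]
    if not members:
        raise ValueError(f"no neurons categorized {label}")
    by_unit = {t.unit: t for t in trains}
    edges = np.arange(0.0, protocol.period + 0.5 * bin_width_ms, bin_width_ms)
    edges[-1] = protocol.period
    counts = np.zeros(len(edges) - 1)
    omega = 0j
    n_spk = 0
    for unit in members:
        train = by_unit[unit]
        if window is not None:
            train = train.slice(*window)
        tmod = np.mod(train.times, protocol.period)
        counts += np.histogram(tmod, bins=edges)[0]
        vec = phase_vector(train, protocol)
        omega += vec.omega
        n_spk += vec.n_spikes
    mean_conf = float(np.mean([r.phase.confidence for r in reports if r.label == label]))
    mean_phase = float(np.angle(omega)) % (2 * np.pi) if n_spk else float("nan")
    return edges, counts, mean_phase, mean_conf


def categorize_population(
    trains: list[SpikeTrain],
    protocol: SWAProtocol,
    window: tuple[float, float],
) -> list[CategoryReport]:
    return [categorize(t, protocol, window) for t in trains]


def group_summary(batteries: list[list[CategoryReport]]):
    """Per-label summary across trials.

    ``batteries`` is one list of reports per trial.  Returns a dict
    ``label -> {count_mean, count_sd, percent_mean, percent_sd,
    rate_mean, rate_sd, confidence_mean, confidence_sd}`` where counts
    are per-trial means/s.d.s and rates/confidences pool neurons across
    all trials.  With a single trial the s.d. fields are NaN.
    """
    if not batteries:
        raise ValueError("need at least one trial")
    out = {}
    n_per_trial = [len(b) for b in batteries]
    for label in LABELS:
        counts = np.array(
            [sum(r.label == label for r in trial) for trial in batteries], dtype=float
        )
        percents = 100.0 * counts / np.asarray(n_per_trial, dtype=float)
        pooled = [r for trial in batteries for r in trial if r.label == label]
        rates = np.array([r.rate for r in pooled])
        confs = np.array([r.phase.confidence for r in pooled])
        sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
        out[label] = {
            "count_mean": float(counts.mean()),
            "count_sd": sd(counts),
            "percent_mean": float(percents.mean()),
            "percent_sd": sd(percents),
            "rate_mean": float(rates.mean()) if rates.size else float("nan"),
            "rate_sd": sd(rates),
            "confidence_mean": float(confs.mean()) if confs.size else float("nan"),
            "confidence_sd": sd(confs),
        }
    return out
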