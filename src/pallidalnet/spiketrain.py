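"""Spike trains and their delimited-text file formats."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpikeTrain", "write_spike_trains", "read_spike_trains"]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one unit over an observation interval.

    Times are in ms.  Spikes must lie inside ``[t_start, t_stop)`` and be
    strictly increasing.
    """

    unit: int
    times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.t_stop <= self.t_start:
            raise ValueError("observation interval must have positive length")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < self.t_start or times[-1] >= self.t_stop:
                raise ValueError("spike times outside the observation interval")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz (times are ms)."""
        return 1000.0 * len(self) / self.duration

    def slice(self, t0: float, t1: float) -> "SpikeTrain":
        """Restrict to the window ``[t0, t1)`` (must overlap the interval)."""
        t0 = max(t0, self.t_start)
        t1 = min(t1, self.t_stop)
        if t1 <= t0:
            raise ValueError("empty window")
        sel = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.unit, self.times[sel], t0, t1)


def write_spike_trains(path, trains: list[SpikeTrain], header: dict | None = None):
    """Write a multi-unit spike file: '# key: value' header lines, then
    one 'unit<TAB>time_ms' row per spike."""
    path = Path(path)
    meta = {"n_units": len(trains)}
    if trains:
        meta["t_start"] = trains[0].t_start
        meta["t_stop"] = trains[0].t_stop
    if header:
        meta.update(header)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("unit\ttime_ms\n")
        for train in trains:
            for t in train.times:
                fh.write(f"{train.unit}\t{t:.6f}\n")


def read_spike_trains(path) -> tuple[list[SpikeTrain], dict]:
    """Read a multi-unit spike file written by `write_spike_trains`."""
    path = Path(path)
    meta: dict = {}
    units: dict[int, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                continue
            if line.startswith("unit"):
                continue
            u, t = line.split("\t")
            units.setdefault(int(u), []).append(float(t))
    t0 = float(meta.get("t_start", 0.0))
    t1 = float(meta.get("t_stop", max((max(v) for v in units.values()), default=1.0) + 1.0))
    n_units = int(meta.get("n_units", len(units)))
    trains = [
        SpikeTrain(u, np.asarray(units.get(u, []), dtype=float), t0, t1)
        for u in range(n_units)
    ]
    return trains, meta
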