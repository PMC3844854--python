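"""Named end-to-end experiments and their run manifests.

Each experiment maps to one of the study's analyses:

- ``fig3_characterization``: current-injection protocol on one neuron,
  with and without HCN channels (voltage traces).
- ``hcn_blockade``: isolated heterogeneous population with and without
  HCN conductances; pacemaking summary.
- ``healthy_battery`` / ``parkinsonian_battery``: network trial
  batteries with TA/TI/NM/QU summaries.
- ``downregulation_ablation``: Parkinsonian batteries with plasticity
  enabled vs disabled; TA-confidence contrast.
- ``post_downregulation_pacemaking``: Parkinsonian runs, synapses then
  severed and intrinsic rates measured.
- ``scaling_200`` / ``scaling_300``: larger networks at constant
  fan-out.
- ``beta_band``: 70 ms modulation variant, reported through STN-GP
  cross-correlograms rather than phase categories.

Every experiment writes delimited-text outputs plus a YAML manifest
with the config echo, sub-seeds, version and sha256 checksums, enough
to reproduce the run bit-exactly.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import categorize_population, correlogram, group_summary
from .config import dump_config
from .neuron import sample_population, simulate_isolated, simulate_population, pacemaking_summary
from .network import NetworkConfig, run_trial_battery
from .plasticity import DownregulationParams, measure_post_downregulation_pacemaking
from .seeding import stream_seed
from .spiketrain import write_spike_trains

__all__ = ["EXPERIMENTS", "ExperimentSpec", "RunManifest", "run_experiment"]

EXPERIMENTS = (
    "fig3_characterization",
    "healthy_battery",
    "parkinsonian_battery",
    "downregulation_ablation",
    "scaling_200",
    "scaling_300",
    "beta_band",
    "hcn_blockade",
    "post_downregulation_pacemaking",
)


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    seed: int = 0
    out_dir: str | Path = "pallidalnet-out"
    n_trials: int | None = None  # None -> experiment default
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from {EXPERIMENTS}"
            )


@dataclass
class RunManifest:
    experiment: str
    seed: int
    version: str
    wall_clock_s: float
    files: dict[str, str]  # relative path -> sha256

    def write(self, path: Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "experiment": self.experiment,
                    "seed": self.seed,
                    "version": self.version,
                    "wall_clock_s": round(self.wall_clock_s, 2),
                    "files": self.files,
                },
                fh,
                sort_keys=True,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_summary_table(path: Path, summary: dict) -> None:
    cols = (
        "count_mean count_sd percent_mean percent_sd rate_mean rate_sd "
        "confidence_mean confidence_sd"
    ).split()
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(cols) + "\n")
        for label, stats in summary.items():
            fh.write(label + "\t" + "\t".join(f"{stats[c]:.4f}" for c in cols) + "\n")


def _write_category_table(path: Path, reports) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tlabel\trate_hz\tcv\tconfidence\tmean_phase_rad\n")
        for r in reports:
            fh.write(
                f"{r.unit}\t{r.label}\t{r.rate:.4f}\t{r.cv:.4f}\t"
                f"{r.phase.confidence:.4f}\t{r.phase.mean_phase:.4f}\n"
            )


def _battery(cfg: NetworkConfig, n_trials: int, out: Path, tag: str):
    results = run_trial_battery(cfg, n_trials=n_trials)
    batteries = []
    for i, res in enumerate(results):
        reports = categorize_population(
            res.gp_trains, res.resolved.protocol, res.analysis_window
        )
        batteries.append(reports)
        write_spike_trains(
            out / f"{tag}_trial{i}_gp_spikes.tsv",
            res.gp_trains,
            header={"condition": cfg.condition, "seed": res.config.seed},
        )
        _write_category_table(out / f"{tag}_trial{i}_categories.tsv", reports)
    summary = group_summary(batteries)
    _write_summary_table(out / f"{tag}_summary.tsv", summary)
    return results, batteries, summary


def run_experiment(spec: ExperimentSpec) -> RunManifest:
    t0 = time.time()
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name, seed = spec.name, spec.seed
    cfg = NetworkConfig(seed=seed, **spec.overrides) if not spec.overrides or all(
        k in NetworkConfig.__dataclass_fields__ for k in spec.overrides
    ) else None
    if cfg is None:
        raise ValueError(f"invalid override keys in {sorted(spec.overrides)}")

    if name == "fig3_characterization":
        protocol = [(1000.0, 0.0), (1000.0, -200.0), (1000.0, 0.0), (500.0, 300.0)]
        for tag, sample in (("intact", None), ("hcn_blocked", None)):
            sam = sample_population(1, seed=stream_seed(seed, "fig3"))
            if tag == "hcn_blocked":
                sam = sam.without_hcn()
            train, (ts, v) = simulate_isolated(protocol, sample=sam, dt=cfg.dt)
            np.savetxt(
                out / f"fig3_{tag}_vtrace.tsv",
                np.column_stack([ts, v]),
                fmt="%.4f",
                header="time_ms\tV_mV",
                delimiter="\t",
            )
    elif name == "hcn_blockade":
        n = int(spec.overrides.get("n_gp", 500))
        sam = sample_population(n, seed=stream_seed(seed, "population"))
        for tag, s in (("intact", sam), ("hcn_blocked", sam.without_hcn())):
            trains = simulate_population(s, 3000.0, dt=cfg.dt)
            pacemaking, rates = pacemaking_summary(trains)
            with open(out / f"blockade_{tag}_rates.tsv", "w") as fh:
                fh.write("unit\tpacemaking\trate_hz\n")
                for i in range(len(trains)):
                    fh.write(f"{i}\t{int(pacemaking[i])}\t{rates[i]:.4f}\n")
    elif name in ("healthy_battery", "parkinsonian_battery"):
        cond = "healthy" if name == "healthy_battery" else "parkinsonian"
        cfg = replace(cfg, condition=cond)
        _battery(cfg, spec.n_trials or 12, out, cond)
    elif name == "downregulation_ablation":
        cfg = replace(cfg, condition="parkinsonian")
        n = spec.n_trials or 12
        _battery(cfg, n, out, "with_downregulation")
        cfg_off = replace(
            cfg,
            downregulation=replace(cfg.downregulation, enabled=False),
        )
        _battery(cfg_off, n, out, "without_downregulation")
    elif name == "post_downregulation_pacemaking":
        cfg = replace(cfg, condition="parkinsonian", duration=6500.0,
                      analysis_window_start=3250.0)
        results = run_trial_battery(cfg, n_trials=spec.n_trials or 4)
        with open(out / "post_downregulation_rates.tsv", "w") as fh:
            fh.write("trial\tmean_intrinsic_rate_hz\tquiet_fraction\n")
            for i, res in enumerate(results):
                mean_rate, rates, pacemaking = measure_post_downregulation_pacemaking(res)
                fh.write(f"{i}\t{mean_rate:.4f}\t{1 - pacemaking.mean():.4f}\n")
    elif name in ("scaling_200", "scaling_300"):
        n_gp = 200 if name == "scaling_200" else 300
        cfg = NetworkConfig.scaled(n_gp, seed=seed, **{
            k: v for k, v in spec.overrides.items() if k not in ("n_gp", "n_stn")
        })
        _battery(cfg, spec.n_trials or 3, out, f"scaled_{n_gp}")
    elif name == "beta_band":
        cfg = replace(cfg, condition="parkinsonian", beta=True)
        results = run_trial_battery(cfg, n_trials=spec.n_trials or 1)
        res = results[0]
        # STN-vs-GP cross-correlograms, averaged over STN units
        window = res.analysis_window
        rows = []
        for gp in res.gp_trains:
            gp_w = gp.slice(*window)
            if len(gp_w) < 5:
                continue
            acc = None
            used = 0
            for stn in res.stn_trains:
                stn_w = stn.slice(*window)
                if len(stn_w) == 0:
                    continue
                cg = correlogram(stn_w, gp_w, bin_width=5.0, n_bins=56)
                acc = cg.counts if acc is None else acc + cg.counts
                used += 1
            if used:
                rows.append((gp.unit, acc / used))
        with open(out / "beta_stn_gp_correlograms.tsv", "w") as fh:
            lags = np.arange(-137.5, 140.0, 5.0)
            fh.write("unit\t" + "\t".join(f"{l:.1f}" for l in lags) + "\n")
            for unit, counts in rows:
                fh.write(f"{unit}\t" + "\t".join(f"{c:.4f}" for c in counts) + "\n")

    dump_config(cfg, out / "config_echo.yaml")
    files = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.yaml"
    }
    manifest = RunManifest(
        experiment=name,
        seed=seed,
        version=__version__,
        wall_clock_s=time.time() - t0,
        files=files,
    )
    manifest.write(out / "manifest.yaml")
    return manifest
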