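"""Shared fixtures.

Heavy simulations (the 500-neuron isolated surface and the network
trial batteries) are session-scoped so the acceptance tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from pallidalnet.analysis import categorize_population
from pallidalnet.channels import default_channels
from pallidalnet.network import NetworkConfig, run_trial_battery
from pallidalnet.neuron import (
    pacemaking_summary,
    sample_population,
    simulate_population,
)

ACCEPTANCE_SEED = 20131202  # master seed for the in-suite acceptance runs


@pytest.fixture(scope="session")
def channels():
    return default_channels()


@pytest.fixture(scope="session")
def isolated_surface():
    """500 heterogeneous neurons simulated in isolation, intact and with
    both HCN conductances zeroed."""
    sample = sample_population(500, seed=ACCEPTANCE_SEED)
    intact = simulate_population(sample, 3000.0)
    blocked = simulate_population(sample.without_hcn(), 3000.0)
    pm_i, rates_i = pacemaking_summary(intact)
    pm_b, rates_b = pacemaking_summary(blocked)
    return {
        "sample": sample,
        "pacemaking_intact": pm_i,
        "rates_intact": rates_i,
        "pacemaking_blocked": pm_b,
        "rates_blocked": rates_b,
    }


def _battery_reports(results):
    return [
        categorize_population(r.gp_trains, r.resolved.protocol, r.analysis_window)
        for r in results
    ]


@pytest.fixture(scope="session")
def healthy_battery():
    cfg = NetworkConfig(condition="healthy", seed=ACCEPTANCE_SEED)
    results = run_trial_battery(cfg, n_trials=4)
    return results, _battery_reports(results)


@pytest.fixture(scope="session")
def parkinsonian_battery():
    cfg = NetworkConfig(condition="parkinsonian", seed=ACCEPTANCE_SEED)
    results = run_trial_battery(cfg, n_trials=4)
    return results, _battery_reports(results)


@pytest.fixture(scope="session")
def parkinsonian_battery_no_downregulation():
    from dataclasses import replace

    from pallidalnet.plasticity import DownregulationParams

    cfg = NetworkConfig(
        condition="parkinsonian",
        seed=ACCEPTANCE_SEED,
        downregulation=DownregulationParams(enabled=False),
    )
    results = run_trial_battery(cfg, n_trials=4)
    return results, _battery_reports(results)
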