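"""pallidalnet: a spiking network model of the rodent globus pallidus
under rhythmic subthalamic drive, with activity-dependent HCN
downregulation and phase-locking analysis tools."""

from .channels import ChannelSpec, channel_current, default_channels
from .kinetics import GateKinetics, load_kinetics
from .neuron import (
    CalciumParams,
    MembraneParams,
    NeuronState,
    PopulationSample,
    detect_spikes,
    sample_population,
    simulate_isolated,
    simulate_population,
)
from .spiketrain import SpikeTrain, read_spike_trains, write_spike_trains

__version__ = "0.1.0"


def __getattr__(name):
    # lazy convenience access to the heavier submodule surfaces
    if name in ("analysis", "network", "stn", "synapses", "plasticity",
                "experiments", "config"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
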