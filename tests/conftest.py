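import dataclasses

import numpy as np
import pytest

from spikescope import simdata, synthgen


def make_neuron(gid, layer=1, column=0, minicolumn=0, mtype="pyramidal",
                etype="excitatory", position=(0.0, 0.0, 0.0), **morph):
    m = {k: 1.0 for k in simdata.MORPHOMETRIC_KEYS}
    m["dendritic_bifurcations"] = 3.0
    m.update(morph)
    return simdata.NeuronRecord(gid, position, layer, column, minicolumn,
                                mtype, etype, m)


@pytest.fixture
def tiny_circuit():
    spec = dataclasses.replace(synthgen.PRESETS["tiny"], seed=7)
    return synthgen.generate_circuit(spec)


@pytest.fixture
def tiny_spikes(tiny_circuit):
    return synthgen.generate_spikes(tiny_circuit, synthgen.ActivitySpec(seed=7))


def random_report(rng, n_gids=20, n_events=200, duration=100.0):
    times = rng.uniform(0, duration, n_events)
    gids = rng.integers(0, n_gids, n_events)
    order = np.lexsort((gids, times))
    return simdata.SpikeReport(times[order], gids[order], 0.0, duration)
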