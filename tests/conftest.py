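import numpy as np
import pytest

import neurosem as ns
from neurosem.synthetic import default_active_vertices


@pytest.fixture(scope="session")
def small_config():
    """A reduced-scale experiment: 20 words, 8-dim embeddings, 3 subjects."""
    return ns.SyntheticConfig(
        n_words=20,
        n_abstract=10,
        embed_dim=8,
        cluster_separation=5.0,
        n_subjects=3,
        n_channels=16,
        n_vertices_per_hemisphere=48,
        sfreq=1000.0,
        epoch_window=(0.0, 400.0),
        active_window=(200.0, 300.0),
        snr=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_mesh(small_config):
    return ns.gen_vertex_mesh(small_config)


@pytest.fixture(scope="session")
def small_table(small_config):
    return ns.gen_embedding_table(small_config)


@pytest.fixture(scope="session")
def signal_config(small_config):
    """Same scale, but with an explicit contiguous active patch and high snr."""
    mesh = ns.gen_vertex_mesh(small_config)
    active = default_active_vertices(mesh, radius_cm=4.0)
    return ns.SyntheticConfig(
        **{
            **small_config.__dict__,
            "active_vertices": tuple(int(v) for v in active),
            "snr": 10.0,
        }
    )


@pytest.fixture(scope="session")
def simulated(signal_config, small_mesh):
    table = ns.gen_embedding_table(signal_config)
    source, truth = ns.simulate_source_estimates(table, small_mesh, signal_config)
    evoked = ns.simulate_sensor_evoked(source, truth, signal_config)
    return table, source, truth, evoked
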