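import numpy as np
import pytest

import motifcoop as mc


@pytest.fixture(scope="session")
def small_library():
    return mc.synthetic_library(n_motifs=12, seed=7)


@pytest.fixture(scope="session")
def tiny_library():
    return mc.synthetic_library(n_motifs=4, seed=3)


@pytest.fixture(scope="session")
def small_simulation(small_library):
    """500+500 embedded-motif dataset with ground truth."""
    spec = mc.SimulationSpec(motif_a=small_library[0], motif_b=small_library[1],
                             n_pos=500, n_neg=500, seed=11)
    dataset, truth = mc.build_simulation(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def trained_small(small_library, small_simulation):
    """A quickly trained classifier plus its feature maps, shared across
    network/attribution tests."""
    from motifcoop.pipeline import _feature_maps_and_hits

    _, dataset, _ = small_simulation
    config = mc.ModelConfig(n_motifs=len(small_library), epochs=8, seed=11)
    maps, hits = _feature_maps_and_hits(dataset, small_library, config)
    model = mc.AttentionClassifier(small_library, config)
    model.fit(maps, dataset.labels(), dataset.train_idx, dataset.test_idx)
    return model, maps, hits, dataset
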