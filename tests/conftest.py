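import numpy as np
import pandas as pd
import pytest

from tripssa.construct import MismatchSpec, build_reference_construct
from tripssa.simulate import (
    SimConfig,
    attach_features,
    simulate_chromatin_features,
    simulate_genome,
    simulate_insertions,
)


@pytest.fixture(scope="session")
def gt_construct():
    return build_reference_construct(MismatchSpec.from_code("G:T"), "A" * 20)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=1, n_barcodes=200, n_replicates=2)


@pytest.fixture(scope="session")
def genome_bundle(small_config):
    """Toy genome, annotation, insertions and chromatin features (shared)."""
    genome, annotation = simulate_genome(small_config)
    insertions = simulate_insertions(genome, annotation, small_config)
    features = simulate_chromatin_features(genome, small_config)
    insertions_f = attach_features(insertions, features, small_config)
    return {
        "genome": genome,
        "annotation": annotation,
        "insertions": insertions,
        "insertions_f": insertions_f,
        "features": features,
    }


def as_pairs(fwd_records, rev_records):
    """Strip read names from simulator output: [(name, seq)] -> [(fwd, rev)]."""
    return [(f, r) for (_, f), (_, r) in zip(fwd_records, rev_records)]
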