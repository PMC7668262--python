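import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from alusirna import (
    CascadeIndex,
    SimConfig,
    make_synthetic_references,
    preprocess_reads,
    run_cascade,
    simulate_library,
)

LIB_SEED = 20240917


@pytest.fixture(scope="session")
def refs():
    """Small synthetic reference world shared across tests."""
    return make_synthetic_references(LIB_SEED)


@pytest.fixture(scope="session")
def cascade_index(refs):
    return CascadeIndex(refs.ref_sets)


@pytest.fixture(scope="session")
def big_library(refs):
    """A 10^5-read simulated library under the default study conditions."""
    config = SimConfig(seed=LIB_SEED, n_reads=100_000)
    reads, truth = simulate_library(config, refs)
    return config, reads, truth


@pytest.fixture(scope="session")
def big_summary(refs, cascade_index, big_library):
    """Preprocessed and fully annotated 10^5-read library."""
    config, reads, truth = big_library
    passed, report = preprocess_reads(reads, config.adaptor)
    summary = run_cascade(passed, refs.ref_sets, index=cascade_index)
    return summary, report, truth
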