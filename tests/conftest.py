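import numpy as np
import pytest

import fivedge as f
from fivedge.mapping import ColorIndex
from fivedge.reference import concatenate_reference


@pytest.fixture(scope="session")
def toy():
    """Small genome + annotation + truth shared across tests."""
    genome, models = f.make_toy_genome(2, 30, seed=5)
    truth = f.assign_expression_profiles(models, seed=6)
    reference = concatenate_reference(genome.scaffolds)
    return {"genome": genome, "models": models, "truth": truth, "reference": reference}


@pytest.fixture(scope="session")
def toy_index(toy):
    return ColorIndex(toy["reference"])


@pytest.fixture(scope="session")
def small_library(toy):
    params = f.LibraryParams(depth=20_000, color_error_rate=0.01)
    batch, truth_hits = f.simulate_tags(
        toy["genome"], toy["models"], toy["truth"], params, "t0", seed=7
    )
    return batch, truth_hits
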