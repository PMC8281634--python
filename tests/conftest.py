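import numpy as np
import pandas as pd
import pytest

from ductevo.synthetic import (
    SimulationConfig,
    assign_samples,
    make_clone_tree,
    make_genome,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def genome(default_config):
    return make_genome(default_config)


@pytest.fixture(scope="session")
def clone_tree(default_config, genome):
    return make_clone_tree(default_config, n_clones=3, n_events=4, genome=genome)


@pytest.fixture(scope="session")
def patient(default_config, genome, clone_tree):
    """One simulated patient: counts, truth, assignment, normals."""
    assignment = assign_samples(clone_tree, default_config.samples_per_clone)
    counts, truth = simulate_expression(genome, clone_tree, default_config, assignment)
    normals = [s for s, c in assignment.items() if c == "normal"]
    return {
        "counts": counts,
        "truth": truth,
        "assignment": assignment,
        "normals": normals,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
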