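import numpy as np
import pytest

from mirmoo.preprocess import (
    ExpressionMatrix,
    filter_missing,
    knn_impute,
    quantile_normalize,
)
from mirmoo.regnet import (
    annotate_disease_genes,
    construct_cascade_network,
    filter_mirna_targets,
    fr_table,
)
from mirmoo.synthetic import SimulationScenario, simulate_expression, simulate_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """4 miRNAs x 3 samples, complete."""
    values = np.array(
        [
            [25.0, 26.0, 24.5],
            [30.0, 29.0, 31.0],
            [22.0, 22.5, 21.0],
            [28.0, 27.5, 29.5],
        ]
    )
    return ExpressionMatrix([f"m{i}" for i in range(4)], ["s0", "s1", "s2"], values)


@pytest.fixture(scope="session")
def default_scenario():
    return SimulationScenario(seed=3)


@pytest.fixture(scope="session")
def scenario_data(default_scenario):
    """Preprocessed expression + labels for the default synthetic scenario."""
    mat, labels, truth = simulate_expression(default_scenario)
    mat = filter_missing(mat, 0.5)
    mat = quantile_normalize(mat)
    mat = knn_impute(mat, 10)
    return mat, labels, truth


@pytest.fixture(scope="session")
def scenario_fr(default_scenario, scenario_data):
    """Annotated network FR table for the default scenario."""
    mat, _, _ = scenario_data
    records, tf_edges, ranks, _ = simulate_network(default_scenario)
    edges = filter_mirna_targets(records)
    net = construct_cascade_network(edges, tf_edges, mat.mirna_ids)
    annotate_disease_genes(net, ranks)
    return fr_table(net, mat.mirna_ids)
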