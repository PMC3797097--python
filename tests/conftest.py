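import numpy as np
import pytest

from gidphylo.orthology import classify_proteomes
from gidphylo.pipeline_cli import pick_references
from gidphylo.synthetic_data import SimulationConfig, generate_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Default-conditions synthetic benchmark, fixed seed."""
    return generate_benchmark(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def benchmark_calls(benchmark):
    """Orthology calls over the benchmark proteomes (true annotations)."""
    proteomes = benchmark.proteomes()
    references = pick_references(
        proteomes, benchmark.truth_orthology(), benchmark.supergroups
    )
    annotations = benchmark.true_annotations()
    return classify_proteomes(proteomes, references, annotations)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
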