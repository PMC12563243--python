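import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from cnsrepurpose import synthdata

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def path_graph_abc() -> nx.Graph:
    """Three-node path A-B-C; B is the unique center."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def small_synth_cfg() -> synthdata.SyntheticConfig:
    return synthdata.SyntheticConfig(seed=7, n_genes=60, n_drugs=30, n_target_genes=8)
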