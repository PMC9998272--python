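import networkx as nx
import numpy as np
import pytest

from istpower.core import LabeledTissue, SpatialParameters, TissueScaffold
from istpower.scaffold import generate_scaffold


@pytest.fixture(scope="session")
def scaffold_2k() -> TissueScaffold:
    """A ~2,200-cell scaffold at the tissue-microarray-core scale."""
    return generate_scaffold(500, 500, seed=11)


@pytest.fixture(scope="session")
def scaffold_small() -> TissueScaffold:
    """A ~200-cell scaffold for fast statistical tests."""
    return generate_scaffold(150, 150, seed=7)


def make_tissue(graph: nx.Graph, labels, K: int, seed: int = 0) -> LabeledTissue:
    """Wrap an arbitrary graph as a labeled tissue with dummy geometry."""
    n = graph.number_of_nodes()
    rng = np.random.default_rng(seed)
    xy = rng.random((n, 2)) * 10.0
    scaffold = TissueScaffold(
        xy=xy, radii=np.ones(n), graph=graph, region_bounds=(10.0, 10.0), r_min=1.0
    )
    return LabeledTissue(scaffold=scaffold, labels=np.asarray(labels), K=K)


@pytest.fixture
def null_params_k4() -> SpatialParameters:
    """Four types, one rare (3%), no adjacency structure."""
    p = np.array([0.03, 0.32, 0.32, 0.33])
    return SpatialParameters.uniform_neighbors(p)
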