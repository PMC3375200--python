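import io

import numpy as np
import obonet
import pytest

from netphylo import funcspace, topology
from netphylo.simulate import GeneratorConfig, generate_dataset

TOY_OBO = """format-version: 1.2
ontology: toy-test

[Term]
id: T:0000
name: biological_process
namespace: biological_process

[Term]
id: T:0001
name: metabolism
namespace: biological_process
is_a: T:0000 ! root

[Term]
id: T:0002
name: signaling
namespace: biological_process
is_a: T:0000 ! root

[Term]
id: T:0003
name: transport
namespace: biological_process
is_a: T:0000 ! root

[Term]
id: T:0011
name: carbohydrate metabolism
namespace: biological_process
is_a: T:0001 ! metabolism

[Term]
id: T:0012
name: membrane signaling transport
namespace: biological_process
is_a: T:0002 ! signaling
is_a: T:0003 ! transport

[Term]
id: T:0111
name: glycolysis
namespace: biological_process
is_a: T:0011 ! carbohydrate metabolism

[Term]
id: M:0000
name: molecular_function
namespace: molecular_function

[Term]
id: M:0001
name: binding
namespace: molecular_function
is_a: M:0000 ! root
"""


@pytest.fixture(scope="session")
def toy_obo():
    return obonet.read_obo(io.StringIO(TOY_OBO))


@pytest.fixture(scope="session")
def small_ds():
    """Small synthetic study at generator defaults."""
    return generate_dataset(GeneratorConfig(n_final=300, seed=7))


@pytest.fixture(scope="session")
def default_ds():
    """Mid-size synthetic study at generator defaults (planted structure)."""
    return generate_dataset(GeneratorConfig(n_final=800, seed=11))


@pytest.fixture(scope="session")
def default_funcspace(default_ds):
    """Annotation matrix, pairwise distances and BFS distances for default_ds."""
    ds = default_ds
    obo = obonet.read_obo(io.StringIO(ds.obo_text))
    am = funcspace.build_annotation_matrix(ds.annotations, obo,
                                           gene_order=sorted(ds.net.graph.nodes))
    D = funcspace.pairwise_mahalanobis(am.X, am.cov_inverse)
    dist = topology.all_pairs_distances(ds.net)
    return {"obo": obo, "am": am, "D": D, "distances": dist}


def random_grouped_graph(n, p, seed):
    """Erdos-Renyi graph with random temporal groups, as (net, groups)."""
    import networkx as nx

    from netphylo.io import PPINetwork

    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    groups = {node: int(rng.integers(1, 7)) for node in g.nodes}
    return PPINetwork(g), groups
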