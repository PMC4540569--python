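import random

import pytest

import ctrlpaths as cp
from ctrlpaths.semantic_similarity import OntologyDAG, SimilarityScorer


@pytest.fixture
def five_node_net():
    """The 5-node worked example: links 1→3, 1→4, 2→3, 3→5; its unique
    maximum matching {1→4, 2→3, 3→5} splits the network into two stems."""
    return cp.network_from_links([("1", "3"), ("1", "4"), ("2", "3"), ("3", "5")])


@pytest.fixture
def three_cycle():
    return cp.network_from_links([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def toy_dag():
    """root ← a ← {t1, t2}, all is_a edges."""
    return OntologyDAG(
        frozenset(["root", "a", "t1", "t2"]),
        {"a": (("root", "is_a"),), "t1": (("a", "is_a"),), "t2": (("a", "is_a"),)},
    )


@pytest.fixture(scope="session")
def bundle():
    return cp.generate_disease_benchmark(seed=1)


@pytest.fixture(scope="session")
def bundle_scorer(bundle):
    return SimilarityScorer(bundle.annotations, bundle.ontology)


def random_small_network(rng: random.Random, max_nodes: int = 8, max_links: int = 12):
    """Seeded random simple digraph for oracle comparisons."""
    n = rng.randint(2, max_nodes)
    names = [f"n{i}" for i in range(n)]
    n_links = rng.randint(1, min(max_links, n * (n - 1)))
    links = set()
    while len(links) < n_links:
        t, h = rng.sample(names, 2)
        links.add((t, h))
    return cp.network_from_links(links, nodes=names)


def random_sparse_network(rng: random.Random, max_nodes: int = 8):
    """Random digraph with at most one link per node on average — the density
    regime of curated regulatory maps, where the link-swap walk mixes well."""
    n = rng.randint(3, max_nodes)
    names = [f"n{i}" for i in range(n)]
    links = set()
    target = rng.randint(1, n)
    while len(links) < target:
        t, h = rng.sample(names, 2)
        links.add((t, h))
    return cp.network_from_links(links, nodes=names)
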