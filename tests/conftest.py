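"""Shared fixtures: worked-example trees and generic random instances."""

import itertools

import networkx as nx
import numpy as np
import pytest

import splitrank as sr


def make_binary_quartet(seed: int = 42):
    """k=2 quartet ((0,1),(2,3)) with zero-length pendant edges and a
    generic invertible internal-edge matrix; uniform root distribution.

    Only patterns of the form (x, x, y, y) have positive probability.
    """
    g = nx.Graph()
    g.add_edge(100, "0", length=0.0)
    g.add_edge(100, "1", length=0.0)
    g.add_edge(101, "2", length=0.0)
    g.add_edge(101, "3", length=0.0)
    rng = np.random.default_rng(seed)
    g.add_edge(100, 101, matrix=rng.dirichlet([5.0, 5.0], size=2), length=0.3)
    return sr.PhyloTree(g, k=2)


def generic_markov_tree(t: int, rng: np.random.Generator, k: int = 4):
    """Random binary tree with generic invertible row-stochastic edge
    matrices (diagonally dominant, so rank gaps stay numerically clean)."""
    tree = sr.random_binary_tree([str(i) for i in range(t)], rng, 0.1, k=k)
    for _, _, d in tree.graph.edges(data=True):
        d["matrix"] = 0.5 * np.eye(k) + 0.5 * rng.dirichlet([5.0] * k, size=k)
    return tree


def brute_force_parsimony(tree, split) -> int:
    """Minimise state changes over all internal-node labellings."""
    g = tree.graph
    internals = tree.internal_nodes()
    states = {x: 0 for x in split.side_a}
    states.update({x: 1 for x in split.side_b})
    best = len(g.edges)
    for assign in itertools.product((0, 1), repeat=len(internals)):
        st = dict(states)
        st.update(zip(internals, assign))
        best = min(best, sum(st[u] != st[v] for u, v in g.edges))
    return best


def brute_force_shared_edges(tree, split) -> int:
    """Intersect the two spanning subtrees built from leaf-pair paths."""

    def span(side):
        edges = set()
        for a, b in itertools.combinations(sorted(side), 2):
            path = nx.shortest_path(tree.graph, a, b)
            edges |= {frozenset(e) for e in zip(path, path[1:])}
        return edges

    return len(span(split.side_a) & span(split.side_b))


@pytest.fixture(scope="session")
def binary_quartet():
    return make_binary_quartet()


@pytest.fixture(scope="session")
def binary_quartet_dist(binary_quartet):
    return sr.site_pattern_distribution(binary_quartet)


@pytest.fixture(scope="session")
def six_taxon_tree():
    from splitrank.experiments import balanced_six_taxon_tree

    return balanced_six_taxon_tree(0.1)


@pytest.fixture(scope="session")
def six_taxon_dist(six_taxon_tree):
    return sr.site_pattern_distribution(six_taxon_tree)
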