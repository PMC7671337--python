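"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation code paths they check:
Dollo placement by exhaustive subset search, ontology counting by naive
graph walking, and tree enumeration by recursive set partitions.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import dendropy


# ---------------------------------------------------------------------------
# Dollo


def dollo_oracle(
    tree: dendropy.Tree, states: dict[str, str]
) -> tuple[int, list[set[frozenset]]]:
    """Minimal Dollo placements by exhaustive search over branch subsets.

    Returns (minimal event count, list of all minimal valid placements),
    each placement given as a set of frozensets of subtended leaf labels.
    A placement is valid when the chosen subtrees are pairwise disjoint,
    contain no INTACT leaf, and jointly cover every LOST leaf.
    """
    # the root branch is a legal event (gene lost in every species)
    branches = list(tree.preorder_node_iter())
    leafsets = [
        frozenset(leaf.taxon.label for leaf in n.leaf_iter()) for n in branches
    ]
    lost = {k for k, v in states.items() if v == "LOST"}
    intact = {k for k, v in states.items() if v == "INTACT"}
    if not lost:
        return 0, [set()]
    candidates = [
        ls for ls in set(leafsets) if not (ls & intact) and (ls & lost)
    ]
    for r in range(1, len(candidates) + 1):
        found = []
        for combo in itertools.combinations(candidates, r):
            cover: set = set()
            ok = True
            for ls in combo:
                if ls & cover:
                    ok = False
                    break
                cover |= ls
            if ok and lost <= cover:
                found.append(set(combo))
        if found:
            return r, found
    raise AssertionError("no valid Dollo placement found")


def enumerate_rooted_trees(leaves: list[str]) -> Iterable[str]:
    """All rooted (multifurcations allowed) topologies on labeled leaves,
    as newick strings, each exactly once."""
    from sympy.utilities.iterables import multiset_partitions

    if len(leaves) == 1:
        yield leaves[0]
        return
    for partition in multiset_partitions(sorted(leaves)):
        if len(partition) < 2:
            continue
        for subtrees in itertools.product(
            *(enumerate_rooted_trees(block) for block in partition)
        ):
            yield "(" + ",".join(subtrees) + ")"


# ---------------------------------------------------------------------------
# ontology


def random_dag(rng, n_terms: int):
    """Random layered is_a DAG (<= n_terms terms) with occasional diamonds."""
    import networkx as nx

    from geneloss.ontology import OntologyDAG

    g = nx.DiGraph()
    g.add_node("R")
    layers = [["R"]]
    t = 0
    while t < n_terms:
        width = int(rng.integers(1, 6))
        layer = []
        for _ in range(width):
            if t >= n_terms:
                break
            term = f"T{t}"
            t += 1
            parent_layer = layers[-1]
            g.add_edge(term, parent_layer[int(rng.integers(0, len(parent_layer)))])
            if len(layers) > 1 and rng.random() < 0.3:
                upper = layers[int(rng.integers(0, len(layers)))]
                other = upper[int(rng.integers(0, len(upper)))]
                if other != term and not nx.has_path(g, other, term):
                    g.add_edge(term, other)
            layer.append(term)
        layers.append(layer or layers[-1])
    return OntologyDAG.from_graph(g)


def closure_oracle(graph_edges: dict[str, set[str]], term: str) -> set[str]:
    """All ancestors reachable over child->parent edges, by plain DFS."""
    seen: set[str] = set()
    stack = [term]
    while stack:
        node = stack.pop()
        for parent in graph_edges.get(node, ()):
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


def level_oracle(graph_edges: dict[str, set[str]], root: str, term: str) -> int:
    """1 + shortest child->parent path length to the root, by BFS over
    ALL paths (no networkx)."""
    if term == root:
        return 1
    frontier = {term}
    depth = 0
    while frontier:
        depth += 1
        nxt = set()
        for node in frontier:
            for parent in graph_edges.get(node, ()):
                if parent == root:
                    return depth + 1
                nxt.add(parent)
        frontier = nxt
    raise AssertionError(f"{term} does not reach root")


# ---------------------------------------------------------------------------
# rank-sum


def exact_rank_sum_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact permutation p for the rank-sum statistic."""
    import numpy as np
    from scipy.stats import rankdata

    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = rankdata(pooled)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total
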