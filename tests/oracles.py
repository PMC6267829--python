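"""Independent brute-force oracles for tree tests.

Enumerates all unrooted leaf-labelled topologies by sequential leaf
insertion, fits branch lengths by ordinary least squares on the pairwise
path design, and scores each topology by total tree length — a brute-force
minimum-evolution search usable as an oracle for neighbor joining on 4–5
taxa.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations

import numpy as np

Edge = tuple[str, str]


def enumerate_topologies(labels: list[str]) -> list[list[Edge]]:
    a, b, c = labels[:3]
    trees: list[list[Edge]] = [[("I0", a), ("I0", b), ("I0", c)]]
    for j, leaf in enumerate(labels[3:]):
        nxt = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = f"I{j + 1}"
                nxt.append(edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, leaf)])
        trees = nxt
    return trees


def _adjacency(edges: list[Edge]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = defaultdict(set)
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _path_edges(edges: list[Edge], src: str, dst: str) -> list[int]:
    adj = _adjacency(edges)
    index = {frozenset(e): i for i, e in enumerate(edges)}
    stack = [(src, None, [])]
    while stack:
        node, prev, path = stack.pop()
        if node == dst:
            return path
        for nb in adj[node]:
            if nb != prev:
                stack.append((nb, node, path + [index[frozenset((node, nb))]]))
    raise AssertionError("disconnected tree")


def ls_tree_length(edges: list[Edge], labels: list[str], dist: np.ndarray) -> float:
    """Total tree length under an OLS branch-length fit of one topology."""
    pairs = list(combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in _path_edges(edges, labels[i], labels[j]):
            A[row, e] = 1.0
        d[row] = dist[i, j]
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    return float(x.sum())


def topology_splits(edges: list[Edge], labels: list[str]) -> frozenset:
    """Non-trivial bipartitions, matching PhyloTree.topology_key format."""
    leaves = frozenset(labels)
    adj = _adjacency(edges)
    out = set()
    for u, v in edges:
        if u in leaves or v in leaves:
            continue
        side = set()
        stack, seen = [u], {v}
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if node in leaves:
                side.add(node)
            else:
                stack.extend(adj[node])
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset({frozenset(side), leaves - side}))
    return frozenset(out)


def brute_force_min_evolution(labels: list[str], dist: np.ndarray) -> frozenset:
    """Splits of the minimum-evolution topology over the full enumeration."""
    best, best_len = None, np.inf
    for edges in enumerate_topologies(labels):
        length = ls_tree_length(edges, labels, dist)
        if length < best_len - 1e-10:
            best, best_len = edges, length
    return topology_splits(best, labels)


def random_additive_matrix(
    labels: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Pairwise path distances of a random binary tree with random lengths."""
    topologies = enumerate_topologies(labels)
    edges = topologies[rng.integers(0, len(topologies))]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    n = len(labels)
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        path = _path_edges(edges, labels[i], labels[j])
        dist[i, j] = dist[j, i] = float(lengths[path].sum())
    return dist
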