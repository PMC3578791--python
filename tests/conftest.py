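"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from protistdiv.distances import DistanceMatrix
from protistdiv.seq_regions import GroupAlignment


@pytest.fixture
def tiny_alignment() -> GroupAlignment:
    return GroupAlignment(
        group_id="tiny",
        names=["s1", "s2", "s3"],
        rows=["ACGTACGT", "ACGTACGA", "ACGTTCGA"],
    )


def make_matrix(names: list[str], pair_d: dict[tuple[str, str], float]) -> DistanceMatrix:
    """DistanceMatrix from explicit pair distances (for clustering tests)."""
    n = len(names)
    d = np.zeros((n, n))
    for (a, b), v in pair_d.items():
        i, j = names.index(a), names.index(b)
        d[i, j] = d[j, i] = v
    sites = np.full((n, n), 100, dtype=np.int64)
    return DistanceMatrix(names=list(names), d=d, comparable_sites=sites)


def random_matrix(rng: np.random.Generator, n: int, scale: float = 0.3) -> DistanceMatrix:
    """Random symmetric distance matrix (not necessarily metric)."""
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.random(len(iu[0])) * scale
    # sprinkle exact ties and zeros to exercise the tie rule
    ties = rng.random(len(vals)) < 0.25
    vals[ties] = rng.choice([0.0, 0.01, 0.05], size=int(ties.sum()))
    d[iu] = vals
    d += d.T
    names = [f"s{i:02d}" for i in range(n)]
    return DistanceMatrix(
        names=names, d=d, comparable_sites=np.full((n, n), 100, dtype=np.int64)
    )


def brute_force_complete_linkage(
    m: DistanceMatrix, precision: int = 10_000
) -> list[tuple[float, frozenset[str]]]:
    """O(n^3) reference agglomeration, recomputing every cluster distance
    directly from the rounded input matrix at every step.

    Uses the same tie rule as the implementation (lexicographically smallest
    member names) so full merge lists are comparable.
    """
    grid = {}
    for i, a in enumerate(m.names):
        for j, b in enumerate(m.names):
            if i < j:
                grid[(a, b)] = grid[(b, a)] = int(
                    math.floor(m.d[i, j] * precision + 0.5)
                )
    clusters: list[frozenset[str]] = [frozenset([n]) for n in m.names]
    merges: list[tuple[float, frozenset[str]]] = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                dist = max(
                    grid[(a, b)] for a in clusters[x] for b in clusters[y]
                )
                key = (dist, tuple(sorted((min(clusters[x]), min(clusters[y])))))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (dist, _), x, y = best
        new = clusters[x] | clusters[y]
        merges.append((dist / precision, new))
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [new]
    return merges


def brute_force_patristic(tree) -> dict[tuple[str, str], float]:
    """All-pairs patristic distances by explicit path enumeration on the
    (undirected) tree graph — independent of the package's LCA computation."""
    adj: dict[int, list[tuple[int, float]]] = {}
    label: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            label[id(node)] = node.taxon.label
        parent = node.parent_node
        if parent is not None:
            w = node.edge.length or 0.0
            adj.setdefault(id(node), []).append((id(parent), w))
            adj.setdefault(id(parent), []).append((id(node), w))
    out: dict[tuple[str, str], float] = {}
    for src, src_label in label.items():
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst, dst_label in label.items():
            if src_label < dst_label:
                out[(src_label, dst_label)] = dist[dst]
    return out
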