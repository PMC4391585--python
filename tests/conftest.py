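"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths (and
networkx) so they can serve as independent references: betweenness by
explicit shortest-path enumeration, components by union-find, path
statistics by hand-rolled BFS.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd
import pytest

from ncnet.matrix import MRNA, NCRNA, ExpressionMatrix
from ncnet.network import BipartiteNetwork


# -- construction helpers -------------------------------------------------


def make_matrix(
    values: np.ndarray,
    gene_ids: list[str],
    gene_class: list[str],
    conditions: list[str],
    patient_ids: list[str | None] | None = None,
    detectable: np.ndarray | None = None,
    subclass: dict[str, str] | None = None,
) -> ExpressionMatrix:
    n_genes, n_samples = values.shape
    sample_ids = [f"S{i:02d}" for i in range(n_samples)]
    if patient_ids is None:
        patient_ids = [
            f"P{i:02d}" if c in ("relapse", "remission") else None
            for i, c in enumerate(conditions)
        ]
    det = None
    if detectable is not None:
        det = pd.DataFrame(detectable, index=gene_ids, columns=sample_ids)
    sub = None
    if subclass:
        sub = pd.Series(subclass)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        gene_class=pd.Series(gene_class, index=gene_ids),
        condition=pd.Series(conditions, index=sample_ids),
        patient_id=pd.Series(patient_ids, index=sample_ids, dtype=object),
        detectable=det,
        ncrna_subclass=sub,
    )


def net_from_pairs(pairs, r=-0.5, sign="negative", label="derived") -> BipartiteNetwork:
    """Network from (ncrna, mrna) pairs, all with the same R."""
    return BipartiteNetwork(
        edges={(nc, m): r for nc, m in pairs}, sign=sign, condition_label=label
    )


def random_bipartite(rng, n_nc: int, n_m: int, n_edges: int) -> BipartiteNetwork:
    pairs = [(f"n{i}", f"m{j}") for i in range(n_nc) for j in range(n_m)]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    return net_from_pairs([pairs[i] for i in idx])


# -- independent oracles --------------------------------------------------


def adjacency(net: BipartiteNetwork) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for nc, m in net.edges:
        adj[nc].add(m)
        adj[m].add(nc)
    return adj


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def oracle_components(net: BipartiteNetwork) -> list[set[str]]:
    """Connected components by union-find."""
    parent = {n: n for n in net.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for nc, m in net.edges:
        ra, rb = find(nc), find(m)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for n in net.nodes:
        groups.setdefault(find(n), set()).add(n)
    return list(groups.values())


def oracle_path_hist(net: BipartiteNetwork) -> tuple[dict[int, int], float]:
    """Shortest-path length histogram over connected unordered pairs (BFS)."""
    adj = adjacency(net)
    nodes = sorted(net.nodes)
    hist: dict[int, int] = {}
    total = count = 0
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1 :]:
            if t in dist:
                hist[dist[t]] = hist.get(dist[t], 0) + 1
                total += dist[t]
                count += 1
    return dict(sorted(hist.items())), total / count


def oracle_betweenness(net: BipartiteNetwork) -> dict[str, float]:
    """Exhaustive shortest-path enumeration, normalized per component."""
    adj = adjacency(net)
    comps = oracle_components(net)
    raw = {n: 0.0 for n in net.nodes}
    for comp in comps:
        nodes = sorted(comp)
        for i, s in enumerate(nodes):
            dist = bfs_distances(adj, s)
            for t in nodes[i + 1 :]:
                if t not in dist:
                    continue
                paths = _all_shortest_paths(adj, dist, s, t)
                for v in comp:
                    if v in (s, t):
                        continue
                    through = sum(1 for p in paths if v in p)
                    raw[v] += through / len(paths)
        n_c = len(comp)
        norm = (n_c - 1) * (n_c - 2) / 2.0
        for v in comp:
            raw[v] = raw[v] / norm if norm > 0 else 0.0
    return raw


def _all_shortest_paths(adj, dist, s, t) -> list[list[str]]:
    """Enumerate shortest s-t paths by walking the BFS level structure."""
    out: list[list[str]] = []

    def extend(path: list[str]) -> None:
        u = path[-1]
        if u == t:
            out.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist.get(v, 1e9) <= dist[t]:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
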