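"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mdinet import AlignedMatrix, SyntheticConfig, default_mdb_table, generate_dataset


@pytest.fixture(scope="session")
def mdb_table():
    return default_mdb_table()


@pytest.fixture(scope="session")
def mdb_table_glycation():
    return default_mdb_table(include_glycation=True)


@pytest.fixture
def toy_matrix():
    """4 features x 3 samples with a missing-value pattern and classes."""
    inten = pd.DataFrame(
        {
            "s1": [100.0, np.nan, 50.0, 10.0],
            "s2": [200.0, 30.0, np.nan, 20.0],
            "s3": [np.nan, 60.0, np.nan, 40.0],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    mass = pd.Series([100.0, 114.01565, 116.0313, 150.0], index=inten.index)
    classes = pd.Series({"s1": "A", "s2": "A", "s3": "B"})
    return AlignedMatrix(inten, mass, classes)


@pytest.fixture(scope="session")
def synthetic_small():
    """3 classes x 5 samples synthetic dataset with ground truth."""
    cfg = SyntheticConfig(seed=11, samples_per_class=5)
    return generate_dataset(cfg)


# ---------------------------------------------------------------------------
# oracle: brute-force MDiN edge list
# ---------------------------------------------------------------------------

def brute_force_edges(masses: dict, mdbs, ppm: float) -> set:
    """All (u, v, label) edges by direct scan of every pair and every MDB."""
    edges = set()
    ids = list(masses)
    for u, v in combinations(ids, 2):
        m_small, m_large = sorted((masses[u], masses[v]))
        for mdb in mdbs:
            if abs((m_large - m_small) - mdb.delta_mass) <= ppm * 1e-6 * m_large:
                edges.add(frozenset((u, v)) | {("label", mdb.label)})
    return edges


def edge_key_set(g: nx.MultiGraph) -> set:
    return {
        frozenset((u, v)) | {("label", k)} for u, v, k in g.edges(keys=True)
    }


# ---------------------------------------------------------------------------
# oracle: shortest-path centralities by explicit path enumeration
# ---------------------------------------------------------------------------

def _bfs(adj: dict, s):
    dist = {s: 0}
    preds: dict = {v: [] for v in adj}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
            if dist.get(w) == dist[u] + 1:
                preds[w].append(u)
    return dist, preds


def _all_shortest_paths(preds, s, t):
    if t == s:
        return [[s]]
    out = []
    for p in preds[t]:
        out.extend(path + [t] for path in _all_shortest_paths(preds, s, p))
    return out


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Sum over unordered pairs of the fraction of geodesics through v."""
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    bt = dict.fromkeys(adj, 0.0)
    nodes = list(adj)
    for s, t in combinations(nodes, 2):
        dist, preds = _bfs(adj, s)
        if t not in dist:
            continue
        paths = _all_shortest_paths(preds, s, t)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bt[v] += through / len(paths)
    return bt


def brute_force_closeness(g: nx.Graph) -> dict:
    """((n-1)/(N-1)) * ((n-1)/sum d) with n = reachable nodes incl. v."""
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    big_n = len(adj)
    out = {}
    for v in adj:
        dist, _ = _bfs(adj, v)
        n = len(dist)
        total = sum(dist.values())
        if n <= 1 or total == 0 or big_n <= 1:
            out[v] = 0.0
        else:
            out[v] = ((n - 1) / (big_n - 1)) * ((n - 1) / total)
    return out


# ---------------------------------------------------------------------------
# oracle: graphlet orbit counts by exhaustive subset enumeration
# ---------------------------------------------------------------------------

# orbit of a node within each connected graphlet, keyed by
# (subset size, induced edge count, degree multiset, node's induced degree);
# built by hand from the canonical 2-4-node graphlet/orbit figure
_ORACLE_ORBIT = {
    (2, 1, (1, 1), 1): 0,
    (3, 2, (1, 1, 2), 1): 1,
    (3, 2, (1, 1, 2), 2): 2,
    (3, 3, (2, 2, 2), 2): 3,
    (4, 3, (1, 1, 2, 2), 1): 4,   # path: end
    (4, 3, (1, 1, 2, 2), 2): 5,   # path: middle
    (4, 3, (1, 1, 1, 3), 1): 6,   # claw: leaf
    (4, 3, (1, 1, 1, 3), 3): 7,   # claw: center
    (4, 4, (2, 2, 2, 2), 2): 8,   # cycle
    (4, 4, (1, 2, 2, 3), 1): 9,   # paw: pendant
    (4, 4, (1, 2, 2, 3), 2): 10,  # paw: triangle edge
    (4, 4, (1, 2, 2, 3), 3): 11,  # paw: attachment
    (4, 5, (2, 2, 3, 3), 2): 12,  # diamond: rim
    (4, 5, (2, 2, 3, 3), 3): 13,  # diamond: hub
    (4, 6, (3, 3, 3, 3), 3): 14,  # K4
}


def _subset_connected(sub, adj) -> bool:
    seen = {sub[0]}
    stack = [sub[0]]
    members = set(sub)
    while stack:
        u = stack.pop()
        for w in adj[u] & members:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(sub)


def brute_force_orbits(g: nx.Graph) -> pd.DataFrame:
    simple = nx.Graph(g)
    nodes = list(simple.nodes)
    adj = {v: set(simple.neighbors(v)) for v in nodes}
    counts = pd.DataFrame(0, index=nodes, columns=[f"o{i}" for i in range(15)])
    for k in (2, 3, 4):
        for sub in combinations(nodes, k):
            if not _subset_connected(sub, adj):
                continue
            deg = {v: len(adj[v] & set(sub)) for v in sub}
            n_edges = sum(deg.values()) // 2
            multiset = tuple(sorted(deg.values()))
            for v in sub:
                orb = _ORACLE_ORBIT[(k, n_edges, multiset, deg[v])]
                counts.loc[v, f"o{orb}"] += 1
    return counts
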