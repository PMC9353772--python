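"""Graph-property profiles of sample mass-difference networks.

Each metric turns a collection of sMDiNs into a samples x features matrix
("profile") that downstream clustering/classification consumes exactly like
a pretreated intensity matrix:

* degree / betweenness / closeness — node-centric profiles over the feature
  universe (absent features are 0);
* MDBI / WMDBI — per-sample fraction of edges attributed to each chemical
  transformation, optionally weighting every edge by the summed importance
  of its endpoints (importances come from a random forest trained on the
  degree profiles);
* GCD-11 — graphlet-correlation topology signature: Spearman correlations
  among the 11 non-redundant orbit counts of 2-4-node graphlets.

Betweenness is the unnormalized sum over unordered node pairs with the
endpoints excluded; closeness is the component-size-corrected form
C(v) = ((n-1)/(N-1)) * ((n-1)/sum_u d(u,v)) with n the size of v's
component and N the graph's node count. Paths and orbits are computed on
the simple-graph skeleton of the multigraph; degree keeps edge multiplicity.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .mdbs import MDB

__all__ = [
    "degree_profile",
    "betweenness_profile",
    "closeness_profile",
    "mdbi_profile",
    "wmdbi_profile",
    "node_importance_from_degree",
    "count_graphlet_orbits",
    "gcd_features",
    "gcd_profile",
    "NON_REDUNDANT_ORBITS",
    "N_ORBITS",
]

N_ORBITS = 15  # orbits 0..14 of the nine connected 2-4-node graphlets
NON_REDUNDANT_ORBITS = (0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11)


# ---------------------------------------------------------------------------
# node-centric profiles
# ---------------------------------------------------------------------------

def _node_profile(
    smdins: Mapping[str, nx.MultiGraph],
    universe: Sequence[str],
    per_graph,
) -> pd.DataFrame:
    rows = {}
    for sample, g in smdins.items():
        vals = per_graph(g)
        rows[sample] = [vals.get(f, 0.0) for f in universe]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(universe), dtype=float)


def degree_profile(
    smdins: Mapping[str, nx.MultiGraph], universe: Sequence[str]
) -> pd.DataFrame:
    """Node degree per sample; parallel MDB edges count separately."""
    return _node_profile(smdins, universe, lambda g: dict(g.degree()))


def betweenness_profile(
    smdins: Mapping[str, nx.MultiGraph], universe: Sequence[str]
) -> pd.DataFrame:
    """Unnormalized betweenness centrality (unordered pairs, endpoints excluded)."""
    return _node_profile(
        smdins, universe,
        lambda g: nx.betweenness_centrality(nx.Graph(g), normalized=False),
    )


def closeness_profile(
    smdins: Mapping[str, nx.MultiGraph], universe: Sequence[str]
) -> pd.DataFrame:
    """Component-corrected closeness (Wasserman–Faust form)."""
    return _node_profile(
        smdins, universe,
        lambda g: nx.closeness_centrality(nx.Graph(g), wf_improved=True),
    )


# ---------------------------------------------------------------------------
# MDB impact profiles
# ---------------------------------------------------------------------------

def _mdb_labels(mdbs: Sequence[MDB] | Sequence[str]) -> list[str]:
    return [m.label if isinstance(m, MDB) else str(m) for m in mdbs]


def mdbi_profile(
    smdins: Mapping[str, nx.MultiGraph], mdbs: Sequence[MDB] | Sequence[str]
) -> pd.DataFrame:
    """Fraction of edges attributed to each MDB (rows sum to 1; empty -> 0)."""
    labels = _mdb_labels(mdbs)
    rows = {}
    for sample, g in smdins.items():
        counts = dict.fromkeys(labels, 0.0)
        total = 0
        for _, _, data in g.edges(data=True):
            lbl = data["mdb"]
            if lbl in counts:
                counts[lbl] += 1
                total += 1
        rows[sample] = [counts[l] / total if total else 0.0 for l in labels]
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels, dtype=float)


def node_importance_from_degree(
    train_profiles: pd.DataFrame,
    train_labels: Sequence[str],
    n_trees: int = 100,
    seed: int | None = 0,
) -> pd.Series:
    """Gini importances of an RF fitted to degree profiles, normalized to 1.

    The forest learns which nodes' connectivity separates the classes; the
    importances weight edges in the WMDBI metric. If the forest assigns zero
    importance everywhere (e.g. constant profiles), falls back to uniform
    weights.
    """
    from sklearn.ensemble import RandomForestClassifier

    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to estimate importances")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(train_profiles.to_numpy(), y)
    imp = pd.Series(rf.feature_importances_, index=train_profiles.columns)
    total = imp.sum()
    if total <= 0:
        imp[:] = 1.0 / len(imp)
    else:
        imp /= total
    return imp


def wmdbi_profile(
    smdins: Mapping[str, nx.MultiGraph],
    mdbs: Sequence[MDB] | Sequence[str],
    importance: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Importance-weighted MDB impact.

    Each edge is weighted by the summed importance of the two nodes it
    links (absent nodes weigh 0); the per-MDB weight fractions replace the
    plain edge-count fractions. Samples whose edges all weigh zero fall
    back to the unweighted MDBI row.
    """
    labels = _mdb_labels(mdbs)
    imp = dict(importance)
    rows = {}
    for sample, g in smdins.items():
        wsum = dict.fromkeys(labels, 0.0)
        counts = dict.fromkeys(labels, 0.0)
        total_w = 0.0
        total_n = 0
        for u, v, data in g.edges(data=True):
            lbl = data["mdb"]
            if lbl not in wsum:
                continue
            w = imp.get(u, 0.0) + imp.get(v, 0.0)
            wsum[lbl] += w
            counts[lbl] += 1
            total_w += w
            total_n += 1
        if total_w > 0:
            rows[sample] = [wsum[l] / total_w for l in labels]
        elif total_n > 0:  # all-zero weights: unweighted fallback
            rows[sample] = [counts[l] / total_n for l in labels]
        else:
            rows[sample] = [0.0] * len(labels)
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels, dtype=float)


# ---------------------------------------------------------------------------
# graphlet orbits / GCD-11
# ---------------------------------------------------------------------------

def _orbits_of_triple(deg_in: dict) -> dict:
    """Orbit per node of a connected 3-node induced subgraph."""
    n_edges = sum(deg_in.values()) // 2
    if n_edges == 3:  # triangle
        return dict.fromkeys(deg_in, 3)
    # path: ends orbit 1, middle orbit 2
    return {v: (2 if d == 2 else 1) for v, d in deg_in.items()}


# degree-within-subgraph -> orbit, keyed by (n_edges, degree); 4-node graphlets
_QUAD_ORBIT = {
    (3, 1, False): 4, (3, 2, False): 5,       # P4 path
    (3, 1, True): 6, (3, 3, True): 7,         # K1,3 claw
    (4, 2, False): 8,                          # C4 cycle
    (4, 1, True): 9, (4, 2, True): 10, (4, 3, True): 11,  # paw
    (5, 2, False): 12, (5, 3, False): 13,      # diamond
    (6, 3, False): 14,                         # K4
}


def _orbits_of_quad(deg_in: dict) -> dict:
    n_edges = sum(deg_in.values()) // 2
    degs = sorted(deg_in.values())
    if n_edges == 3:
        star = degs == [1, 1, 1, 3]
        return {v: _QUAD_ORBIT[(3, d, star)] for v, d in deg_in.items()}
    if n_edges == 4:
        paw = degs == [1, 2, 2, 3]
        return {v: _QUAD_ORBIT[(4, d, paw)] for v, d in deg_in.items()}
    return {v: _QUAD_ORBIT[(n_edges, d, False)] for v, d in deg_in.items()}


def _connected_subsets(adj: dict, k: int):
    """Enumerate each connected k-node subset exactly once (ESU)."""
    order = {v: i for i, v in enumerate(sorted(adj))}
    for root in sorted(adj, key=order.get):
        ext = {u for u in adj[root] if order[u] > order[root]}
        yield from _esu_extend([root], ext, {root} | adj[root], root, adj, order, k)


def _esu_extend(sub, extension, neighborhood, root, adj, order, k):
    if len(sub) == k:
        yield tuple(sub)
        return
    ext = set(extension)
    while ext:
        w = ext.pop()
        excl = {u for u in adj[w] if order[u] > order[root] and u not in neighborhood}
        yield from _esu_extend(sub + [w], ext | excl, neighborhood | adj[w], root, adj, order, k)


def count_graphlet_orbits(net: nx.Graph) -> pd.DataFrame:
    """Count, per node, the 15 automorphism orbits of 2-4-node graphlets.

    Enumerates every connected induced subgraph on 2, 3 and 4 nodes of the
    simple-graph skeleton (ESU enumeration, each subset visited once) and
    classifies it by its degree sequence. Column ``o0`` equals node degree.
    """
    simple = nx.Graph(net)
    nodes = list(simple.nodes)
    counts = pd.DataFrame(0, index=nodes, columns=[f"o{i}" for i in range(N_ORBITS)])
    if not nodes:
        return counts
    adj = {v: set(simple.neighbors(v)) for v in nodes}
    arr = counts.to_numpy()
    pos = {v: i for i, v in enumerate(nodes)}
    for v in nodes:
        arr[pos[v], 0] = len(adj[v])
    for k, classify in ((3, _orbits_of_triple), (4, _orbits_of_quad)):
        for sub in _connected_subsets(adj, k):
            deg_in = {v: sum(1 for u in sub if u != v and u in adj[v]) for v in sub}
            for v, orb in classify(deg_in).items():
                arr[pos[v], orb] += 1
    counts.iloc[:, :] = arr
    return counts


def gcd_features(counts: pd.DataFrame, include_diagonal: bool = False) -> pd.Series:
    """Graphlet-correlation signature of one network.

    Restricts the orbit-count matrix to the 11 non-redundant orbits, appends
    an all-ones dummy row (so constant columns never yield undefined
    correlations), Spearman-correlates the columns with average ranks for
    ties, and returns the upper-triangle off-diagonal entries as a named
    55-vector (66 with ``include_diagonal``). An empty network gives zeros.
    """
    cols = [f"o{i}" for i in NON_REDUNDANT_ORBITS]
    names = [
        f"{a}~{b}"
        for i, a in enumerate(cols)
        for b in cols[i if include_diagonal else i + 1:]
    ]
    if counts.shape[0] == 0:
        return pd.Series(0.0, index=names)
    mat = counts[cols].to_numpy(dtype=float)
    mat = np.vstack([mat, np.ones(len(cols))])
    rho = spearmanr(mat, axis=0).statistic
    rho = np.atleast_2d(np.nan_to_num(rho, nan=0.0))
    vals = []
    for i in range(len(cols)):
        for j in range(i if include_diagonal else i + 1, len(cols)):
            vals.append(rho[i, j])
    return pd.Series(vals, index=names)


def gcd_profile(
    smdins: Mapping[str, nx.MultiGraph], include_diagonal: bool = False
) -> pd.DataFrame:
    """Samples x orbit-pair GCD-11 profile matrix."""
    rows = {
        s: gcd_features(count_graphlet_orbits(g), include_diagonal)
        for s, g in smdins.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")
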