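"""Mass-difference network (MDiN) construction and per-sample subgraphs.

An MDiN is an undirected multigraph on the detected features: nodes carry
neutral masses, and an edge labelled with an MDB connects two features
whenever the absolute difference of their masses matches that MDB's delta
mass within a relative (ppm) tolerance. The per-sample network (sMDiN) is
the induced subgraph on the features detected in one sample, with isolated
nodes removed — edge existence depends only on the two endpoint masses, so
subgraphing equals building from scratch.

The tolerance window for a pair (u, v) is ``ppm * max(m_u, m_v) * 1e-6``:
measurement error scales with the measured masses, and the larger mass is
the conservative reference. The alternative ``sum`` reference is exposed via
``tol_ref``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .datamodel import AlignedMatrix
from .mdbs import MDB

__all__ = [
    "build_mdin",
    "build_mdin_from_masses",
    "derive_smdin",
    "derive_all_smdins",
    "summarize",
    "NetworkSummary",
    "export_network",
    "import_network",
]


def _pair_tolerance(m_small: np.ndarray, m_large: np.ndarray, ppm: float, tol_ref: str) -> np.ndarray:
    if tol_ref == "max":
        return ppm * 1e-6 * m_large
    if tol_ref == "sum":
        return ppm * 1e-6 * (m_small + m_large)
    raise ValueError(f"unknown tol_ref {tol_ref!r} (use 'max' or 'sum')")


def build_mdin_from_masses(
    masses: Mapping[str, float],
    mdbs: Sequence[MDB],
    ppm: float = 1.0,
    tol_ref: str = "max",
) -> nx.MultiGraph:
    """Build an MDiN from {feature_id: neutral_mass}.

    Equivalent to the brute-force scan over all unordered pairs and all
    MDBs, implemented with a sort-and-window search per MDB. Edges carry
    ``mdb`` (label) and ``residual_ppm`` (signed residual of the matched
    difference, in ppm of the larger mass). Parallel edges are allowed only
    with distinct MDB labels; ties create one edge per matching MDB.
    """
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    ids = list(masses)
    mass = np.asarray([masses[i] for i in ids], dtype=float)
    g = nx.MultiGraph()
    for i, fid in enumerate(ids):
        g.add_node(fid, mass=float(mass[i]))
    if len(ids) < 2:
        return g
    order = np.argsort(mass, kind="stable")
    ms = mass[order]
    for mdb in mdbs:
        delta = mdb.delta_mass
        # For sorted masses, the partner of ms[i] is near ms[i] + delta.
        # Window bounds use the loosest possible tolerance at each target.
        tol_hi = _pair_tolerance(ms, ms + delta, ppm, tol_ref) * (1.0 + 1e-9)
        lo = np.searchsorted(ms, ms + delta - tol_hi, side="left")
        hi = np.searchsorted(ms, ms + delta + tol_hi, side="right")
        for i in range(len(ms)):
            for j in range(lo[i], hi[i]):
                if j == i:
                    continue
                m_small, m_large = ms[i], ms[j]
                if m_large < m_small:
                    m_small, m_large = m_large, m_small
                tol = _pair_tolerance(m_small, m_large, ppm, tol_ref)
                resid = (m_large - m_small) - delta
                if abs(resid) <= tol:
                    u, v = ids[order[i]], ids[order[j]]
                    if not g.has_edge(u, v, key=mdb.label):
                        g.add_edge(
                            u, v, key=mdb.label, mdb=mdb.label,
                            residual_ppm=float(resid / m_large * 1e6),
                        )
    return g


def build_mdin(
    m: AlignedMatrix,
    mdbs: Sequence[MDB],
    ppm: float = 1.0,
    tol_ref: str = "max",
) -> nx.MultiGraph:
    """Build the dataset-level MDiN from an aligned matrix's features."""
    return build_mdin_from_masses(dict(m.neutral_mass), mdbs, ppm=ppm, tol_ref=tol_ref)


def derive_smdin(mdin: nx.MultiGraph, present_features: Iterable[str]) -> nx.MultiGraph:
    """Induced subgraph on the sample's features, isolated nodes removed."""
    present = set(present_features)
    unknown = present - set(mdin.nodes)
    if unknown:
        raise ValueError(f"features not in the MDiN: {sorted(unknown)[:5]}...")
    sub = mdin.subgraph(present).copy()
    sub.remove_nodes_from([n for n, d in sub.degree() if d == 0])
    return sub


def derive_all_smdins(mdin: nx.MultiGraph, m: AlignedMatrix) -> dict[str, nx.MultiGraph]:
    """One sMDiN per sample, keyed by sample id."""
    return {s: derive_smdin(mdin, m.features_of_sample(s)) for s in m.sample_ids}


@dataclass(frozen=True)
class NetworkSummary:
    """Headline structure of an MDiN (diameter/radius on largest component)."""

    n_nodes: int
    n_edges: int
    largest_component_size: int
    pct_connected_nodes: float
    diameter: int
    radius: int


def summarize(net: nx.MultiGraph, total_feature_count: int | None = None) -> NetworkSummary:
    """Node/edge counts, largest component, % connected nodes, diameter, radius.

    ``pct_connected_nodes`` is computed against ``total_feature_count`` (the
    pre-exclusion feature universe) when given, else against the node count.
    """
    n_nodes = net.number_of_nodes()
    n_edges = net.number_of_edges()
    connected = sum(1 for _, d in net.degree() if d >= 1)
    universe = total_feature_count if total_feature_count else n_nodes
    pct = 100.0 * connected / universe if universe else 0.0
    if n_nodes == 0 or n_edges == 0:
        return NetworkSummary(n_nodes, n_edges, 1 if n_nodes else 0, pct, 0, 0)
    comp = max(nx.connected_components(net), key=len)
    simple = nx.Graph(net.subgraph(comp))
    ecc = nx.eccentricity(simple)
    return NetworkSummary(
        n_nodes, n_edges, len(comp), pct,
        max(ecc.values()), min(ecc.values()),
    )


def export_network(net: nx.MultiGraph, path: str | Path, format: str | None = None) -> None:
    """Write GraphML (node mass, edge mdb/residual) or a 4-column edge TSV.

    The edge TSV has columns u, v, mdb, residual_ppm plus ``# node`` comment
    lines carrying isolated-node-safe node/mass records, so a round-trip
    reproduces node and edge sets exactly.
    """
    path = Path(path)
    fmt = format or ("graphml" if path.suffix.lower() == ".graphml" else "edge-tsv")
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "edge-tsv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["u", "v", "mdb", "residual_ppm"])
            for n, data in net.nodes(data=True):
                mass = data.get("mass")
                fh.write(f"# node\t{n}\t{'' if mass is None else repr(float(mass))}\n")
            for u, v, data in net.edges(data=True):
                writer.writerow([u, v, data["mdb"], f"{data['residual_ppm']:.6f}"])
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'graphml' or 'edge-tsv')")


def import_network(path: str | Path, format: str | None = None) -> nx.MultiGraph:
    """Inverse of :func:`export_network`."""
    path = Path(path)
    fmt = format or ("graphml" if path.suffix.lower() == ".graphml" else "edge-tsv")
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        return nx.MultiGraph(g)
    if fmt != "edge-tsv":
        raise ValueError(f"unknown format {fmt!r}")
    g = nx.MultiGraph()
    with path.open() as fh:
        header = fh.readline()
        if header and not header.startswith("u\t"):
            raise ValueError(f"{path}: not an edge TSV")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# node\t"):
                parts = line.split("\t")
                node, mass = parts[1], parts[2] if len(parts) > 2 else ""
                if mass:
                    g.add_node(node, mass=float(mass))
                else:
                    g.add_node(node)
            else:
                u, v, mdb, resid = line.split("\t")
                g.add_edge(u, v, key=mdb, mdb=mdb, residual_ppm=float(resid))
    return g
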