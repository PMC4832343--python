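"""Occupancy-filtered, correlation-weighted residue interaction networks.

Nodes are residues; an edge joins two residues that are not covalently
linked (chain-adjacent) but keep heavy atoms within the contact cutoff
(4.5 Å) for more than the occupancy threshold (75%) of frames.  Each edge
carries its occupancy, the fluctuation correlation C_ij of its endpoints,
and the information-transfer path length

    w_ij = -log|C_ij|,

so highly correlated contacts are "short".  On this weighted graph the
module computes all-pairs shortest paths (Floyd-Warshall with deterministic
tie-breaking), edge betweenness (integer single-path counts by default, or
fractional all-shortest-paths in the Brandes sense), correlation-weighted
degrees, topology summaries, and source-target shortest pathways.

All algorithms are implemented here; graph libraries are used only as
independent oracles in the test suite.  Node order is canonicalized by
sorting labels, so results are invariant to insertion order.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .trajectory import NodeMap, Trajectory, chain_adjacent_pairs

__all__ = [
    "ResidueNetwork",
    "PathResult",
    "SitePathStats",
    "NetworkSummary",
    "contact_edges",
    "build_network",
    "weighted_degree",
    "top_degree_table",
    "site_degree_sum",
    "all_pairs_shortest_paths",
    "reconstruct_path",
    "edge_betweenness",
    "site_path_statistics",
    "network_summary",
    "shortest_pathway",
    "write_edge_list",
    "write_graphml",
]

CONTACT_CUTOFF = 4.5        # Å, heavy-atom minimum distance
OCCUPANCY_THRESHOLD = 0.75  # strict: occupancy must exceed this


# ---------------------------------------------------------------------------
# construction


def contact_edges(traj: Trajectory, cutoff: float = CONTACT_CUTOFF,
                  occupancy: float = OCCUPANCY_THRESHOLD) -> pd.DataFrame:
    """Contact occupancies and the resulting edge set.

    A pair (i, j) becomes an edge iff it is not chain-adjacent and the
    fraction of frames with minimum heavy-atom distance < ``cutoff`` is
    strictly greater than ``occupancy``.  Returns a DataFrame with columns
    ``node_i, node_j, occupancy`` (i < j), edges only.
    """
    atoms = traj.topology.atoms
    heavy = atoms.index[atoms["heavy"]].to_numpy()
    if len(heavy) == 0:
        raise ValueError("trajectory has no heavy atoms")
    res_of_heavy = atoms.loc[heavy, "residue_index"].to_numpy()
    n_res = traj.topology.n_residues
    counts_per_res = np.bincount(res_of_heavy, minlength=n_res)
    if (counts_per_res == 0).any():
        bad = np.flatnonzero(counts_per_res == 0)
        raise ValueError(f"residues without heavy atoms: {bad.tolist()}")
    # heavy atoms must be grouped by residue for reduceat
    order = np.argsort(res_of_heavy, kind="stable")
    heavy = heavy[order]
    starts = np.searchsorted(res_of_heavy[order], np.arange(n_res))

    counts = np.zeros((n_res, n_res), dtype=np.int64)
    xyz = traj.coords[:, heavy, :]
    for f in range(traj.n_frames):
        diff = xyz[f][:, None, :] - xyz[f][None, :, :]
        D = np.sqrt(np.einsum("ijd,ijd->ij", diff, diff))
        Dres = np.minimum.reduceat(np.minimum.reduceat(D, starts, axis=0),
                                   starts, axis=1)
        counts += Dres < cutoff
    occ = counts / traj.n_frames

    excluded = chain_adjacent_pairs(traj.topology)
    rows = []
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if (i, j) in excluded:
                continue
            if occ[i, j] > occupancy:
                rows.append(dict(node_i=i, node_j=j, occupancy=float(occ[i, j])))
    return pd.DataFrame(rows, columns=["node_i", "node_j", "occupancy"])


@dataclass
class ResidueNetwork:
    """Residue graph with occupancy, correlation and path-length edge data.

    Node order is canonical (sorted by label); ``edges`` uses these internal
    indices with ``node_i < node_j``.
    """

    labels: list
    chains: list
    edges: pd.DataFrame      # node_i, node_j, occupancy, correlation, length
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.argsort(self.labels, kind="stable")
        if not np.array_equal(order, np.arange(len(self.labels))):
            remap = np.empty(len(order), int)
            remap[order] = np.arange(len(order))
            self.labels = [self.labels[k] for k in order]
            self.chains = [self.chains[k] for k in order]
            e = self.edges.copy()
            i = remap[e["node_i"].to_numpy()]
            j = remap[e["node_j"].to_numpy()]
            e["node_i"] = np.minimum(i, j)
            e["node_j"] = np.maximum(i, j)
            self.edges = e
        self.edges = (
            self.edges.sort_values(["node_i", "node_j"])
            .reset_index(drop=True)
        )
        if (self.edges["node_i"] == self.edges["node_j"]).any():
            raise ValueError("self-edges are not allowed")
        if (self.edges["length"] < 0).any():
            raise ValueError("negative edge lengths are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node) -> int:
        if isinstance(node, (int, np.integer)):
            return int(node)
        try:
            return self.labels.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def adjacency(self) -> list:
        """Adjacency list of (neighbor, length, edge_row) triples."""
        adj = [[] for _ in range(self.n_nodes)]
        for row, (i, j, w) in enumerate(
            zip(self.edges["node_i"], self.edges["node_j"], self.edges["length"])
        ):
            adj[i].append((int(j), float(w), row))
            adj[j].append((int(i), float(w), row))
        return adj

    def degree_raw(self) -> np.ndarray:
        k = np.zeros(self.n_nodes, int)
        np.add.at(k, self.edges["node_i"].to_numpy(), 1)
        np.add.at(k, self.edges["node_j"].to_numpy(), 1)
        return k

    def replace_edges(self, edges: pd.DataFrame) -> "ResidueNetwork":
        return ResidueNetwork(labels=list(self.labels), chains=list(self.chains),
                              edges=edges.copy(), params=dict(self.params))


def build_network(C: CorrelationMatrix, edges: pd.DataFrame,
                  chains=None, params=None) -> ResidueNetwork:
    """Attach correlations and path lengths to an occupancy edge set.

    Edges whose correlation is undefined (NaN) or exactly zero have no
    finite path length and are dropped with a warning.
    """
    n = C.n_nodes
    if len(edges) and (edges[["node_i", "node_j"]].to_numpy().max() >= n):
        raise ValueError("edge endpoint outside the correlation matrix")
    if chains is None:
        chains = ["A"] * n
    rows, dropped = [], []
    for _, e in edges.iterrows():
        i, j = int(e["node_i"]), int(e["node_j"])
        c = C.value(i, j)
        if np.isnan(c) or c == 0.0:
            dropped.append((C.labels[i], C.labels[j]))
            continue
        rows.append(dict(node_i=i, node_j=j,
                         occupancy=float(e.get("occupancy", 1.0)),
                         correlation=float(c),
                         length=float(-np.log(abs(c)))))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} edges with undefined/zero correlation: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            RuntimeWarning, stacklevel=2,
        )
    frame = pd.DataFrame(
        rows, columns=["node_i", "node_j", "occupancy", "correlation", "length"]
    )
    return ResidueNetwork(labels=list(C.labels), chains=list(chains),
                          edges=frame, params=dict(params or {}))


# ---------------------------------------------------------------------------
# degrees


def weighted_degree(net: ResidueNetwork, node=None):
    """Sum of |C_ij| over incident edges; all nodes if ``node`` is None."""
    deg = np.zeros(net.n_nodes)
    w = np.abs(net.edges["correlation"].to_numpy())
    np.add.at(deg, net.edges["node_i"].to_numpy(), w)
    np.add.at(deg, net.edges["node_j"].to_numpy(), w)
    if node is None:
        return deg
    return float(deg[net.index_of(node)])


def top_degree_table(net: ResidueNetwork, k: int = 10) -> pd.DataFrame:
    """Top-k nodes by correlation-weighted degree."""
    deg = weighted_degree(net)
    order = np.argsort(-deg, kind="stable")[:k]
    return pd.DataFrame(dict(
        node=[net.labels[i] for i in order],
        chain=[net.chains[i] for i in order],
        weighted_degree=deg[order],
        raw_degree=net.degree_raw()[order],
    ))


def site_degree_sum(net: ResidueNetwork, sites) -> float:
    """Sum of weighted degrees over a designated site set."""
    return float(sum(weighted_degree(net, s) for s in sites))


# ---------------------------------------------------------------------------
# shortest paths


def all_pairs_shortest_paths(net: ResidueNetwork):
    """Floyd-Warshall distances and next-hop matrix.

    Unreachable pairs have distance +inf.  Ties are broken deterministically:
    only strict improvements replace a path, and intermediates are scanned in
    ascending canonical node order, so the lowest intermediate index wins.
    """
    n = net.n_nodes
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nxt = np.full((n, n), -1, dtype=np.int64)
    np.fill_diagonal(nxt, np.arange(n))
    for i, j, w in zip(net.edges["node_i"], net.edges["node_j"],
                       net.edges["length"]):
        i, j, w = int(i), int(j), float(w)
        if w < dist[i, j]:
            dist[i, j] = dist[j, i] = w
            nxt[i, j] = j
            nxt[j, i] = i
    for k in range(n):
        alt = dist[:, k, None] + dist[None, k, :]
        better = alt < dist
        if better.any():
            dist = np.where(better, alt, dist)
            nxt = np.where(better, nxt[:, k, None], nxt)
    return dist, nxt


def reconstruct_path(nxt: np.ndarray, source: int, target: int):
    """Node index sequence of the stored shortest path, or None."""
    if nxt[source, target] < 0:
        return None
    path = [source]
    while path[-1] != target:
        path.append(int(nxt[path[-1], target]))
        if len(path) > len(nxt):
            raise RuntimeError("cycle in predecessor structure")
    return path


@dataclass
class PathResult:
    """A source-target shortest pathway in residue-label form."""

    nodes: list
    total_length: float
    edges: list                  # (label_i, label_j, length) per step
    found: bool = True

    def __str__(self) -> str:
        if not self.found:
            return "<no path>"
        return "-".join(str(n) for n in self.nodes)


def shortest_pathway(net: ResidueNetwork, source, target) -> PathResult:
    """Reconstructed Floyd-Warshall pathway between two nodes."""
    s, t = net.index_of(source), net.index_of(target)
    dist, nxt = all_pairs_shortest_paths(net)
    idx_path = reconstruct_path(nxt, s, t)
    if idx_path is None:
        return PathResult(nodes=[net.labels[s], net.labels[t]],
                          total_length=float("inf"), edges=[], found=False)
    lengths = {}
    for i, j, w in zip(net.edges["node_i"], net.edges["node_j"],
                       net.edges["length"]):
        lengths[(int(i), int(j))] = float(w)
    steps = []
    for a, b in zip(idx_path[:-1], idx_path[1:]):
        w = lengths[(min(a, b), max(a, b))]
        steps.append((net.labels[a], net.labels[b], w))
    return PathResult(
        nodes=[net.labels[i] for i in idx_path],
        total_length=float(dist[s, t]),
        edges=steps,
    )


# ---------------------------------------------------------------------------
# betweenness


def _betweenness_single(net: ResidueNetwork) -> np.ndarray:
    """Integer traversal counts: one deterministic path per node pair."""
    edge_row = {}
    for row, (i, j) in enumerate(zip(net.edges["node_i"], net.edges["node_j"])):
        edge_row[(int(i), int(j))] = row
    dist, nxt = all_pairs_shortest_paths(net)
    counts = np.zeros(net.n_edges)
    n = net.n_nodes
    for s in range(n):
        for t in range(s + 1, n):
            path = reconstruct_path(nxt, s, t)
            if path is None:
                continue
            for a, b in zip(path[:-1], path[1:]):
                counts[edge_row[(min(a, b), max(a, b))]] += 1
    return counts


def _betweenness_fractional(net: ResidueNetwork, rtol: float = 1e-9) -> np.ndarray:
    """Brandes-style edge betweenness: every shortest path counts
    fractionally, summed over unordered node pairs."""
    n = net.n_nodes
    adj = net.adjacency()
    bc = np.zeros(net.n_edges)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds = [[] for _ in range(n)]       # (pred, edge_row)
        dist[s] = 0.0
        sigma[s] = 1.0
        heap = [(0.0, s)]
        order = []
        done = np.zeros(n, bool)
        while heap:
            d, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u, w, row in adj[v]:
                nd = d + w
                tol = rtol * (1.0 + abs(nd))
                if nd < dist[u] - tol:
                    dist[u] = nd
                    sigma[u] = sigma[v]
                    preds[u] = [(v, row)]
                    heapq.heappush(heap, (nd, u))
                elif abs(nd - dist[u]) <= tol:
                    sigma[u] += sigma[v]
                    preds[u].append((v, row))
        delta = np.zeros(n)
        for w_node in reversed(order):
            for v, row in preds[w_node]:
                c = sigma[v] / sigma[w_node] * (1.0 + delta[w_node])
                bc[row] += c
                delta[v] += c
    return bc / 2.0


def edge_betweenness(net: ResidueNetwork, policy: str = "single") -> pd.DataFrame:
    """Per-edge shortest-path traversal counts.

    ``single`` (default) counts the one deterministic reconstructed path per
    node pair, yielding integers; ``fractional`` splits counts over all
    shortest paths.
    """
    if policy == "single":
        counts = _betweenness_single(net)
    elif policy == "fractional":
        counts = _betweenness_fractional(net)
    else:
        raise ValueError(f"unknown betweenness policy {policy!r}")
    out = net.edges.copy()
    out["betweenness"] = counts
    return out


# ---------------------------------------------------------------------------
# site statistics and summaries


@dataclass
class SitePathStats:
    """Inter-chain shortest-path traffic attributable to a site."""

    count: int
    edges: pd.DataFrame
    convention: str


def site_path_statistics(net: ResidueNetwork, site_nodes, partner_chain: str,
                         convention: str = "site_paths",
                         betweenness_policy: str = "single") -> SitePathStats:
    """Count the inter-chain edges that carry a site's information flow.

    The quantity "number of betweenness between a site and the partner
    chain" admits several readings; three are implemented and labeled, none
    asserted as canonical:

    * ``site_paths`` (default): inter-chain edges traversed by at least one
      shortest path from a site node to any partner-chain node; ``count`` is
      the number of such distinct edges.
    * ``incident``: inter-chain edges incident to a site node or one of its
      direct neighbors that lie on >= 1 global shortest path; ``count`` is
      their number.
    * ``betweenness_sum``: same edge set as ``site_paths`` but ``count`` is
      the integer sum of their global betweenness values.
    """
    sites = [net.index_of(s) for s in site_nodes]
    if not sites:
        raise KeyError("no site nodes given")
    partner = [i for i, c in enumerate(net.chains) if c == partner_chain]
    if not partner:
        raise KeyError(f"no nodes on partner chain {partner_chain!r}")
    inter = {
        row: (int(i), int(j))
        for row, (i, j) in enumerate(zip(net.edges["node_i"], net.edges["node_j"]))
        if net.chains[int(i)] != net.chains[int(j)]
    }
    bt = edge_betweenness(net, policy=betweenness_policy)

    if convention in ("site_paths", "betweenness_sum"):
        dist, nxt = all_pairs_shortest_paths(net)
        used = set()
        for s in sites:
            for t in partner:
                path = reconstruct_path(nxt, s, t)
                if path is None:
                    continue
                for a, b in zip(path[:-1], path[1:]):
                    pair = (min(a, b), max(a, b))
                    for row, ij in inter.items():
                        if ij == pair:
                            used.add(row)
        rows = bt.loc[sorted(used)]
        count = (int(rows["betweenness"].sum())
                 if convention == "betweenness_sum" else len(rows))
    elif convention == "incident":
        neigh = set(sites)
        for i, j in zip(net.edges["node_i"], net.edges["node_j"]):
            if int(i) in sites:
                neigh.add(int(j))
            if int(j) in sites:
                neigh.add(int(i))
        used = [row for row, (i, j) in inter.items()
                if (i in neigh or j in neigh)
                and bt.loc[row, "betweenness"] > 0]
        rows = bt.loc[sorted(used)]
        count = len(rows)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    rows = rows.assign(
        label_i=[net.labels[int(i)] for i in rows["node_i"]],
        label_j=[net.labels[int(j)] for j in rows["node_j"]],
    )
    return SitePathStats(count=count, edges=rows.reset_index(drop=True),
                         convention=convention)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    degree_centralization: float | None
    mean_degree: float
    n_high_degree: int
    degree_threshold: float
    degree_kind: str


def network_summary(net: ResidueNetwork, degree_threshold: float = 10.0,
                    degree_kind: str = "weighted") -> NetworkSummary:
    """Topology summary: clustering, centralization, degree statistics.

    ``n_high_degree`` counts nodes whose degree exceeds ``degree_threshold``;
    the degree is correlation-weighted by default (``degree_kind="raw"``
    switches to neighbor counts).  Degree centralization is
    sum(k_max - k_i) / ((n - 1)(n - 2)), undefined (None) for n < 3.
    """
    n = net.n_nodes
    k = net.degree_raw()
    neighbors = [set() for _ in range(n)]
    for i, j in zip(net.edges["node_i"], net.edges["node_j"]):
        neighbors[int(i)].add(int(j))
        neighbors[int(j)].add(int(i))
    cc = np.zeros(n)
    for v in range(n):
        nb = sorted(neighbors[v])
        if len(nb) < 2:
            continue
        links = sum(
            1 for a in range(len(nb)) for b in range(a + 1, len(nb))
            if nb[b] in neighbors[nb[a]]
        )
        cc[v] = 2.0 * links / (len(nb) * (len(nb) - 1))
    clustering = float(cc.mean()) if n else 0.0
    centralization = None
    if n >= 3:
        centralization = float((k.max() - k).sum() / ((n - 1) * (n - 2)))
    deg = weighted_degree(net) if degree_kind == "weighted" else k.astype(float)
    return NetworkSummary(
        n_nodes=n,
        n_edges=net.n_edges,
        clustering_coefficient=clustering,
        degree_centralization=centralization,
        mean_degree=float(k.mean()) if n else 0.0,
        n_high_degree=int((deg > degree_threshold).sum()),
        degree_threshold=degree_threshold,
        degree_kind=degree_kind,
    )


# ---------------------------------------------------------------------------
# export


def write_edge_list(net: ResidueNetwork, path: str,
                    betweenness_policy: str = "single") -> None:
    """TSV edge list: node_a, node_b, occupancy, correlation, length,
    betweenness."""
    bt = edge_betweenness(net, policy=betweenness_policy)
    out = pd.DataFrame(dict(
        node_a=[net.labels[int(i)] for i in bt["node_i"]],
        node_b=[net.labels[int(j)] for j in bt["node_j"]],
        occupancy=bt["occupancy"],
        correlation=bt["correlation"],
        length=bt["length"],
        betweenness=bt["betweenness"],
    ))
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_graphml(net: ResidueNetwork, path: str) -> None:
    """Minimal GraphML export with node chain and all edge attributes."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '<key id="chain" for="node" attr.name="chain" attr.type="string"/>',
        '<key id="occupancy" for="edge" attr.name="occupancy" attr.type="double"/>',
        '<key id="correlation" for="edge" attr.name="correlation" attr.type="double"/>',
        '<key id="length" for="edge" attr.name="length" attr.type="double"/>',
        '<graph edgedefault="undirected">',
    ]
    for lab, chain in zip(net.labels, net.chains):
        lines.append(f'<node id="{lab}"><data key="chain">{chain}</data></node>')
    for _, e in net.edges.iterrows():
        a = net.labels[int(e["node_i"])]
        b = net.labels[int(e["node_j"])]
        lines.append(
            f'<edge source="{a}" target="{b}">'
            f'<data key="occupancy">{e["occupancy"]:.6g}</data>'
            f'<data key="correlation">{e["correlation"]:.6g}</data>'
            f'<data key="length">{e["length"]:.6g}</data></edge>'
        )
    lines += ["</graph>", "</graphml>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
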