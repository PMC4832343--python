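"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fcnet.correlation import CorrelationMatrix
from fcnet.network import ResidueNetwork
from fcnet.trajectory import Topology, Trajectory


def net_from_edges(edges, n=None, chains=None):
    """Abstract weighted network: edges are (i, j, |C|) triples.

    Labels are zero-padded so canonical (sorted) order equals index order.
    """
    edges = [(int(i), int(j), float(c)) for i, j, c in edges]
    if n is None:
        n = 1 + max(max(i, j) for i, j, _ in edges)
    labels = [f"N{i:03d}" for i in range(n)]
    chains = list(chains) if chains is not None else ["A"] * n
    C = np.eye(n)
    occ = []
    rows = []
    for i, j, c in edges:
        C[i, j] = C[j, i] = c
        rows.append(dict(node_i=min(i, j), node_j=max(i, j),
                         occupancy=1.0, correlation=c,
                         length=float(-np.log(abs(c)))))
    frame = pd.DataFrame(rows, columns=["node_i", "node_j", "occupancy",
                                        "correlation", "length"])
    return ResidueNetwork(labels=labels, chains=chains, edges=frame)


def unit_length_net(edge_list, n=None, chains=None):
    """Unit-length edges (|C| = 1/e, so w = 1) for hop-count graph tests."""
    c = float(np.exp(-1.0))
    return net_from_edges([(i, j, c) for i, j in edge_list], n=n, chains=chains)


def enumerate_shortest(net, s, t):
    """Brute-force shortest path by DFS over all simple paths.

    Returns (distance, set of optimal node tuples); (inf, empty) when
    unreachable.  Independent of the Floyd-Warshall implementation.
    """
    adj = {}
    for i, j, w in zip(net.edges["node_i"], net.edges["node_j"],
                       net.edges["length"]):
        adj.setdefault(int(i), []).append((int(j), float(w)))
        adj.setdefault(int(j), []).append((int(i), float(w)))
    best = [np.inf]
    optimal = []

    def dfs(v, dist, path):
        if dist > best[0] + 1e-12:
            return
        if v == t:
            if dist < best[0] - 1e-12:
                best[0] = dist
                optimal.clear()
            optimal.append(tuple(path))
            return
        for u, w in adj.get(v, []):
            if u not in path:
                path.append(u)
                dfs(u, dist + w, path)
                path.pop()

    dfs(s, 0.0, [s])
    return best[0], set(optimal)


def brute_force_max_q(edge_list, n):
    """Global max modularity by exhaustive search over all partitions."""

    def all_partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in all_partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [part[k] + [first]] + part[k + 1:]
            yield part + [[first]]

    m = len(edge_list)
    deg = np.zeros(n)
    for i, j in edge_list:
        deg[i] += 1
        deg[j] += 1
    best = -1.0
    for part in all_partitions(list(range(n))):
        lab = np.empty(n, int)
        for c, grp in enumerate(part):
            lab[grp] = c
        e_in = sum(1 for i, j in edge_list if lab[i] == lab[j]) / m
        a = np.bincount(lab, weights=deg) / (2 * m)
        best = max(best, e_in - float(a @ a))
    return best


def toy_trajectory(atom_rows, frames):
    """Build a trajectory from explicit atom metadata and per-frame coords.

    ``atom_rows`` is a list of dicts (atom_name, element, mass,
    residue_index, residue_number, residue_name, chain_id, heavy);
    ``frames`` an (F, A, 3) array.
    """
    return Trajectory(coords=np.asarray(frames, float),
                      topology=Topology(pd.DataFrame(atom_rows)))


def simple_residue(ridx, number, name, chain, atoms):
    """Atom rows for one residue: atoms = [(atom_name, element, mass), ...]."""
    return [dict(atom_name=a, element=e, mass=m, residue_index=ridx,
                 residue_number=number, residue_name=name, chain_id=chain,
                 heavy=e != "H")
            for a, e, m in atoms]


def correlation_from_matrix(C, labels=None):
    C = np.asarray(C, float)
    n = C.shape[0]
    labels = labels or [f"N{i:03d}" for i in range(n)]
    return CorrelationMatrix(C=C, cov=C.copy(), labels=list(labels), n_frames=0)


@pytest.fixture(scope="session")
def barbell_k5():
    """Two K5 cliques joined by a single bridge edge (0..4 | 5..9)."""
    edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
    edges += [(4, 5)]
    return edges


def random_weighted_graph(rng, n, p=0.4):
    """Connected-ish ER graph with distinct random |C| weights."""
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((i, j, float(rng.uniform(0.2, 0.95))))
    if not edges:
        edges = [(0, 1, 0.5)]
    return edges
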