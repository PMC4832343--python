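"""Girvan-Newman community decomposition and partition selection.

The decomposition repeatedly computes edge betweenness on the remaining
graph, removes the highest-betweenness edge (ties broken lexicographically
on node labels so runs are bit-reproducible), and records the component
structure whenever a removal splits a component.  Backtracking the removal
sequence yields a hierarchical merge tree (dendrogram).

Betweenness during removal uses the same -log|C| edge lengths as the rest of
the network analysis — communities reflect correlated information flow, not
mere hop counts — with the all-shortest-paths fractional policy by default.

Because "inspecting the main branches" of a dendrogram by eye is not an
algorithm, partition selection is made explicit: maximize Newman-Girvan
modularity Q over the recorded component structures (default), or return the
first structure reaching a fixed number of communities.  Q is evaluated on
the original unweighted edge set.  Note the dendrogram only contains nested
partitions, so the max-Q cut coincides with the global modularity optimum on
clearly modular graphs but not for arbitrary graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ResidueNetwork, _betweenness_fractional, _betweenness_single

__all__ = [
    "GirvanNewmanResult",
    "CommunityPartition",
    "girvan_newman",
    "modularity",
    "select_partition",
    "interface_communities",
    "dendrogram_newick",
]


@dataclass
class GirvanNewmanResult:
    """Full edge-removal record of a Girvan-Newman run."""

    labels: list
    removal_order: list          # (label_i, label_j, betweenness at removal)
    structures: list             # (n_components, labels array) per split
    dendrogram: dict             # frozenset(component) -> tuple of children
    root_components: list        # components of the original graph

    @property
    def n_removals(self) -> int:
        return len(self.removal_order)


def _components(n: int, adj_sets) -> list:
    seen = np.zeros(n, bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in adj_sets[v]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(u)
        comps.append(sorted(comp))
    return comps


def _labels_from_components(n: int, comps) -> np.ndarray:
    lab = np.empty(n, int)
    for c, comp in enumerate(sorted(comps, key=lambda c: c[0])):
        lab[comp] = c
    return lab


def girvan_newman(net: ResidueNetwork,
                  betweenness_policy: str = "fractional") -> GirvanNewmanResult:
    """Run the full edge-removal decomposition until no edge is left.

    Records the betweenness of every edge at its removal, every component
    split, and the merge dendrogram obtained by backtracking.
    """
    if net.n_edges == 0:
        raise ValueError("Girvan-Newman needs at least one edge")
    n = net.n_nodes
    work = net
    adj_sets = [set() for _ in range(n)]
    for i, j in zip(net.edges["node_i"], net.edges["node_j"]):
        adj_sets[int(i)].add(int(j))
        adj_sets[int(j)].add(int(i))
    comps = _components(n, adj_sets)
    root_components = [list(c) for c in comps]
    structures = [(len(comps), _labels_from_components(n, comps))]
    splits = []                  # (parent frozenset, children frozensets)
    removal_order = []

    betw = (_betweenness_fractional if betweenness_policy == "fractional"
            else _betweenness_single)
    while work.n_edges > 0:
        bc = betw(work)
        ei = work.edges["node_i"].to_numpy(int)
        ej = work.edges["node_j"].to_numpy(int)
        # deterministic max: highest betweenness, lexicographic labels on ties
        best_row, best_key = None, None
        for row in range(work.n_edges):
            key = (-bc[row], net.labels[ei[row]], net.labels[ej[row]])
            if best_key is None or key < best_key:
                best_row, best_key = row, key
        i, j = int(ei[best_row]), int(ej[best_row])
        removal_order.append((net.labels[i], net.labels[j], float(bc[best_row])))
        work = work.replace_edges(work.edges.drop(work.edges.index[best_row]))
        adj_sets[i].discard(j)
        adj_sets[j].discard(i)
        new_comps = _components(n, adj_sets)
        if len(new_comps) > len(comps):
            old_sets = {frozenset(c) for c in comps}
            parent = frozenset(comps[[k for k, c in enumerate(comps)
                                      if i in c][0]])
            children = [frozenset(c) for c in new_comps
                        if frozenset(c) not in old_sets]
            splits.append((parent, tuple(children)))
            structures.append((len(new_comps),
                               _labels_from_components(n, new_comps)))
            comps = new_comps

    dendrogram = {parent: children for parent, children in splits}
    return GirvanNewmanResult(
        labels=list(net.labels),
        removal_order=removal_order,
        structures=structures,
        dendrogram=dendrogram,
        root_components=root_components,
    )


def modularity(net: ResidueNetwork, labels) -> float:
    """Newman-Girvan Q = sum_c (e_cc - a_c^2) on the unweighted edge set."""
    lab = np.asarray(labels, int)
    if lab.shape != (net.n_nodes,):
        raise ValueError("partition must label every node exactly once")
    m = net.n_edges
    if m == 0:
        return 0.0
    ei = net.edges["node_i"].to_numpy(int)
    ej = net.edges["node_j"].to_numpy(int)
    e_in = float(np.sum(lab[ei] == lab[ej])) / m
    deg = np.zeros(net.n_nodes)
    np.add.at(deg, ei, 1.0)
    np.add.at(deg, ej, 1.0)
    a = np.bincount(lab, weights=deg) / (2.0 * m)
    return e_in - float(np.sum(a * a))


@dataclass
class CommunityPartition:
    """A selected cut of the dendrogram."""

    labels: np.ndarray           # node -> community id, contiguous from 0
    n_communities: int
    Q: float
    criterion: str
    node_labels: list = field(default_factory=list)

    def table(self, chains=None) -> pd.DataFrame:
        data = dict(node=self.node_labels, community=self.labels)
        if chains is not None:
            data["chain"] = chains
        return pd.DataFrame(data)

    def community_of(self, node_label) -> int:
        return int(self.labels[self.node_labels.index(node_label)])


def select_partition(gn: GirvanNewmanResult, net: ResidueNetwork,
                     criterion: str = "max_modularity",
                     k: int | None = None) -> CommunityPartition:
    """Choose a partition from the recorded component structures.

    ``max_modularity`` returns the structure maximizing Q on the original
    edge set (earliest structure wins ties, favoring fewer communities);
    ``fixed_k`` returns the first structure with at least ``k`` components
    (a single removal can split a component into several, so exactly-k
    structures may be skipped).
    """
    if criterion == "max_modularity":
        best = None
        for n_comm, lab in gn.structures:
            q = modularity(net, lab)
            if best is None or q > best[0] + 1e-12:
                best = (q, n_comm, lab)
        q, n_comm, lab = best
    elif criterion == "fixed_k":
        if k is None:
            raise ValueError("fixed_k criterion requires k")
        if k > net.n_nodes:
            raise ValueError(f"k = {k} exceeds node count {net.n_nodes}")
        for n_comm, lab in gn.structures:
            if n_comm >= k:
                q = modularity(net, lab)
                break
        else:
            raise ValueError(f"no recorded structure reaches k = {k}")
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return CommunityPartition(
        labels=np.asarray(lab, int),
        n_communities=int(n_comm),
        Q=float(q),
        criterion=criterion,
        node_labels=list(gn.labels),
    )


def interface_communities(partition: CommunityPartition, group_a, group_b):
    """Number of distinct communities containing each interface group.

    ``group_a`` / ``group_b`` are node-label collections (e.g. the two sides
    of an inter-chain interface from the interactions module).  Returns a
    dict with per-group community counts and a membership table.  Empty
    groups are flagged with a count of 0 rather than an error.
    """
    known = set(partition.node_labels)
    rows = []
    counts = {}
    for name, group in (("a", list(group_a)), ("b", list(group_b))):
        missing = [g for g in group if g not in known]
        if missing:
            raise KeyError(f"interface nodes not in partition: {missing}")
        comms = set()
        for g in group:
            c = partition.community_of(g)
            comms.add(c)
            rows.append(dict(group=name, node=g, community=c))
        counts[name] = len(comms)
    return dict(
        count_a=counts["a"],
        count_b=counts["b"],
        empty_a=len(list(group_a)) == 0,
        empty_b=len(list(group_b)) == 0,
        table=pd.DataFrame(rows, columns=["group", "node", "community"]),
    )


def dendrogram_newick(gn: GirvanNewmanResult) -> str:
    """Nested-parentheses (Newick-like) rendering of the merge tree."""

    def render(comp: frozenset) -> str:
        children = gn.dendrogram.get(comp)
        if not children:
            if len(comp) == 1:
                return str(gn.labels[next(iter(comp))])
            inner = ",".join(str(gn.labels[i]) for i in sorted(comp))
            return f"({inner})"
        return "(" + ",".join(render(c) for c in children) + ")"

    roots = [frozenset(c) for c in gn.root_components]
    if len(roots) == 1:
        return render(roots[0]) + ";"
    return "(" + ",".join(render(r) for r in roots) + ");"
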