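"""In-silico network perturbations.

A modification site's role in information transfer can be probed without new
simulation: multiply |C| on every edge incident to the chosen node(s) by a
factor in [0, 1) — 0 removes the edges outright — recompute the derived
-log|C| path lengths, and re-run the community, site-statistics and pathway
analyses on the perturbed graph.  Weakening can only lengthen shortest
paths; removal of a sole bridge visibly blocks the flow between the two
designated sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .communities import CommunityPartition, girvan_newman, select_partition
from .network import PathResult, ResidueNetwork, shortest_pathway

__all__ = ["PerturbationReport", "weaken_node_edges", "perturbation_report"]


def weaken_node_edges(net: ResidueNetwork, nodes, factor: float) -> ResidueNetwork:
    """Scale |C| of all edges incident to ``nodes`` by ``factor``.

    ``factor`` must satisfy 0 <= factor < 1 (1 would be a silent no-op and is
    rejected); factor 0 removes the edges, isolating the node.  Returns a new
    network; the input is unchanged.
    """
    if not (0.0 <= factor < 1.0):
        raise ValueError(f"factor must be in [0, 1); got {factor}")
    idx = {net.index_of(v) for v in nodes}
    if not idx:
        raise KeyError("no nodes given")
    edges = net.edges.copy()
    hit = (edges["node_i"].isin(idx) | edges["node_j"].isin(idx)).to_numpy()
    if factor == 0.0:
        edges = edges.loc[~hit]
    else:
        corr = edges["correlation"].to_numpy(float).copy()
        corr[hit] *= factor
        edges["correlation"] = corr
        edges["length"] = -np.log(np.abs(corr))
    return net.replace_edges(edges.reset_index(drop=True))


@dataclass
class PerturbationReport:
    """Baseline vs perturbed comparison after weakening a site's edges."""

    nodes: list
    factor: float
    baseline_communities: int
    perturbed_communities: int
    ari: float
    baseline_path: PathResult | None
    perturbed_path: PathResult | None
    baseline_Q: float
    perturbed_Q: float

    @property
    def path_blocked(self) -> bool:
        return (self.baseline_path is not None
                and self.baseline_path.found
                and not self.perturbed_path.found)

    @property
    def path_length_change(self) -> float:
        if self.baseline_path is None or not self.baseline_path.found:
            return float("nan")
        return self.perturbed_path.total_length - self.baseline_path.total_length


def perturbation_report(net: ResidueNetwork, nodes, factor: float = 0.0,
                        baseline_partition: CommunityPartition | None = None,
                        sites=None,
                        criterion: str = "max_modularity") -> PerturbationReport:
    """Weaken a site's edges and re-run the downstream analyses.

    Reports community counts and modularity before/after, the adjusted Rand
    index between the two partitions, and the shortest pathway between the
    two designated ``sites`` (a pair of node labels) before/after.
    """
    from sklearn.metrics import adjusted_rand_score

    if baseline_partition is None:
        baseline_partition = select_partition(girvan_newman(net), net,
                                              criterion=criterion)
    perturbed = weaken_node_edges(net, nodes, factor)
    if perturbed.n_edges > 0:
        perturbed_partition = select_partition(girvan_newman(perturbed),
                                               perturbed, criterion=criterion)
    else:
        perturbed_partition = CommunityPartition(
            labels=np.arange(net.n_nodes), n_communities=net.n_nodes,
            Q=0.0, criterion=criterion, node_labels=list(net.labels),
        )
    ari = float(adjusted_rand_score(baseline_partition.labels,
                                    perturbed_partition.labels))
    base_path = pert_path = None
    if sites is not None:
        a, b = sites
        base_path = shortest_pathway(net, a, b)
        pert_path = shortest_pathway(perturbed, a, b)
    return PerturbationReport(
        nodes=list(nodes),
        factor=factor,
        baseline_communities=baseline_partition.n_communities,
        perturbed_communities=perturbed_partition.n_communities,
        ari=ari,
        baseline_path=base_path,
        perturbed_path=pert_path,
        baseline_Q=baseline_partition.Q,
        perturbed_Q=perturbed_partition.Q,
    )
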