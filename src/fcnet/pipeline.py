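"""End-to-end pipeline: trajectory -> correlation -> network -> communities
-> perturbation -> pathway -> JSON report.

The configuration is a flat key-value mapping (YAML on disk); every numeric
default is the analysis convention used throughout the package (4.5 Å
contact cutoff, 75% occupancy, 6.5/11/3.5 Å interaction cutoffs, 40%
population filter, 8 landscape bins).  All distances are Å, times ps.
Reports embed the full parameter set and package version, and runs are
deterministic given the same config and seed.
"""

from __future__ import annotations

import json
import logging

import numpy as np

from . import __version__
from .communities import girvan_newman, interface_communities, select_partition
from .correlation import correlation_matrix
from .fluctuation import mean_rmsf, rmsf, superpose_to_mean
from .interactions import (
    ResidueClasses,
    assign_electrostatic,
    assign_hbond,
    assign_hydrophobic,
    interaction_populations,
    interface_residues,
)
from .network import (
    build_network,
    contact_edges,
    network_summary,
    shortest_pathway,
    site_degree_sum,
    top_degree_table,
    weighted_degree,
)
from .perturbation import perturbation_report
from .synthetic import make_demo_complex, sample_trajectory
from .trajectory import frame_window, load_trajectory, make_node_map

__all__ = ["DEFAULT_CONFIG", "PipelineError", "run_pipeline"]

log = logging.getLogger("fcnet.pipeline")

DEFAULT_CONFIG = dict(
    mode="synthetic",            # synthetic | files
    seed=0,
    n_frames=4000,
    topology=None,               # files mode
    coordinates=(),              # files mode
    window_start=0.0,
    window_end=1.0,
    node_rule="alpha_carbon",
    contact_cutoff=4.5,
    occupancy_threshold=0.75,
    hydrophobic_cutoff=6.5,
    electrostatic_cutoff=11.0,
    hbond_cutoff=3.5,
    min_population=0.40,
    landscape_bins=8,
    degree_threshold=10.0,
    community_criterion="max_modularity",
    site_a=None,                 # node labels; synthetic mode fills them in
    site_b=None,
    hydrophobic_extra=("ALY",),  # acetyl-lysine packs hydrophobically
    perturb_factor=None,         # set to run the perturbation stage
    perturb_nodes=(),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: dict | None = None) -> dict:
    """Execute all stages and return the JSON-serializable report bundle."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    report = dict(version=__version__, parameters={
        k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()})

    # --- input stage
    @_stage("input")
    def _input():
        if cfg["mode"] == "synthetic":
            system = make_demo_complex(n_frames=int(cfg["n_frames"]),
                                       seed=int(cfg["seed"]))
            traj = sample_trajectory(system)
            labels = system.node_labels
            if cfg["site_a"] is None:
                cfg["site_a"] = labels[system.site_a]
            if cfg["site_b"] is None:
                cfg["site_b"] = labels[system.site_b]
            report["parameters"]["site_a"] = cfg["site_a"]
            report["parameters"]["site_b"] = cfg["site_b"]
            report["synthetic_truth"] = dict(
                pathway=[labels[i] for i in system.pathway],
                n_blocks=int(system.block_labels.max()) + 1,
                repair=system.repair_report,
            )
            return traj
        if not cfg["topology"]:
            raise ValueError("files mode requires a topology path")
        traj = load_trajectory(cfg["topology"], list(cfg["coordinates"]) or None)
        return frame_window(traj, float(cfg["window_start"]),
                            float(cfg["window_end"]))

    traj = _input()
    node_map = make_node_map(traj.topology, cfg["node_rule"])

    @_stage("superpose")
    def _superpose():
        return superpose_to_mean(traj)

    fitted = _superpose()

    @_stage("fluctuation")
    def _fluct():
        prof = rmsf(fitted, node_map)
        return dict(mean_rmsf=mean_rmsf(prof),
                    max_rmsf=float(prof.values.max()),
                    profile={l: float(v)
                             for l, v in zip(prof.labels, prof.values)})

    report["rmsf"] = _fluct()

    @_stage("correlation")
    def _corr():
        return correlation_matrix(fitted, node_map)

    C = _corr()
    report["correlation"] = dict(
        n_nodes=C.n_nodes, n_frames=C.n_frames, node_rule=C.node_rule,
        mean_abs_offdiag=float(np.nanmean(
            np.abs(C.C[~np.eye(C.n_nodes, dtype=bool)]))),
    )

    @_stage("network")
    def _network():
        edges = contact_edges(traj, cutoff=float(cfg["contact_cutoff"]),
                              occupancy=float(cfg["occupancy_threshold"]))
        return build_network(C, edges, chains=node_map.chain_ids,
                             params=dict(cutoff=cfg["contact_cutoff"],
                                         occupancy=cfg["occupancy_threshold"]))

    net = _network()
    summary = network_summary(net, degree_threshold=float(cfg["degree_threshold"]))
    report["network"] = dict(
        n_nodes=summary.n_nodes, n_edges=summary.n_edges,
        clustering_coefficient=summary.clustering_coefficient,
        degree_centralization=summary.degree_centralization,
        mean_degree=summary.mean_degree,
        n_high_degree=summary.n_high_degree,
    )
    top = top_degree_table(net, k=10)
    report["top_degrees"] = [
        dict(node=r.node, chain=r.chain, weighted_degree=float(r.weighted_degree))
        for r in top.itertuples()
    ]
    sites = [s for s in (cfg["site_a"], cfg["site_b"]) if s]
    if sites:
        report["site_degree_sum"] = site_degree_sum(net, sites)
        report["site_degrees"] = {s: weighted_degree(net, s) for s in sites}

    @_stage("communities")
    def _communities():
        gn = girvan_newman(net)
        part = select_partition(gn, net, criterion=cfg["community_criterion"])
        return gn, part

    gn, part = _communities()
    report["communities"] = dict(
        n_communities=part.n_communities, Q=part.Q,
        criterion=part.criterion,
        assignment={l: int(c) for l, c in zip(part.node_labels, part.labels)},
    )

    @_stage("interactions")
    def _interactions():
        classes = ResidueClasses().with_overrides(
            hydrophobic_extra=tuple(cfg["hydrophobic_extra"]))
        results = [
            assign_hydrophobic(traj, cutoff=float(cfg["hydrophobic_cutoff"]),
                               classes=classes),
            assign_electrostatic(traj, cutoff=float(cfg["electrostatic_cutoff"]),
                                 classes=classes),
            assign_hbond(traj, cutoff=float(cfg["hbond_cutoff"])),
        ]
        return interaction_populations(results, traj,
                                       min_population=float(cfg["min_population"]))

    table = _interactions()
    report["interactions"] = dict(
        class_counts={k: int(v) for k, v in table.class_counts.items()},
        records=table.records.to_dict("records"),
    )
    chains = sorted(set(node_map.chain_ids))
    if len(chains) == 2:
        ga, gb = interface_residues(table, chains[0], chains[1])
        report["interface"] = dict(chain_a=chains[0], chain_b=chains[1],
                                   group_a=ga, group_b=gb)
        present = [g for g in (ga, gb) if g]
        if ga and gb:
            ic = interface_communities(part, ga, gb)
            report["interface"]["communities_a"] = ic["count_a"]
            report["interface"]["communities_b"] = ic["count_b"]
        elif present:
            report["interface"]["note"] = "one interface side empty"

    if cfg["site_a"] and cfg["site_b"]:
        @_stage("pathway")
        def _pathway():
            return shortest_pathway(net, cfg["site_a"], cfg["site_b"])

        path = _pathway()
        report["pathway"] = dict(
            nodes=path.nodes if path.found else None,
            total_length=path.total_length if path.found else None,
            found=path.found,
            rendered=str(path),
        )
    else:
        report["pathway"] = dict(skipped="no sites configured")

    if cfg["perturb_factor"] is not None and cfg["perturb_nodes"]:
        @_stage("perturbation")
        def _perturb():
            return perturbation_report(
                net, list(cfg["perturb_nodes"]),
                factor=float(cfg["perturb_factor"]),
                baseline_partition=part,
                sites=(cfg["site_a"], cfg["site_b"]) if sites else None,
                criterion=cfg["community_criterion"],
            )

        pr = _perturb()
        report["perturbation"] = dict(
            nodes=pr.nodes, factor=pr.factor,
            baseline_communities=pr.baseline_communities,
            perturbed_communities=pr.perturbed_communities,
            ari=pr.ari,
            path_blocked=pr.path_blocked,
            path_length_change=(None if not np.isfinite(pr.path_length_change)
                                else pr.path_length_change),
        )
    return report


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def save_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
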