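"""Frame-wise interaction assignment and population statistics.

Three distance rules classify residue-pair interactions per frame:

* hydrophobic — side-chain mass centers closer than 6.5 Å, both residues in
  the hydrophobic class;
* electrostatic — charged-moiety mass centers of a positive and a negative
  residue closer than 11 Å;
* hydrogen bond — any donor/acceptor heavy-atom (N or O) pair closer than
  3.5 Å; no angle criterion by default (an optional one exists but is off).

All cutoffs are strict ("closer than").  The population of a pair is the
fraction of frames in contact; the reporting filter keeps populations
strictly above 40% by default.  Residue class membership is configuration-
driven so modified residues (e.g. acetyl-lysine, which loses its positive
charge and may be treated as hydrophobic) can be reassigned per system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory, chain_adjacent_pairs

__all__ = [
    "ResidueClasses",
    "InteractionTable",
    "assign_hydrophobic",
    "assign_electrostatic",
    "assign_hbond",
    "interaction_populations",
    "interface_residues",
]

HYDROPHOBIC_CUTOFF = 6.5
ELECTROSTATIC_CUTOFF = 11.0
HBOND_CUTOFF = 3.5
MIN_POPULATION = 0.40

_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})
#: Charged-moiety atom names per residue; falls back to all side-chain heavy
#: atoms when none are present (pseudo-residue topologies).
_CHARGE_MOIETY = {
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASP": {"CG", "OD1", "OD2"},
    "GLU": {"CD", "OE1", "OE2"},
}


@dataclass
class ResidueClasses:
    """Configurable residue class sets for the three interaction rules.

    Defaults follow standard chemistry; acetyl-lysine (ALY) is excluded from
    the positive set (acetylation neutralizes the amine) and may be added to
    the hydrophobic set via ``hydrophobic_extra``.
    """

    hydrophobic: set = field(default_factory=lambda: {
        "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"})
    positive: set = field(default_factory=lambda: {"ARG", "LYS"})
    negative: set = field(default_factory=lambda: {"ASP", "GLU"})

    def with_overrides(self, hydrophobic_extra=(), positive_extra=(),
                       negative_extra=(), remove=()):
        h = (self.hydrophobic | set(hydrophobic_extra)) - set(remove)
        p = (self.positive | set(positive_extra)) - set(remove)
        n = (self.negative | set(negative_extra)) - set(remove)
        return ResidueClasses(hydrophobic=h, positive=p, negative=n)


def _residue_atom_groups(traj: Trajectory, kind: str):
    """Atom-index groups per residue for the requested distance rule."""
    atoms = traj.topology.atoms
    res_names = traj.topology.residue_table()["residue_name"]
    groups = {}
    for ridx in range(traj.topology.n_residues):
        sub = atoms[(atoms["residue_index"] == ridx) & atoms["heavy"]]
        if kind == "sidechain":
            sel = sub[~sub["atom_name"].isin(_BACKBONE)]
        elif kind == "moiety":
            moiety = _CHARGE_MOIETY.get(res_names[ridx], set())
            sel = sub[sub["atom_name"].isin(moiety)]
            if sel.empty:
                sel = sub[~sub["atom_name"].isin(_BACKBONE)]
        elif kind == "donor_acceptor":
            sel = sub[sub["element"].isin(["N", "O"])]
        else:
            raise ValueError(kind)
        groups[ridx] = (sel.index.to_numpy(),
                        sel["mass"].to_numpy(float))
    return groups


def _mass_center_series(traj: Trajectory, groups, ridx: int) -> np.ndarray:
    idx, m = groups[ridx]
    w = m / m.sum()
    return np.einsum("fad,a->fd", traj.coords[:, idx, :], w)


def _pair_contacts_masscenter(traj, pairs, groups, cutoff):
    """(F, n_pairs) distances between per-residue mass centers."""
    dist = np.empty((traj.n_frames, len(pairs)))
    centers = {}
    for k, (i, j) in enumerate(pairs):
        for r in (i, j):
            if r not in centers:
                centers[r] = _mass_center_series(traj, groups, r)
        dist[:, k] = np.linalg.norm(centers[i] - centers[j], axis=1)
    return dist, dist < cutoff


def _candidate_pairs(traj: Trajectory, names_ok_i, names_ok_j, scope: str):
    """Residue pairs passing class membership and chain scope."""
    res = traj.topology.residue_table()
    adjacent = chain_adjacent_pairs(traj.topology)
    pairs = []
    n = len(res)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in adjacent:
                continue
            same = res["chain_id"][i] == res["chain_id"][j]
            if scope == "inter" and same:
                continue
            if scope == "intra" and not same:
                continue
            ni, nj = res["residue_name"][i], res["residue_name"][j]
            if (ni in names_ok_i and nj in names_ok_j) or \
               (ni in names_ok_j and nj in names_ok_i):
                pairs.append((i, j))
    return pairs


@dataclass
class AssignmentResult:
    """Per-frame contact matrix for one interaction class."""

    interaction_class: str
    pairs: list                  # residue-index pairs (i, j)
    contacts: np.ndarray         # (F, n_pairs) bool
    distances: np.ndarray        # (F, n_pairs) Å
    cutoff: float


def assign_hydrophobic(traj: Trajectory, cutoff: float = HYDROPHOBIC_CUTOFF,
                       classes: ResidueClasses | None = None,
                       scope: str = "inter",
                       pairs=None) -> AssignmentResult:
    """Hydrophobic contacts: side-chain mass centers closer than ``cutoff``.

    Residues in the class set without side-chain heavy atoms (glycine) are a
    configuration error, not a silent miss.
    """
    classes = classes or ResidueClasses()
    groups = _residue_atom_groups(traj, "sidechain")
    res = traj.topology.residue_table()
    if pairs is None:
        pairs = _candidate_pairs(traj, classes.hydrophobic,
                                 classes.hydrophobic, scope)
    for i, j in pairs:
        for r in (i, j):
            if res["residue_name"][r] not in classes.hydrophobic:
                raise ValueError(
                    f"residue {res['label'][r]} is not in the hydrophobic class")
            if len(groups[r][0]) == 0:
                raise ValueError(
                    f"residue {res['label'][r]} has no side-chain heavy atoms")
    if not pairs:
        return AssignmentResult("hydrophobic", [], np.zeros((traj.n_frames, 0), bool),
                                np.zeros((traj.n_frames, 0)), cutoff)
    dist, contact = _pair_contacts_masscenter(traj, pairs, groups, cutoff)
    return AssignmentResult("hydrophobic", list(pairs), contact, dist, cutoff)


def assign_electrostatic(traj: Trajectory, cutoff: float = ELECTROSTATIC_CUTOFF,
                         classes: ResidueClasses | None = None,
                         scope: str = "inter",
                         pairs=None) -> AssignmentResult:
    """Electrostatic contacts between charged-moiety mass centers < cutoff.

    Pairs must be one positive and one negative residue; a same-sign pair
    requested explicitly is an error.
    """
    classes = classes or ResidueClasses()
    groups = _residue_atom_groups(traj, "moiety")
    res = traj.topology.residue_table()
    if pairs is None:
        pairs = _candidate_pairs(traj, classes.positive, classes.negative, scope)
        pairs = [
            (i, j) for i, j in pairs
            if {res["residue_name"][i], res["residue_name"][j]} &
               classes.positive
            and {res["residue_name"][i], res["residue_name"][j]} &
                classes.negative
        ]
    for i, j in pairs:
        ni, nj = res["residue_name"][i], res["residue_name"][j]
        pos = (ni in classes.positive) + (nj in classes.positive)
        neg = (ni in classes.negative) + (nj in classes.negative)
        if not (pos >= 1 and neg >= 1):
            raise ValueError(
                f"pair ({res['label'][i]}, {res['label'][j]}) is not a "
                "positive/negative residue pair")
    if not pairs:
        return AssignmentResult("electrostatic", [],
                                np.zeros((traj.n_frames, 0), bool),
                                np.zeros((traj.n_frames, 0)), cutoff)
    dist, contact = _pair_contacts_masscenter(traj, pairs, groups, cutoff)
    return AssignmentResult("electrostatic", list(pairs), contact, dist, cutoff)


def assign_hbond(traj: Trajectory, cutoff: float = HBOND_CUTOFF,
                 scope: str = "inter", pairs=None) -> AssignmentResult:
    """Hydrogen bonds: any donor/acceptor (N, O) heavy-atom pair < cutoff.

    The rule is purely distance-based; pairs with no N/O atoms on either
    side yield an empty result with a warning rather than an error.
    """
    import warnings

    groups = _residue_atom_groups(traj, "donor_acceptor")
    res = traj.topology.residue_table()
    adjacent = chain_adjacent_pairs(traj.topology)
    if pairs is None:
        candidates = []
        n = len(res)
        for i in range(n):
            if len(groups[i][0]) == 0:
                continue
            for j in range(i + 1, n):
                if len(groups[j][0]) == 0 or (i, j) in adjacent:
                    continue
                same = res["chain_id"][i] == res["chain_id"][j]
                if (scope == "inter" and same) or (scope == "intra" and not same):
                    continue
                candidates.append((i, j))
        pairs = candidates
    pairs = [p for p in pairs
             if len(groups[p[0]][0]) and len(groups[p[1]][0])]
    if not pairs:
        warnings.warn("no donor/acceptor atoms found; empty hydrogen-bond table",
                      RuntimeWarning, stacklevel=2)
        return AssignmentResult("hbond", [], np.zeros((traj.n_frames, 0), bool),
                                np.zeros((traj.n_frames, 0)), cutoff)
    dist = np.empty((traj.n_frames, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        ai, aj = groups[i][0], groups[j][0]
        diff = traj.coords[:, ai, None, :] - traj.coords[:, None, aj, :]
        dist[:, k] = np.sqrt(np.einsum("fabd,fabd->fab", diff, diff)).min(axis=(1, 2))
    return AssignmentResult("hbond", list(pairs), dist < cutoff, dist, cutoff)


@dataclass
class InteractionTable:
    """Population-filtered interaction records."""

    records: pd.DataFrame        # residue_i, residue_j, label_i, label_j,
    # chain_i, chain_j, interaction_class, population, mean_distance
    min_population: float
    class_counts: dict

    def __len__(self) -> int:
        return len(self.records)


def interaction_populations(results, traj: Trajectory,
                            min_population: float = MIN_POPULATION) -> InteractionTable:
    """Population = fraction of frames in contact; keep strictly > filter.

    ``results`` is an iterable of :class:`AssignmentResult` from a single
    frame window.  Per-class record counts are reported alongside.
    """
    res = traj.topology.residue_table()
    rows = []
    for r in results:
        if r.contacts.shape[0] == 0:
            raise ValueError("empty frame set: populations undefined")
        pops = r.contacts.mean(axis=0)
        for k, (i, j) in enumerate(r.pairs):
            if pops[k] > min_population:
                rows.append(dict(
                    residue_i=i, residue_j=j,
                    label_i=res["label"][i], label_j=res["label"][j],
                    chain_i=res["chain_id"][i], chain_j=res["chain_id"][j],
                    interaction_class=r.interaction_class,
                    population=float(pops[k]),
                    mean_distance=float(r.distances[:, k].mean()),
                ))
    records = pd.DataFrame(rows, columns=[
        "residue_i", "residue_j", "label_i", "label_j", "chain_i", "chain_j",
        "interaction_class", "population", "mean_distance"])
    counts = records["interaction_class"].value_counts().to_dict()
    return InteractionTable(records=records, min_population=min_population,
                            class_counts=counts)


def interface_residues(table: InteractionTable, chain_a: str, chain_b: str):
    """Residues of each chain participating in >= 1 retained inter-chain
    interaction; returns (group_a_labels, group_b_labels)."""
    rec = table.records
    chains_seen = set(rec["chain_i"]) | set(rec["chain_j"]) if len(rec) else set()
    if len(rec) and not ({chain_a, chain_b} & chains_seen):
        raise KeyError(f"chains {chain_a!r}/{chain_b!r} absent from table")
    ga, gb = set(), set()
    for _, row in rec.iterrows():
        ci, cj = row["chain_i"], row["chain_j"]
        if {ci, cj} == {chain_a, chain_b}:
            if ci == chain_a:
                ga.add(row["label_i"])
                gb.add(row["label_j"])
            else:
                ga.add(row["label_j"])
                gb.add(row["label_i"])
    return sorted(ga), sorted(gb)
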