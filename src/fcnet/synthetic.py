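"""Synthetic coordinate trajectories with planted correlation structure.

Real fluctuation-network studies start from MD trajectories that are rarely
deposited.  This module generates surrogate trajectories whose statistical
structure is known exactly, so that every downstream stage — correlation
estimation, contact-occupancy networks, community detection, pathway mining —
can be tested against planted ground truth:

* a **block correlation matrix** (communities of residues moving together),
* a **designed contact graph** (which residue pairs sit within the 4.5 Å
  heavy-atom contact cutoff, and which are kept beyond 6 Å),
* optional **pathway boosts** (an ordered residue chain given extra-high
  correlation, the ground truth for shortest-pathway recovery), and
* marked **modification-site** nodes at the pathway endpoints.

Each residue carries three pseudo heavy atoms (a CA node point plus two
side-chain points) so heavy-atom minimum-distance and mass-center rules are
exercised.  Frames are i.i.d. draws: per axis, the residue displacement
vector is multivariate normal with the planted correlation matrix, scaled by
the per-residue fluctuation SD; axes are independent and isotropic, which
makes the estimand of the normalized-covariance correlation equal to the
planted scalar correlation.

Geometric realizability is non-trivial: the contact rule (< 4.5 Å) and the
separation rule (> 6 Å) leave a forbidden annulus, so not every graph can be
embedded (e.g. a 4-cycle with all sides < 4.5 Å cannot have both diagonals
> 6 Å).  :func:`make_chain_geometry` solves a hinge-loss distance-geometry
problem and verifies the result, raising :class:`GeometryError` naming an
offending pair when the requested graph is unrealizable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .trajectory import Topology, Trajectory

__all__ = [
    "GeometryError",
    "PlantedSystem",
    "make_chain_geometry",
    "target_correlation",
    "sample_trajectory",
    "make_two_block_system",
    "make_ring_pathway_system",
    "make_demo_complex",
    "write_ground_truth",
]

#: Side-chain pseudo-atom offset from the CA point (Å).  Small enough that a
#: CA separation of 7 Å guarantees heavy-atom separation > 6 Å.
SIDECHAIN_OFFSET = 0.4

#: Surrogate CA-CA targets used by the solver; the final check is on actual
#: pseudo heavy atoms against the 4.5 / 6.0 Å rules.
_CONTACT_CA_TARGET = 4.0
_SEPARATE_CA_TARGET = 7.0
_MIN_CA_DISTANCE = 2.0

#: SC2 pseudo-atom element/name per residue type (SC1 is always a CB carbon).
_SIDECHAIN_TIP = {
    "LYS": ("NZ", "N", 14.007), "ARG": ("NH1", "N", 14.007),
    "ASP": ("OD1", "O", 15.999), "GLU": ("OE1", "O", 15.999),
    "SER": ("OG", "O", 15.999), "THR": ("OG1", "O", 15.999),
    "ASN": ("OD1", "O", 15.999), "GLN": ("OE1", "O", 15.999),
    "ALY": ("NZ", "N", 14.007),
}
_DEFAULT_TIP = ("CG", "C", 12.011)


class GeometryError(ValueError):
    """A requested contact graph cannot be realized in 3-D."""


# ---------------------------------------------------------------------------
# geometry


def _canonical_pairs(pairs) -> set:
    out = set()
    for i, j in pairs:
        if i == j:
            raise GeometryError(f"self-contact ({i}, {j}) is not meaningful")
        out.add((min(i, j), max(i, j)))
    return out


def _chain_adjacent(chain_ids) -> set:
    pairs = set()
    for i in range(len(chain_ids) - 1):
        if chain_ids[i] == chain_ids[i + 1]:
            pairs.add((i, i + 1))
    return pairs


def _solve_ca_positions(n, contacts, adjacent, seed, n_restarts=8):
    """Hinge-loss distance geometry for the CA points."""
    allp = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], int)
    is_contact = np.array([tuple(p) in contacts for p in allp])
    is_adj = np.array([tuple(p) in adjacent for p in allp])
    cu = allp[is_contact]
    nl = allp[~is_contact & ~is_adj]

    def fg(x):
        X = x.reshape(n, 3)
        f = 0.0
        G = np.zeros_like(X)
        for pairs, bound, upper in ((cu, _CONTACT_CA_TARGET, True),
                                    (nl, _SEPARATE_CA_TARGET, False),
                                    (allp, _MIN_CA_DISTANCE, False)):
            if len(pairs) == 0:
                continue
            d = X[pairs[:, 0]] - X[pairs[:, 1]]
            r = np.linalg.norm(d, axis=1) + 1e-12
            v = np.maximum(r - bound, 0.0) if upper else np.minimum(r - bound, 0.0)
            f += float(np.sum(v * v))
            coef = (2.0 * v / r)[:, None] * d
            np.add.at(G, pairs[:, 0], coef)
            np.add.at(G, pairs[:, 1], -coef)
        return f, G.ravel()

    # classical-MDS initialization from coarse target distances
    D = np.full((n, n), 10.0)
    np.fill_diagonal(D, 0.0)
    for i, j in contacts:
        D[i, j] = D[j, i] = 3.6
    for i, j in adjacent - contacts:
        D[i, j] = D[j, i] = 3.8
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    k = min(3, n)
    X0 = np.zeros((n, 3))
    X0[:, :k] = V[:, -k:] * np.sqrt(np.maximum(w[-k:], 0.0))

    rng = np.random.default_rng(seed)
    best = None
    for t in range(n_restarts):
        x0 = (X0 + rng.normal(0.0, 0.3 + 0.5 * t, X0.shape)).ravel()
        res = minimize(fg, x0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=3000, ftol=1e-14, gtol=1e-10))
        f, _ = fg(res.x)
        if best is None or f < best[0]:
            best = (f, res.x.reshape(n, 3))
        if f < 1e-10:
            break
    return best[1]


def _build_pseudo_atoms(X, chain_ids, residue_names, residue_numbers,
                        orient_pairs=None):
    """Attach CB/tip pseudo-atoms around each CA point.

    Side chains point away from the molecular centroid by default.  For pairs
    listed in ``orient_pairs`` the tip atoms of both residues are instead
    turned toward each other and placed at a donor-acceptor style separation,
    so stable short-range (hydrogen-bond-like) contacts can be planted.
    """
    n = len(X)
    centroid = X.mean(axis=0)
    tips = np.empty((n, 3))
    cbs = np.empty((n, 3))
    for i in range(n):
        out = X[i] - centroid
        nrm = np.linalg.norm(out)
        u = out / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        # two fixed perpendicular-ish directions derived from u
        a = np.array([1.0, 0.0, 0.0])
        if abs(u @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, a)
        v /= np.linalg.norm(v)
        cbs[i] = X[i] + SIDECHAIN_OFFSET * (0.8 * u + 0.6 * v)
        tips[i] = X[i] + SIDECHAIN_OFFSET * (0.8 * u - 0.6 * v)
    for i, j in (orient_pairs or []):
        mid = 0.5 * (X[i] + X[j])
        for k, other in ((i, j), (j, i)):
            d = mid - X[k]
            d /= np.linalg.norm(d)
            # tip sits 1.45 Å short of the midpoint: tip-tip distance 2.9 Å
            tips[k] = mid - 1.45 * d

    rows, coords = [], []
    for i in range(n):
        name, elem, mass = _SIDECHAIN_TIP.get(residue_names[i], _DEFAULT_TIP)
        for atom_name, e, m, xyz in (
            ("CA", "C", 12.011, X[i]),
            ("CB", "C", 12.011, cbs[i]),
            (name, elem, mass, tips[i]),
        ):
            rows.append(dict(
                atom_name=atom_name, element=e, mass=m, residue_index=i,
                residue_number=int(residue_numbers[i]),
                residue_name=residue_names[i],
                chain_id=chain_ids[i], heavy=True,
            ))
            coords.append(xyz)
    topology = Topology(pd.DataFrame(rows))
    return Trajectory(coords=np.asarray(coords)[None, :, :], topology=topology,
                      provenance=[dict(source="synthetic")])


def _verify_geometry(base: Trajectory, contacts, adjacent):
    """Check planted contacts/separations on actual pseudo heavy atoms."""
    coords = base.coords[0]
    res_idx = base.topology.atoms["residue_index"].to_numpy()
    n = base.topology.n_residues
    groups = [np.flatnonzero(res_idx == i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(
                coords[groups[i]][:, None, :] - coords[groups[j]][None, :, :],
                axis=2,
            ).min()
            if (i, j) in contacts:
                if not d < 4.5:
                    raise GeometryError(
                        f"contact pair ({i}, {j}) unrealized: min heavy-atom "
                        f"distance {d:.2f} Å >= 4.5 Å"
                    )
            elif (i, j) not in adjacent and not d > 6.0:
                raise GeometryError(
                    f"separation pair ({i}, {j}) unrealized: min heavy-atom "
                    f"distance {d:.2f} Å <= 6.0 Å"
                )


def make_chain_geometry(n_res: int, contact_spec, seed: int = 0,
                        chain_ids=None, residue_names=None,
                        residue_numbers=None, orient_pairs=None) -> Trajectory:
    """Build a single-frame base geometry realizing a contact graph.

    Every pair in ``contact_spec`` ends within 4.5 Å minimum heavy-atom
    distance; every other pair that is not chain-adjacent ends beyond 6 Å.
    Chain-adjacent pairs are covalently linked and exempt from both rules.

    Returns a 1-frame :class:`~fcnet.trajectory.Trajectory` with three pseudo
    heavy atoms per residue.  Raises :class:`GeometryError` naming an
    offending pair if the graph cannot be embedded.
    """
    if n_res < 1:
        raise GeometryError("need at least one residue")
    contacts = _canonical_pairs(contact_spec)
    for i, j in contacts:
        if not (0 <= i < n_res and 0 <= j < n_res):
            raise GeometryError(f"contact pair ({i}, {j}) outside 0..{n_res - 1}")
    chain_ids = list(chain_ids) if chain_ids is not None else ["A"] * n_res
    if residue_names is None:
        residue_names = ["ALA"] * n_res
    if residue_numbers is None:
        residue_numbers, counts = [], {}
        for c in chain_ids:
            counts[c] = counts.get(c, 0) + 1
            residue_numbers.append(counts[c])
    adjacent = _chain_adjacent(chain_ids)

    X = _solve_ca_positions(n_res, contacts, adjacent, seed)
    base = _build_pseudo_atoms(X, chain_ids, residue_names, residue_numbers,
                               orient_pairs=orient_pairs)
    _verify_geometry(base, contacts, adjacent)
    return base


# ---------------------------------------------------------------------------
# planted correlation model


@dataclass
class PlantedSystem:
    """A base geometry plus the planted statistical ground truth."""

    base: Trajectory
    block_labels: np.ndarray
    contact_spec: frozenset
    intra_corr: float
    inter_corr: float
    fluct_scale: np.ndarray
    n_frames: int
    seed: int
    pathway: tuple = ()
    pathway_corr: float = 0.9
    site_a: int | None = None
    site_b: int | None = None
    contact_jitter: float = 0.0
    repair_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        n = self.base.topology.n_residues
        self.block_labels = np.asarray(self.block_labels, int)
        if self.block_labels.shape != (n,):
            raise ValueError("block_labels must have one entry per residue")
        self.fluct_scale = np.broadcast_to(
            np.asarray(self.fluct_scale, float), (n,)
        ).copy()
        if not (0.0 <= self.intra_corr < 1.0 and 0.0 <= self.inter_corr < 1.0):
            raise ValueError("block correlations must lie in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def n_res(self) -> int:
        return self.base.topology.n_residues

    @property
    def node_labels(self) -> list:
        return list(self.base.topology.residue_table()["label"])


def target_correlation(system: PlantedSystem):
    """Planted correlation matrix, PSD-repaired if necessary.

    Blocks receive ``intra_corr`` within / ``inter_corr`` across; consecutive
    pathway pairs are boosted to ``pathway_corr``.  If the construction is
    indefinite, negative eigenvalues are clipped at 1e-10 and the diagonal
    renormalized to 1; the repair magnitude is recorded in
    ``system.repair_report``.
    """
    lab = system.block_labels
    C = np.where(lab[:, None] == lab[None, :], system.intra_corr,
                 system.inter_corr).astype(float)
    for a, b in zip(system.pathway[:-1], system.pathway[1:]):
        C[a, b] = C[b, a] = system.pathway_corr
    np.fill_diagonal(C, 1.0)

    w, V = np.linalg.eigh(C)
    min_eig = float(w.min())
    if min_eig < 1e-10:
        w_clipped = np.clip(w, 1e-10, None)
        R = (V * w_clipped) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        repaired = 0.5 * (R + R.T)
        system.repair_report.update(
            repaired=True,
            min_eigenvalue=min_eig,
            frobenius_change=float(np.linalg.norm(repaired - C)),
            max_entry_change=float(np.abs(repaired - C).max()),
        )
        C = repaired
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("planted correlation matrix is not repairable")
    else:
        system.repair_report.update(repaired=False, min_eigenvalue=min_eig)
    return C


def sample_trajectory(system: PlantedSystem) -> Trajectory:
    """Draw i.i.d. frames from the planted Gaussian displacement model.

    Per axis, the n-residue displacement vector is multivariate normal with
    the planted correlation matrix; axes are independent and isotropic.  A
    residue's three pseudo-atoms move rigidly together.  Identical systems
    (including seed) give bit-identical trajectories.
    """
    C = target_correlation(system)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    rng = np.random.default_rng(system.seed)
    n, F = system.n_res, system.n_frames
    z = rng.standard_normal((F, 3, n))
    disp = np.einsum("fdn,mn->fmd", z, L)          # (F, n_res, 3), corr planted
    disp *= system.fluct_scale[None, :, None]

    res_idx = system.base.topology.atoms["residue_index"].to_numpy()
    coords = system.base.coords[0][None, :, :] + disp[:, res_idx, :]
    if system.contact_jitter > 0.0:
        coords = coords + rng.normal(0.0, system.contact_jitter, coords.shape)
    return Trajectory(
        coords=coords,
        topology=system.base.topology,
        provenance=[dict(source="synthetic", seed=system.seed, n_frames=F)],
    )


# ---------------------------------------------------------------------------
# designed systems


def _ring_block(base: int, anchors=(0,)):
    """Closed triangle-strip ring on ten residues ``base..base+9``.

    The spatial ring order interleaves sequence positions so that spatially
    adjacent residues are never chain-adjacent (their contacts would otherwise
    be excluded as covalent).  ``anchors`` are ring positions whose skip
    edges are dropped, freeing the node to accept an external bridge contact
    without violating the 6 Å separation rule around it.
    """
    sigma = [base + s for s in (0, 2, 4, 6, 8, 1, 3, 5, 7, 9)]
    edges = set()
    for k in range(10):
        edges.add(tuple(sorted((sigma[k], sigma[(k + 1) % 10]))))
    for k in range(10):
        if k in anchors or (k + 2) % 10 in anchors:
            continue
        edges.add(tuple(sorted((sigma[k], sigma[(k + 2) % 10]))))
    return edges, sigma


def make_two_block_system(intra_corr: float = 0.9, inter_corr: float = 0.1,
                          n_frames: int = 10_000, fluct_scale=0.3,
                          seed: int = 0) -> PlantedSystem:
    """Twenty residues in two planted blocks joined by one bridge contact.

    Block 1 is chain A (residues 0-9), block 2 chain B (residues 10-19); each
    block is a thinned triangle-strip ring and the single inter-block contact
    joins the two anchor residues (0, 10).  The designated sites sit at the
    far ends (residues 9 and 19), so removing the bridge must disconnect
    them.
    """
    e1, _ = _ring_block(0, anchors=(0,))
    e2, _ = _ring_block(10, anchors=(0,))
    contacts = frozenset(e1 | e2 | {(0, 10)})
    base = make_chain_geometry(
        20, contacts, seed=seed,
        chain_ids=["A"] * 10 + ["B"] * 10,
    )
    return PlantedSystem(
        base=base,
        block_labels=np.repeat([0, 1], 10),
        contact_spec=contacts,
        intra_corr=intra_corr,
        inter_corr=inter_corr,
        fluct_scale=fluct_scale,
        n_frames=n_frames,
        seed=seed,
        site_a=9,
        site_b=19,
    )


def make_ring_pathway_system(intra_corr: float = 0.35, inter_corr: float = 0.15,
                             pathway_corr: float = 0.9, n_frames: int = 5_000,
                             fluct_scale=0.3, seed: int = 0) -> PlantedSystem:
    """Sixteen residues on a spatial ring crossing two chains twice.

    The contact graph is a single cycle, so exactly two routes join the two
    marked sites (residues 0 and 8, one per chain).  One arc is planted as
    the high-correlation pathway; the other arc keeps background
    correlations, making the planted chain the unique shortest pathway under
    w = -log|C| edge lengths.
    """
    order = [0, 2, 4, 6, 1, 3, 5, 7, 8, 10, 12, 14, 9, 11, 13, 15]
    contacts = frozenset(
        tuple(sorted((order[k], order[(k + 1) % 16]))) for k in range(16)
    )
    base = make_chain_geometry(
        16, contacts, seed=seed,
        chain_ids=["A"] * 8 + ["B"] * 8,
    )
    pathway = (0, 2, 4, 6, 1, 3, 5, 7, 8)     # forward arc, site to site
    return PlantedSystem(
        base=base,
        block_labels=np.repeat([0, 1], 8),
        contact_spec=contacts,
        intra_corr=intra_corr,
        inter_corr=inter_corr,
        fluct_scale=fluct_scale,
        n_frames=n_frames,
        seed=seed,
        pathway=pathway,
        pathway_corr=pathway_corr,
        site_a=0,
        site_b=8,
    )


def make_demo_complex(n_frames: int = 4_000, seed: int = 0,
                      intra_corr: float = 0.45, inter_corr: float = 0.1,
                      pathway_corr: float = 0.9) -> PlantedSystem:
    """A two-chain receptor-peptide complex with planted regulation pathway.

    Chain A (receptor, 22 residues) folds into two ring-block domains joined
    by one inter-domain contact, with a two-residue flexible linker carrying
    no contacts.  Chain B (peptide, 9 residues) docks two marked sites onto
    the domains: K4 (positive, hydrogen-bonded to S824 of domain 1) and K8ac
    (an acetyl-lysine, classifiable hydrophobic, packed against L838 of
    domain 2).  The planted pathway runs from K4 through domain 1, across the
    inter-domain bridge and domain 2 to K8ac — the synthetic analogue of a
    modification-to-modification information-transfer route.
    """
    # receptor domains: thinned ring blocks on 0..9 and 12..21
    e1, _ = _ring_block(0, anchors=(0, 5))     # anchor nodes 0 and 1
    e2, _ = _ring_block(12, anchors=(0, 5))    # anchor nodes 12 and 13
    bridge = (1, 12)
    site_a, site_b = 25, 29                    # peptide residues 4 and 8
    contacts = frozenset(e1 | e2 | {bridge, (0, site_a), (13, site_b)})

    chain_ids = ["A"] * 22 + ["B"] * 9
    residue_numbers = list(range(824, 846)) + list(range(1, 10))
    residue_names = ["ALA"] * 31
    # receptor: anchors and pathway-relevant residues get distinctive types
    names = {0: "SER", 1: "VAL", 2: "GLU", 12: "PHE", 13: "LEU",
             4: "LEU", 6: "ILE", 8: "MET", 14: "VAL", 16: "LEU",
             18: "PHE", 20: "ALA", 3: "ASP", 17: "GLU"}
    # peptide: K4 positive site, K8ac acetyl-lysine site, an arginine nearby
    names.update({22: "GLY", 23: "THR", 24: "ALA", 25: "LYS", 26: "ARG",
                  27: "SER", 28: "VAL", 29: "ALY", 30: "GLY"})
    for k, v in names.items():
        residue_names[k] = v

    base = make_chain_geometry(
        31, contacts, seed=seed,
        chain_ids=chain_ids,
        residue_names=residue_names,
        residue_numbers=residue_numbers,
        orient_pairs=[(0, site_a)],            # planted hydrogen bond S824/K4
    )
    # blocks: domain 1 (+linker), domain 2, peptide
    blocks = np.empty(31, int)
    blocks[0:12] = 0
    blocks[12:22] = 1
    blocks[22:31] = 2
    pathway = (site_a, 0, 2, 4, 6, 8, 1, 12, 14, 16, 18, 20, 13, site_b)
    # peptide residues fluctuate more than the folded receptor core
    fluct = np.where(np.arange(31) >= 22, 0.45, 0.3)
    return PlantedSystem(
        base=base,
        block_labels=blocks,
        contact_spec=contacts,
        intra_corr=intra_corr,
        inter_corr=inter_corr,
        fluct_scale=fluct,
        n_frames=n_frames,
        seed=seed,
        pathway=pathway,
        pathway_corr=pathway_corr,
        site_a=site_a,
        site_b=site_b,
    )


def write_ground_truth(system: PlantedSystem, path: str) -> None:
    """Dump planted block labels, contacts, pathway and sites as JSON."""
    labels = system.node_labels
    payload = dict(
        node_labels=labels,
        block_labels=system.block_labels.tolist(),
        contacts=sorted([int(i), int(j)] for i, j in system.contact_spec),
        pathway=[labels[i] for i in system.pathway],
        site_a=None if system.site_a is None else labels[system.site_a],
        site_b=None if system.site_b is None else labels[system.site_b],
        intra_corr=system.intra_corr,
        inter_corr=system.inter_corr,
        pathway_corr=system.pathway_corr,
        fluct_scale=system.fluct_scale.tolist(),
        n_frames=system.n_frames,
        seed=system.seed,
        repair_report=system.repair_report,
    )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
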