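"""Trajectory containers and I/O.

Coordinates are stored as a dense ``(n_frames, n_atoms, 3)`` array in
Angstroms together with a flat per-atom topology table.  Standard formats
(PDB topologies, multi-model PDB, DCD, XTC) are read through :mod:`mdtraj`;
a plain whitespace coordinate table is supported as a text-only interchange
format.

Residue-level analyses address residues through a :class:`NodeMap`, which
fixes the "one node per amino acid" convention: each node carries a label in
author numbering (``L838``), a representative point (alpha-carbon by default,
residue mass center optionally) and its set of heavy atoms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Trajectory",
    "NodeMap",
    "TrajectoryError",
    "load_trajectory",
    "concatenate",
    "frame_window",
    "write_multimodel_pdb",
    "write_coordinate_table",
    "read_coordinate_table",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Default aliases mapping modified-residue names to a parent residue and a
#: label suffix; extend via config for system-specific chemistry.
MODIFIED_RESIDUE_ALIASES = {
    "ALY": ("LYS", "ac"),   # acetyl-lysine
    "KAC": ("LYS", "ac"),
    "MLY": ("LYS", "me"),   # methyl-lysine
    "M2L": ("LYS", "me2"),
    "M3L": ("LYS", "me3"),
}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent trajectory inputs."""


@dataclass(frozen=True)
class Topology:
    """Per-atom metadata shared by all frames of a trajectory.

    ``atoms`` is a DataFrame with one row per atom and columns
    ``atom_name, element, mass, residue_index, residue_number, residue_name,
    chain_id, heavy``.  ``residue_index`` is a 0-based contiguous node index;
    ``residue_number`` is the author numbering used for reporting.
    """

    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "atom_name", "element", "mass", "residue_index",
            "residue_number", "residue_name", "chain_id", "heavy",
        }
        missing = required - set(self.atoms.columns)
        if missing:
            raise TrajectoryError(f"topology missing columns: {sorted(missing)}")
        idx = np.asarray(self.atoms["residue_index"])
        if len(idx) and not np.array_equal(np.unique(idx), np.arange(idx.max() + 1)):
            raise TrajectoryError("residue indices must be contiguous from 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return 0 if self.atoms.empty else int(self.atoms["residue_index"].max()) + 1

    def residue_table(self) -> pd.DataFrame:
        """One row per residue: index, number, name, chain, label."""
        res = (
            self.atoms.groupby("residue_index")
            .agg(
                residue_number=("residue_number", "first"),
                residue_name=("residue_name", "first"),
                chain_id=("chain_id", "first"),
            )
            .reset_index()
        )
        res["label"] = [
            residue_label(n, num)
            for n, num in zip(res["residue_name"], res["residue_number"])
        ]
        # disambiguate duplicated author numbers across chains
        dup = res["label"].duplicated(keep=False)
        if dup.any():
            res.loc[dup, "label"] = (
                res.loc[dup, "label"] + "/" + res.loc[dup, "chain_id"].astype(str)
            )
        return res

    def same_atoms(self, other: "Topology") -> bool:
        cols = ["atom_name", "element", "residue_index", "residue_name", "chain_id"]
        return self.atoms[cols].equals(other.atoms[cols])


def residue_label(residue_name: str, residue_number: int) -> str:
    """Author-style residue label, e.g. ``L838`` or ``K23ac``."""
    name = residue_name.upper()
    suffix = ""
    if name in MODIFIED_RESIDUE_ALIASES:
        name, suffix = MODIFIED_RESIDUE_ALIASES[name]
    one = THREE_TO_ONE.get(name)
    if one is None:
        return f"{residue_name}{residue_number}{suffix}"
    return f"{one}{residue_number}{suffix}"


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (Angstrom) over a fixed topology."""

    coords: np.ndarray
    topology: Topology
    frame_stride_ps: float = 1.0
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must be (frames, atoms, 3); got {self.coords.shape}"
            )
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class NodeMap:
    """One node per amino acid: labels, representative points, heavy atoms.

    ``node_rule`` selects the representative point: ``"alpha_carbon"`` (the
    CA atom; falls back to the residue heavy-atom mass center when absent) or
    ``"mass_center"`` (mass-weighted heavy-atom centroid).
    """

    node_rule: str
    labels: list
    chain_ids: list
    residue_numbers: np.ndarray
    residue_names: list
    heavy_atom_indices: list          # list of int arrays, one per node
    _weights: list = field(repr=False, default_factory=list)  # per-node atom weights

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def node_positions(self, coords: np.ndarray) -> np.ndarray:
        """Representative point per node, ``(n_frames, n_nodes, 3)``."""
        coords = np.asarray(coords, dtype=float)
        out = np.empty((coords.shape[0], self.n_nodes, 3))
        for i, (atoms, w) in enumerate(zip(self.heavy_atom_indices, self._weights)):
            out[:, i, :] = np.einsum("fad,a->fd", coords[:, atoms, :], w)
        return out

    def chain_of(self, node: int) -> str:
        return self.chain_ids[node]


def make_node_map(topology: Topology, node_rule: str = "alpha_carbon") -> NodeMap:
    """Build the residue→node mapping from a topology."""
    if node_rule not in ("alpha_carbon", "mass_center"):
        raise TrajectoryError(f"unknown node_rule {node_rule!r}")
    atoms = topology.atoms
    res = topology.residue_table()
    heavy_sets, weights = [], []
    for ridx in res["residue_index"]:
        sub = atoms[(atoms["residue_index"] == ridx) & atoms["heavy"]]
        if sub.empty:
            raise TrajectoryError(
                f"residue index {ridx} has no heavy atoms; cannot define a node"
            )
        idx = sub.index.to_numpy()
        heavy_sets.append(idx)
        if node_rule == "alpha_carbon":
            ca = sub[sub["atom_name"] == "CA"]
            if len(ca):
                w = np.zeros(len(idx))
                w[np.flatnonzero(idx == ca.index[0])[0]] = 1.0
            else:
                m = sub["mass"].to_numpy(float)
                w = m / m.sum()
        else:
            m = sub["mass"].to_numpy(float)
            w = m / m.sum()
        weights.append(w)
    return NodeMap(
        node_rule=node_rule,
        labels=list(res["label"]),
        chain_ids=list(res["chain_id"]),
        residue_numbers=res["residue_number"].to_numpy(),
        residue_names=list(res["residue_name"]),
        heavy_atom_indices=heavy_sets,
        _weights=weights,
    )


def chain_adjacent_pairs(topology: Topology) -> set:
    """Residue-index pairs linked by the backbone (|i-j| <= 1 within a chain)."""
    res = topology.residue_table()
    pairs = set()
    for _, grp in res.groupby("chain_id"):
        idx = grp.sort_values("residue_number")["residue_index"].to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            pairs.add((min(a, b), max(a, b)))
    return pairs


# ---------------------------------------------------------------------------
# I/O


def _topology_from_mdtraj(md_top) -> Topology:
    rows = []
    ridx = -1
    last = None
    for atom in md_top.atoms:
        r = atom.residue
        key = (r.chain.index, r.index)
        if key != last:
            ridx += 1
            last = key
        elem = atom.element.symbol if atom.element is not None else "X"
        mass = atom.element.mass if atom.element is not None else 0.0
        rows.append(
            dict(
                atom_name=atom.name,
                element=elem,
                mass=float(mass),
                residue_index=ridx,
                residue_number=int(r.resSeq),
                residue_name=r.name,
                chain_id=str(r.chain.chain_id or chr(ord("A") + r.chain.index)),
                heavy=elem != "H",
            )
        )
    return Topology(pd.DataFrame(rows))


def load_trajectory(topology_path: str, coord_paths=None,
                    frame_stride_ps: float = 1.0) -> Trajectory:
    """Load a topology plus zero or more coordinate files.

    With no ``coord_paths`` the topology file itself must carry coordinates
    (e.g. a multi-model PDB).  Coordinate files may be PDB/DCD/XTC (via
    mdtraj) or the plain whitespace table; frames are concatenated in file
    order and provenance records the source of every frame range.
    """
    import mdtraj

    if not os.path.exists(topology_path):
        raise TrajectoryError(f"topology file not found: {topology_path}")
    ref = mdtraj.load(topology_path)
    topology = _topology_from_mdtraj(ref.topology)

    blocks, provenance = [], []
    sources = list(coord_paths) if coord_paths else [topology_path]
    start = 0
    for path in sources:
        if not os.path.exists(path):
            raise TrajectoryError(f"coordinate file not found: {path}")
        if path.endswith((".tab", ".txt", ".dat")):
            block = read_coordinate_table(path, topology).coords
        else:
            try:
                sub = mdtraj.load(path, top=ref.topology)
            except Exception as exc:  # mdtraj raises many concrete types
                raise TrajectoryError(f"cannot read {path}: {exc}") from exc
            block = np.asarray(sub.xyz, dtype=float) * 10.0  # nm -> Angstrom
        if block.shape[1] != topology.n_atoms:
            raise TrajectoryError(
                f"atom count mismatch: topology has {topology.n_atoms} atoms "
                f"but {path} has {block.shape[1]}"
            )
        blocks.append(block)
        provenance.append(
            dict(source=path, frame_start=start, frame_stop=start + block.shape[0])
        )
        start += block.shape[0]
    return Trajectory(
        coords=np.concatenate(blocks, axis=0),
        topology=topology,
        frame_stride_ps=frame_stride_ps,
        provenance=provenance,
    )


def concatenate(trajs) -> Trajectory:
    """Join replicate trajectories end to end over an identical topology."""
    trajs = list(trajs)
    if not trajs:
        raise TrajectoryError("cannot concatenate an empty list of trajectories")
    head = trajs[0]
    for t in trajs[1:]:
        if not head.topology.same_atoms(t.topology):
            raise TrajectoryError("topology mismatch between trajectories")
    prov = []
    for t in trajs:
        prov.extend(t.provenance or [dict(source="<memory>", n_frames=t.n_frames)])
    return Trajectory(
        coords=np.concatenate([t.coords for t in trajs], axis=0),
        topology=head.topology,
        frame_stride_ps=head.frame_stride_ps,
        provenance=prov,
    )


def frame_window(traj: Trajectory, start_frac: float, end_frac: float) -> Trajectory:
    """Contiguous fractional frame window, e.g. ``(0.5, 1.0)`` = last half."""
    if not (0.0 <= start_frac < end_frac <= 1.0):
        raise TrajectoryError(
            f"need 0 <= start < end <= 1; got ({start_frac}, {end_frac})"
        )
    n = traj.n_frames
    lo = int(np.floor(start_frac * n))
    hi = int(np.ceil(end_frac * n))
    if hi <= lo:
        raise TrajectoryError("empty frame selection")
    out = traj.with_coords(traj.coords[lo:hi])
    out.provenance = list(traj.provenance) + [dict(window=(lo, hi))]
    return out


def write_multimodel_pdb(traj: Trajectory, path: str) -> None:
    """Write all frames as MODEL/ENDMDL records of a single PDB file."""
    atoms = traj.topology.atoms
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 1
            for (_, row), (x, y, z) in zip(atoms.iterrows(), traj.coords[f]):
                fh.write(
                    "ATOM  {serial:5d} {name:^4s} {res:<3s} {chain:1s}{num:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}\n".format(
                        serial=serial,
                        name=row["atom_name"][:4],
                        res=row["residue_name"][:3],
                        chain=str(row["chain_id"])[:1],
                        num=int(row["residue_number"]),
                        x=x, y=y, z=z,
                        elem=row["element"][:2],
                    )
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_coordinate_table(traj: Trajectory, path: str) -> None:
    """Plain whitespace table: frame, atom, residue_index, x, y, z (Å)."""
    res_idx = traj.topology.atoms["residue_index"].to_numpy()
    with open(path, "w") as fh:
        fh.write("# frame atom residue x y z\n")
        for f in range(traj.n_frames):
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(f"{f} {a} {res_idx[a]} {x:.3f} {y:.3f} {z:.3f}\n")


def read_coordinate_table(path: str, topology: Topology) -> Trajectory:
    """Read the plain table format back against a known topology."""
    data = np.loadtxt(path, comments="#")
    if data.size == 0:
        raise TrajectoryError(f"no coordinate rows in {path}")
    data = np.atleast_2d(data)
    n_atoms = topology.n_atoms
    if len(data) % n_atoms:
        raise TrajectoryError(
            f"row count {len(data)} in {path} is not a multiple of the "
            f"topology atom count {n_atoms}"
        )
    n_frames = len(data) // n_atoms
    coords = np.empty((n_frames, n_atoms, 3))
    frames = data[:, 0].astype(int)
    atoms = data[:, 1].astype(int)
    coords[frames, atoms] = data[:, 3:6]
    return Trajectory(coords=coords, topology=topology,
                      provenance=[dict(source=path)])
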