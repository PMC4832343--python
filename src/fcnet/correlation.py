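"""Residue-residue fluctuation correlations and coordinate PCA.

The central quantity is the normalized covariance of 3-D displacement
vectors,

    C_ij = <dr_i · dr_j> / sqrt(<dr_i^2> <dr_j^2>),

with dr_i(t) = r_i(t) - <r_i> the displacement of node i from its time
average and <.> the uniform average over the configured frame window.  The
same node covariance machinery backs the principal-component analysis of the
3n-dimensional coordinate fluctuations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory import NodeMap, Trajectory

__all__ = [
    "CorrelationMatrix",
    "PcaResult",
    "correlation_matrix",
    "correlation_difference",
    "pca",
    "save_matrix",
    "load_matrix",
]


@dataclass
class CorrelationMatrix:
    """Symmetric n x n correlation matrix with provenance.

    Rows/columns of zero-fluctuation nodes are NaN (undefined, never silently
    zero); ``defined`` flags them.
    """

    C: np.ndarray
    cov: np.ndarray
    labels: list
    n_frames: int
    node_rule: str = "alpha_carbon"
    defined: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, float)
        self.cov = np.asarray(self.cov, float)
        n = len(self.labels)
        if self.C.shape != (n, n) or self.cov.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if self.defined is None:
            self.defined = ~np.isnan(self.C).all(axis=0)
        self.defined = np.asarray(self.defined, bool)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def value(self, i: int, j: int) -> float:
        return float(self.C[i, j])


def correlation_matrix(traj: Trajectory, node_map: NodeMap,
                       frame_slice: slice | None = None) -> CorrelationMatrix:
    """Estimate the fluctuation correlation matrix over node points.

    The trajectory is expected to be superposed already (fit to a common
    reference); the estimator itself is a plain time average with uniform
    weights.  Nodes with zero positional variance yield NaN rows/columns and
    a warning.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate correlations")
    coords = traj.coords if frame_slice is None else traj.coords[frame_slice]
    pos = node_map.node_positions(coords)            # (F, n, 3)
    d = pos - pos.mean(axis=0, keepdims=True)
    F = d.shape[0]
    cov = np.einsum("fid,fjd->ij", d, d) / F          # <dr_i . dr_j>, Å^2
    var = np.diag(cov).copy()
    defined = var > 1e-300
    if not defined.all():
        bad = [node_map.labels[i] for i in np.flatnonzero(~defined)]
        warnings.warn(
            f"nodes with zero fluctuation have undefined correlations: {bad}",
            RuntimeWarning, stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.sqrt(np.outer(var, var))
        C = np.where(norm > 0, cov / np.where(norm > 0, norm, 1.0), np.nan)
    C[~defined, :] = np.nan
    C[:, ~defined] = np.nan
    C = np.clip(C, -1.0, 1.0)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, np.where(defined, 1.0, np.nan))
    return CorrelationMatrix(
        C=C, cov=cov, labels=list(node_map.labels), n_frames=F,
        node_rule=node_map.node_rule, defined=defined,
    )


def correlation_difference(a: CorrelationMatrix, b: CorrelationMatrix,
                           threshold: float):
    """Nodes whose correlation with >= 1 partner changed by more than
    ``threshold`` between two conditions.

    Returns ``(labels, count, pairs)`` where ``pairs`` lists the offending
    (i, j, delta) triples.
    """
    if a.labels != b.labels:
        raise ValueError("correlation matrices cover different node sets")
    delta = np.abs(a.C - b.C)
    np.fill_diagonal(delta, 0.0)
    with np.errstate(invalid="ignore"):
        mask = delta > threshold
    mask &= ~np.isnan(delta)
    nodes = sorted(set(np.flatnonzero(mask.any(axis=1))))
    labels = [a.labels[i] for i in nodes]
    ii, jj = np.nonzero(np.triu(mask, 1))
    pairs = [(a.labels[i], a.labels[j], float(delta[i, j]))
             for i, j in zip(ii, jj)]
    return labels, len(labels), pairs


@dataclass
class PcaResult:
    """Eigen-decomposition of the 3n-coordinate covariance."""

    eigenvalues: np.ndarray        # Å^2, descending
    eigenvectors: np.ndarray       # (3n, k), columns
    variance_fractions: np.ndarray
    projections: np.ndarray        # (F, k)
    labels: list


def pca(traj: Trajectory, node_map: NodeMap,
        n_components: int | None = None) -> PcaResult:
    """PCA of node-coordinate fluctuations via SVD of the centered matrix.

    Eigenvalues are the variances (Å^2) along the principal modes; variance
    fractions are computed over the full spectrum regardless of how many
    components are returned; projections are the centered coordinates dotted
    onto each retained eigenvector.
    """
    pos = node_map.node_positions(traj.coords)
    F, n, _ = pos.shape
    X = pos.reshape(F, 3 * n)
    dim = 3 * n
    if n_components is None:
        n_components = min(F, dim)
    if n_components > dim:
        raise ValueError(f"n_components {n_components} exceeds 3n = {dim}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / F
    total = eig.sum()
    frac_full = eig / total if total > 0 else np.zeros_like(eig)
    k = min(n_components, len(eig))
    return PcaResult(
        eigenvalues=eig[:k],
        eigenvectors=Vt[:k].T,
        variance_fractions=frac_full[:k],
        projections=Xc @ Vt[:k].T,
        labels=list(node_map.labels),
    )


def save_matrix(cm: CorrelationMatrix, path: str, labels_path: str | None = None):
    """Dense whitespace text matrix (or .npy); node labels as a sidecar TSV."""
    if path.endswith(".npy"):
        np.save(path, cm.C)
    else:
        header = f"n_frames={cm.n_frames} node_rule={cm.node_rule}"
        np.savetxt(path, cm.C, fmt="%.10g", header=header)
    if labels_path:
        with open(labels_path, "w") as fh:
            fh.write("node\tlabel\n")
            for i, lab in enumerate(cm.labels):
                fh.write(f"{i}\t{lab}\n")


def load_matrix(path: str, labels=None) -> CorrelationMatrix:
    if path.endswith(".npy"):
        C = np.atleast_2d(np.load(path))
    else:
        C = np.atleast_2d(np.loadtxt(path))
    n = C.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    return CorrelationMatrix(C=C, cov=C.copy(), labels=list(labels), n_frames=0)
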