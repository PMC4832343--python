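"""Rigid-body superposition and fluctuation analytics.

Covers the standard trajectory descriptors that frame a correlation-network
study: least-squares (Kabsch) superposition, per-residue RMSF profiles and
their statistical comparison (Wilcoxon signed-rank across residues for whole
profiles, rank-sum across replicates per residue), the 8 x 8 Rg x RMSD
energy-landscape histogram, and the residue-pair distance-difference map
between two conditions.

RMSF profiles only make sense after superposition removes global rigid-body
motion; :func:`superpose_to_mean` implements the convention used here — fit
to the time-averaged structure, iterated twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectory import NodeMap, Trajectory

__all__ = [
    "FluctuationProfile",
    "EnergyLandscape",
    "WilcoxonResult",
    "kabsch",
    "superpose",
    "superpose_to_mean",
    "rmsf",
    "mean_rmsf",
    "rg_series",
    "rmsd_series",
    "wilcoxon_profiles",
    "significant_regions",
    "energy_landscape",
    "distance_difference_landscape",
]


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None):
    """Optimal proper rotation + translation mapping ``mobile`` onto
    ``reference`` (least-squares, det(R) = +1).

    Raises ``ValueError`` for degenerate (collinear or fewer than 3 distinct)
    point sets, where the rotation is underdetermined.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check on the reference selection
    s_ref = np.linalg.svd(Q0 * np.sqrt(w)[:, None], compute_uv=False)
    if len(s_ref) < 2 or s_ref[1] < 1e-8 * max(s_ref[0], 1.0):
        raise ValueError("degenerate (collinear) selection: rotation undetermined")
    H = (w[:, None] * P0).T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def superpose(traj: Trajectory, reference: np.ndarray,
              selection: np.ndarray | None = None) -> Trajectory:
    """Least-squares fit every frame to ``reference`` on ``selection`` atoms.

    ``reference`` is an ``(n_atoms, 3)`` coordinate set; ``selection`` is an
    integer atom-index array (default: all atoms).  Returns a new trajectory;
    the input is unchanged.
    """
    reference = np.asarray(reference, float)
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    out = np.empty_like(traj.coords)
    ref_sel = reference[selection]
    for f in range(traj.n_frames):
        R, t = kabsch(traj.coords[f, selection], ref_sel)
        out[f] = traj.coords[f] @ R.T + t
    return traj.with_coords(out)


def superpose_to_mean(traj: Trajectory, selection: np.ndarray | None = None,
                      n_iter: int = 2) -> Trajectory:
    """Superpose to the time-averaged structure, iterated ``n_iter`` times.

    Iteration makes the reference self-consistent: the mean is recomputed
    after each fit.  Two rounds are sufficient in practice.
    """
    current = superpose(traj, traj.coords[0], selection)
    for _ in range(n_iter):
        current = superpose(current, current.coords.mean(axis=0), selection)
    return current


# ---------------------------------------------------------------------------
# fluctuation profiles


@dataclass
class FluctuationProfile:
    """Per-residue RMSF (Å) with node labels."""

    values: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 1 or len(self.values) != len(self.labels):
            raise ValueError("profile length must equal label count")
        if (self.values < 0).any():
            raise ValueError("RMSF cannot be negative")


def rmsf(traj: Trajectory, node_map: NodeMap) -> FluctuationProfile:
    """RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>) over frames, per node.

    Assumes a superposed trajectory; a single frame is an error.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    pos = node_map.node_positions(traj.coords)
    d = pos - pos.mean(axis=0, keepdims=True)
    vals = np.sqrt(np.einsum("fid,fid->i", d, d) / traj.n_frames)
    return FluctuationProfile(values=vals, labels=list(node_map.labels))


def mean_rmsf(profile: FluctuationProfile) -> float:
    """Arithmetic mean RMSF over nodes (Å)."""
    return float(profile.values.mean())


def rg_series(traj: Trajectory, selection: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted radius of gyration per frame (Å)."""
    if selection is None:
        selection = np.arange(traj.n_atoms)
    m = traj.topology.atoms["mass"].to_numpy(float)[selection]
    w = m / m.sum()
    xyz = traj.coords[:, selection, :]
    com = np.einsum("fad,a->fd", xyz, w)
    d2 = np.einsum("fad,fad->fa", xyz - com[:, None, :], xyz - com[:, None, :])
    return np.sqrt(np.einsum("fa,a->f", d2, w))


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: np.ndarray | None = None,
                fit: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference structure, optionally after fitting."""
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, int)
    work = superpose(traj, np.asarray(reference, float), selection) if fit else traj
    d = work.coords[:, selection, :] - np.asarray(reference, float)[selection]
    return np.sqrt(np.einsum("fad,fad->f", d, d) / len(selection))


# ---------------------------------------------------------------------------
# statistical comparison


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float
    mode: str
    degenerate: bool = False


def _exact_signed_rank_p(d: np.ndarray) -> tuple:
    """Exact two-sided signed-rank p-value by sign-flip enumeration.

    Under H0 every sign pattern of the (nonzero) differences is equally
    likely; the null distribution of W+ is built with a generating-function
    convolution over midranks (doubled to integers), which remains exact in
    the presence of tied magnitudes.  Returns (p, W+).
    """
    ranks = stats.rankdata(np.abs(d))          # midranks; ties allowed
    r2 = np.rint(2.0 * ranks).astype(int)       # doubled ranks are integers
    w_obs = int(np.rint(2.0 * ranks[d > 0].sum()))
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r or None]
    counts /= counts.sum()
    p_low = counts[: w_obs + 1].sum()
    p_high = counts[w_obs:].sum()
    p = min(1.0, 2.0 * min(p_low, p_high))
    return float(p), w_obs / 2.0


def wilcoxon_profiles(profile_a, profile_b, mode: str = "paired") -> WilcoxonResult:
    """Two-sided Wilcoxon comparison of two RMSF profiles.

    ``paired`` runs the signed-rank test across residues (profiles of equal
    length); ``unpaired`` the Mann-Whitney rank-sum.  The exact small-sample
    null is used for n <= 25 (tie-robust, by enumeration), the normal
    approximation with tie correction beyond.  All-zero differences in
    paired mode are degenerate and flagged (p = 1) rather than an error.
    """
    a = np.asarray(getattr(profile_a, "values", profile_a), float)
    b = np.asarray(getattr(profile_b, "values", profile_b), float)
    if mode == "paired":
        if len(a) != len(b):
            raise ValueError("paired mode requires equal-length profiles")
        d = a - b
        if np.all(d == 0):
            return WilcoxonResult(1.0, 0.0, mode, degenerate=True)
        nz = d[d != 0]
        if len(nz) <= 25:
            p, stat = _exact_signed_rank_p(nz)
            return WilcoxonResult(p, stat, mode)
        res = stats.wilcoxon(a, b, alternative="two-sided",
                             zero_method="wilcox",
                             method="approx", correction=True)
        return WilcoxonResult(float(res.pvalue), float(res.statistic), mode)
    if mode == "unpaired":
        pooled = np.concatenate([a, b])
        ties = len(np.unique(pooled)) < len(pooled)
        method = ("exact" if (max(len(a), len(b)) <= 25 and not ties)
                  else "asymptotic")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return WilcoxonResult(float(res.pvalue), float(res.statistic), mode)
    raise ValueError(f"unknown mode {mode!r}")


def significant_regions(profiles_a, profiles_b, alpha: float = 0.05,
                        labels=None):
    """Residue ranges where replicate RMSF differs between two conditions.

    ``profiles_a`` / ``profiles_b`` are (replicates x residues) arrays (or
    lists of profiles); each residue is tested with the unpaired rank-sum
    across replicates, and consecutive residues with p < alpha are merged
    into (start, stop) index ranges (inclusive).
    """
    A = np.vstack([np.asarray(getattr(p, "values", p), float) for p in profiles_a])
    B = np.vstack([np.asarray(getattr(p, "values", p), float) for p in profiles_b])
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 replicates per condition")
    if A.shape[1] != B.shape[1]:
        raise ValueError("conditions cover different residue counts")
    n_res = A.shape[1]
    pvals = np.ones(n_res)
    for i in range(n_res):
        if np.all(A[:, i] == A[0, i]) and np.all(B[:, i] == A[0, i]):
            continue  # identical constants: no evidence of difference
        pvals[i] = wilcoxon_profiles(A[:, i], B[:, i], mode="unpaired").p_value
    sig = pvals < alpha
    regions = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            regions.append((start, i - 1))
            start = None
    if start is not None:
        regions.append((start, n_res - 1))
    if labels is not None:
        regions = [(labels[i], labels[j]) for i, j in regions]
    return regions, pvals


# ---------------------------------------------------------------------------
# landscapes


@dataclass
class EnergyLandscape:
    """Normalized 8 x 8 (by default) joint histogram over (Rg, RMSD)."""

    probabilities: np.ndarray
    rg_edges: np.ndarray
    rmsd_edges: np.ndarray
    frame_bins: np.ndarray        # (F, 2) bin index per frame

    @property
    def lowest_energy_bin(self):
        """Index pair of the most populated (lowest free energy) bin."""
        return tuple(np.unravel_index(np.argmax(self.probabilities),
                                      self.probabilities.shape))

    def members(self, bin_index=None) -> np.ndarray:
        """Frame indices that fall in a bin (default: lowest-energy bin)."""
        if bin_index is None:
            bin_index = self.lowest_energy_bin
        i, j = bin_index
        return np.flatnonzero((self.frame_bins[:, 0] == i)
                              & (self.frame_bins[:, 1] == j))

    def minus_ln_p(self) -> np.ndarray:
        """-ln(P) with empty bins mapped to +inf."""
        with np.errstate(divide="ignore"):
            return -np.log(self.probabilities)


def energy_landscape(rg: np.ndarray, rmsd: np.ndarray,
                     n_bins: int = 8) -> EnergyLandscape:
    """Joint equal-width histogram of (Rg, RMSD), normalized to sum 1."""
    rg = np.asarray(rg, float)
    rmsd = np.asarray(rmsd, float)
    if rg.shape != rmsd.shape or rg.ndim != 1:
        raise ValueError("Rg and RMSD series must be equal-length 1-D arrays")
    if np.ptp(rg) == 0 or np.ptp(rmsd) == 0:
        raise ValueError("constant series: zero range cannot be binned")
    counts, rg_edges, rmsd_edges = np.histogram2d(rg, rmsd, bins=n_bins)
    probs = counts / counts.sum()
    bi = np.clip(np.searchsorted(rg_edges, rg, side="right") - 1, 0, n_bins - 1)
    bj = np.clip(np.searchsorted(rmsd_edges, rmsd, side="right") - 1, 0, n_bins - 1)
    return EnergyLandscape(
        probabilities=probs,
        rg_edges=rg_edges,
        rmsd_edges=rmsd_edges,
        frame_bins=np.stack([bi, bj], axis=1),
    )


def distance_difference_landscape(traj_a: Trajectory, traj_b: Trajectory,
                                  node_map: NodeMap) -> np.ndarray:
    """D_ij = <d_ij>_a - <d_ij>_b of node-point distances (Å).

    Antisymmetric under swapping the two trajectories; zero diagonal.  Both
    trajectories must resolve the same node set under ``node_map``.
    """
    if traj_a.topology.n_residues != traj_b.topology.n_residues:
        raise ValueError("trajectories cover different node sets")

    def mean_dist(traj):
        pos = node_map.node_positions(traj.coords)
        diff = pos[:, :, None, :] - pos[:, None, :, :]
        return np.sqrt(np.einsum("fijd,fijd->fij", diff, diff)).mean(axis=0)

    return mean_dist(traj_a) - mean_dist(traj_b)
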