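"""Superposition, RMSF analytics, Wilcoxon comparisons and landscapes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy import stats

from fcnet.fluctuation import (
    distance_difference_landscape,
    energy_landscape,
    kabsch,
    mean_rmsf,
    rg_series,
    rmsd_series,
    rmsf,
    significant_regions,
    superpose,
    superpose_to_mean,
    wilcoxon_profiles,
)
from fcnet.synthetic import make_two_block_system, sample_trajectory
from fcnet.trajectory import Trajectory, make_node_map

from conftest import simple_residue, toy_trajectory


def _four_atom_traj(frames):
    rows = []
    for i in range(4):
        rows += simple_residue(i, i + 1, "ALA", chr(ord("A") + i),
                               [("CA", "C", 12.0)])
    return toy_trajectory(rows, frames)


REF4 = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0]])


class TestSuperpose:
    def test_identity_frame_rmsd_zero(self):
        traj = _four_atom_traj([REF4])
        out = superpose(traj, REF4)
        assert rmsd_series(out, REF4, fit=False)[0] < 1e-12

    def test_rigid_rotation_removed(self):
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = REF4 @ R.T + np.array([5.0, -2.0, 1.0])
        traj = _four_atom_traj([moved])
        out = superpose(traj, REF4)
        assert rmsd_series(out, REF4, fit=False)[0] < 1e-10

    def test_fitted_rmsd_matches_independent_kabsch(self):
        # known displacement: one atom moved; oracle is scipy's
        # Rotation.align_vectors weighted Kabsch
        frame = REF4.copy()
        frame[3] += [0.5, -0.2, 0.4]
        rot, rssd = Rotation.align_vectors(
            REF4 - REF4.mean(0), frame - frame.mean(0))
        expected = rssd / np.sqrt(4)
        traj = _four_atom_traj([frame])
        got = rmsd_series(traj, REF4, fit=True)[0]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_proper_rotation_enforced(self):
        frame = REF4 * np.array([-1.0, 1.0, 1.0])  # mirrored
        R, t = kabsch(frame, REF4)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_selection_errors(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
                         [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)

    def test_empty_selection_errors(self):
        traj = _four_atom_traj([REF4])
        with pytest.raises(ValueError, match="empty"):
            superpose(traj, REF4, selection=np.array([], int))


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        traj = _four_atom_traj([REF4] * 10)
        nm = make_node_map(traj.topology)
        assert np.allclose(rmsf(traj, nm).values, 0.0)

    def test_single_frame_errors(self):
        traj = _four_atom_traj([REF4])
        nm = make_node_map(traj.topology)
        with pytest.raises(ValueError):
            rmsf(traj, nm)

    def test_mirrored_frames_give_half_displacement(self):
        delta = np.array([0.3, 0.4, 0.0])
        traj = _four_atom_traj([REF4 + delta, REF4 - delta])
        nm = make_node_map(traj.topology)
        assert np.allclose(rmsf(traj, nm).values, 0.5)  # |delta| = 0.5

    def test_iid_gaussian_limit_sigma_sqrt3(self):
        # no refit: displacement SD sigma per axis gives RMSF -> sigma*sqrt(3)
        rng = np.random.default_rng(42)
        sigma = 0.7
        frames = REF4[None] + rng.normal(0, sigma, (10_000, 4, 3))
        traj = _four_atom_traj(frames)
        nm = make_node_map(traj.topology)
        vals = rmsf(traj, nm).values
        assert np.allclose(vals, sigma * np.sqrt(3), rtol=0.03)

    def test_mean_rmsf(self):
        traj = _four_atom_traj([REF4] * 3)
        nm = make_node_map(traj.topology)
        prof = rmsf(traj, nm)
        prof.values[:] = [1.0, 2.0, 3.0, 2.0]
        assert mean_rmsf(prof) == pytest.approx(2.0)

    def test_rmsf_invariant_under_global_rigid_motion(self):
        sys_ = make_two_block_system(n_frames=50, seed=6)
        traj = sample_trajectory(sys_)
        nm = make_node_map(traj.topology)
        base = rmsf(superpose_to_mean(traj), nm).values
        R = Rotation.from_euler("zyx", [1.0, 0.2, -0.4]).as_matrix()
        moved = traj.with_coords(traj.coords @ R.T + np.array([3.0, 1.0, -2.0]))
        again = rmsf(superpose_to_mean(moved), nm).values
        np.testing.assert_allclose(base, again, atol=1e-8)


class TestWilcoxon:
    def test_identical_profiles_degenerate(self):
        a = np.linspace(1, 2, 15)
        res = wilcoxon_profiles(a, a.copy())
        assert res.degenerate and res.p_value == 1.0

    def test_uniform_shift_exact_closed_form(self):
        # 20 equal-magnitude one-sided differences: p = 2 / 2^20
        a = np.arange(1.0, 21.0)
        res = wilcoxon_profiles(a, a + 0.5)
        assert res.p_value == pytest.approx(2.0 ** -19, rel=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.5, 0.3, 18)
        b = a + rng.normal(0.1, 0.2, 18)
        mine = wilcoxon_profiles(a, b).p_value
        ref = stats.wilcoxon(a, b, method="exact",
                             alternative="two-sided").pvalue
        assert mine == pytest.approx(float(ref), rel=1e-12)

    def test_unpaired_null_p_uniform(self):
        # repeated null draws: KS test against U(0,1) should not reject
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            x = rng.normal(0, 1, 200)
            y = rng.normal(0, 1, 200)
            ps.append(wilcoxon_profiles(x, y, mode="unpaired").p_value)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_unequal_lengths_rejected_in_paired_mode(self):
        with pytest.raises(ValueError):
            wilcoxon_profiles(np.ones(5), np.ones(6))


class TestSignificantRegions:
    @staticmethod
    def _replicates(rng, n_rep, n_res, bump=None, scale=0.1):
        out = []
        for _ in range(n_rep):
            prof = 1.0 + rng.normal(0, scale, n_res)
            if bump is not None:
                lo, hi = bump
                prof[lo:hi + 1] += 1.0
            out.append(np.abs(prof))
        return out

    def test_identical_sets_give_no_regions(self):
        rng = np.random.default_rng(0)
        a = self._replicates(rng, 5, 30)
        regions, _ = significant_regions(a, [p.copy() for p in a])
        assert regions == []

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(1)
        a = self._replicates(rng, 5, 30)
        b = self._replicates(rng, 5, 30, bump=(10, 17))
        regions, _ = significant_regions(a, b)
        assert regions == [(10, 17)]

    def test_alpha_zero_gives_nothing(self):
        rng = np.random.default_rng(2)
        a = self._replicates(rng, 5, 20)
        b = self._replicates(rng, 5, 20, bump=(5, 9))
        regions, _ = significant_regions(a, b, alpha=0.0)
        assert regions == []

    def test_alpha_one_gives_everything_and_monotone(self):
        rng = np.random.default_rng(3)
        a = self._replicates(rng, 5, 20)
        b = self._replicates(rng, 5, 20, bump=(5, 9))
        full, _ = significant_regions(a, b, alpha=1.0000001)
        assert full == [(0, 19)]

        def covered(regions):
            s = set()
            for lo, hi in regions:
                s.update(range(lo, hi + 1))
            return s

        prev = covered(full)
        for alpha in (0.5, 0.05, 0.01):
            cur = covered(significant_regions(a, b, alpha=alpha)[0])
            assert cur <= prev
            prev = cur

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError):
            significant_regions([np.ones(5)], [np.ones(5), np.ones(5)])


class TestEnergyLandscape:
    def test_probabilities_sum_to_one_and_tight_cluster(self):
        rng = np.random.default_rng(5)
        rg = 10.0 + rng.normal(0, 1e-6, 500)
        rg[0] = 10.001  # break zero range
        rmsd = 2.0 + rng.normal(0, 1e-6, 500)
        rmsd[0] = 2.001
        ls = energy_landscape(rg, rmsd)
        assert ls.probabilities.sum() == pytest.approx(1.0)
        assert ls.probabilities.max() >= 499 / 500

    def test_uniform_grid_fills_bins_equally(self):
        centers = (np.arange(8) + 0.5) / 8
        rg, rmsd = np.meshgrid(centers, centers)
        ls = energy_landscape(rg.ravel(), rmsd.ravel())
        np.testing.assert_allclose(ls.probabilities, 1 / 64)

    def test_bimodal_argmax_matches_manual_histogram(self):
        rng = np.random.default_rng(7)
        rg = np.concatenate([rng.normal(10, 0.1, 300), rng.normal(12, 0.1, 700)])
        rmsd = np.concatenate([rng.normal(1, 0.05, 300), rng.normal(2, 0.05, 700)])
        ls = energy_landscape(rg, rmsd)
        counts = np.zeros((8, 8))
        for x, y in zip(rg, rmsd):
            i = min(int((x - rg.min()) / (np.ptp(rg) / 8)), 7)
            j = min(int((y - rmsd.min()) / (np.ptp(rmsd) / 8)), 7)
            counts[i, j] += 1
        assert ls.lowest_energy_bin == tuple(
            np.unravel_index(np.argmax(counts), (8, 8)))
        members = ls.members()
        assert len(members) == counts.max()

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            energy_landscape(np.ones(10), np.arange(10.0))

    def test_rg_series_point_mass_cases(self):
        traj = _four_atom_traj([REF4])
        rg = rg_series(traj)
        com = REF4.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((REF4 - com) ** 2, axis=1)))
        assert rg[0] == pytest.approx(expected)


class TestDistanceDifference:
    def test_equal_trajectories_zero(self):
        traj = _four_atom_traj([REF4] * 3)
        nm = make_node_map(traj.topology)
        D = distance_difference_landscape(traj, traj, nm)
        np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_swap_negates(self):
        t1 = _four_atom_traj([REF4] * 2)
        t2 = _four_atom_traj([REF4 * 1.1] * 2)
        nm = make_node_map(t1.topology)
        D = distance_difference_landscape(t1, t2, nm)
        Dswap = distance_difference_landscape(t2, t1, nm)
        np.testing.assert_allclose(D, -Dswap, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)

    def test_three_node_hand_computed(self):
        rows = []
        for i in range(3):
            rows += simple_residue(i, i + 1, "ALA", chr(ord("A") + i),
                                   [("CA", "C", 12.0)])
        a = toy_trajectory(rows, [[[0.0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]]])
        b = toy_trajectory(rows, [[[0.0, 0, 0], [4.0, 0, 0], [0, 4.0, 0]]])
        nm = make_node_map(a.topology)
        D = distance_difference_landscape(a, b, nm)
        assert D[0, 1] == pytest.approx(-1.0)
        assert D[0, 2] == pytest.approx(0.0)
        assert D[1, 2] == pytest.approx(5.0 - np.sqrt(32))
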