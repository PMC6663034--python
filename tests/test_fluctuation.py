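"""Superposition, RMSD/RMSF, PCA and TICA."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from memsorb.fluctuation import (B_FACTOR_PREFACTOR, correlation_matrix,
                                 pca_modes, rmsd_series, rmsf_profile,
                                 superpose, tica_modes)
from memsorb.structio import Trajectory
from memsorb.synthetic import PlantedTrajectorySpec, make_planted_trajectory


def _coords(rng, n=20):
    return rng.normal(scale=5.0, size=(n, 3))


class TestSuperpose:
    def test_identity(self, rng):
        x = _coords(rng)
        rot, trans, rmsd = superpose(x, x)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)
        assert rmsd < 1e-9

    def test_known_rotation_recovered(self, rng):
        x = _coords(rng)
        r_true = Rotation.from_rotvec([0.4, -1.1, 0.7]).as_matrix()
        mobile = x @ r_true.T + np.array([3.0, -2.0, 8.0])
        rot, trans, rmsd = superpose(mobile, x)
        assert rmsd < 1e-9
        np.testing.assert_allclose(rot, r_true.T, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_noisy_pair_matches_quaternion_optimizer(self, rng):
        """Kabsch result equals direct numerical minimisation over
        rotations parameterised by rotation vectors."""
        from scipy.optimize import minimize

        x = _coords(rng)
        y = x + rng.normal(scale=0.4, size=x.shape)
        _, _, rmsd = superpose(y, x)

        yc = y - y.mean(axis=0)
        xc = x - x.mean(axis=0)

        def cost(rv):
            r = Rotation.from_rotvec(rv).as_matrix()
            return np.sqrt(((yc @ r.T - xc) ** 2).sum(axis=1).mean())

        best = min(minimize(cost, v0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 4000}).fun
                   for v0 in ([0.0, 0, 0], [1.0, 0.5, -0.5], [-1, 1, 1]))
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_matches_mdanalysis_oracle(self, rng):
        mda = pytest.importorskip("MDAnalysis.analysis.rms")
        x = _coords(rng)
        y = x + rng.normal(scale=0.5, size=x.shape)
        _, _, rmsd = superpose(y, x)
        ref = mda.rmsd(y, x, center=True, superposition=True)
        assert rmsd == pytest.approx(ref, abs=1e-6)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self, rng):
        x = _coords(rng)
        traj = Trajectory(_topology(len(x)), np.repeat(x[None], 5, axis=0))
        np.testing.assert_allclose(rmsd_series(traj, x), 0.0, atol=1e-9)

    def test_uniform_displacement_without_alignment(self, rng):
        x = _coords(rng)
        d = 2.5
        frames = (x + np.array([0, 0, d]))[None]
        traj = Trajectory(_topology(len(x)), frames)
        rmsd = rmsd_series(traj, x, align=False)
        assert rmsd[0] == pytest.approx(d, rel=1e-12)

    def test_brute_force_formula(self, rng):
        x = _coords(rng)
        frames = x[None] + rng.normal(scale=1.0, size=(4, len(x), 3))
        traj = Trajectory(_topology(len(x)), frames)
        series = rmsd_series(traj, x)
        for f in range(4):
            _, _, ref = superpose(frames[f], x)
            assert series[f] == pytest.approx(ref, abs=1e-9)

    def test_invariant_under_global_rigid_motion(self, rng):
        x = _coords(rng)
        frames = x[None] + rng.normal(scale=0.5, size=(3, len(x), 3))
        traj = Trajectory(_topology(len(x)), frames)
        base = rmsd_series(traj, x)
        r = Rotation.from_rotvec([0.5, 0.2, -0.9]).as_matrix()
        moved = Trajectory(_topology(len(x)),
                           frames @ r.T + np.array([4.0, 5.0, -1.0]))
        np.testing.assert_allclose(rmsd_series(moved, x), base, atol=1e-8)


def _topology(n):
    from memsorb.structio import AtomicStructure
    return AtomicStructure(
        serial=np.arange(1, n + 1), name=["CA"] * n, element=["C"] * n,
        res_name=["ALA"] * n, res_id=np.arange(1, n + 1),
        chain_id=["A"] * n, coords=np.zeros((n, 3)))


class TestRmsf:
    def test_static_trajectory_zero(self):
        spec = PlantedTrajectorySpec(n_frames=10, n_residues=12, sigma=0.0,
                                     seed=0)
        traj, _ = make_planted_trajectory(spec)
        prof = rmsf_profile(traj)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-9)
        np.testing.assert_allclose(prof.b_factor, 0.0, atol=1e-9)

    def test_planted_isotropic_sigma(self):
        # rigid-body superposition absorbs 6 of the 3N noise dimensions,
        # biasing the RMSF by ~1/N, so the residue count must be large for
        # the sigma*sqrt(3) identity to hold at the 2% level
        sigma = 0.5
        spec = PlantedTrajectorySpec(n_frames=4000, n_residues=100,
                                     sigma=sigma, seed=21)
        traj, _ = make_planted_trajectory(spec)
        prof = rmsf_profile(traj)
        expected = sigma * np.sqrt(3.0)
        assert np.mean(prof.rmsf) == pytest.approx(expected, rel=0.02)

    def test_b_factor_relation(self):
        spec = PlantedTrajectorySpec(n_frames=200, n_residues=10, sigma=0.7,
                                     seed=3)
        traj, _ = make_planted_trajectory(spec)
        prof = rmsf_profile(traj)
        np.testing.assert_allclose(prof.b_factor,
                                   8 * np.pi**2 / 3 * prof.rmsf**2,
                                   rtol=1e-12)
        assert B_FACTOR_PREFACTOR * 1.0**2 == pytest.approx(26.32, abs=0.01)

    def test_too_few_frames_rejected(self):
        spec = PlantedTrajectorySpec(n_frames=1, n_residues=10, seed=1)
        traj, _ = make_planted_trajectory(spec)
        with pytest.raises(ValueError):
            rmsf_profile(traj)


class TestPCA:
    def test_single_direction_of_variance(self, rng):
        n, f = 10, 200
        base = _coords(rng, n)
        direction = np.zeros((n, 3))
        direction[4, 0] = 1.0
        amp = rng.normal(size=f)
        frames = base[None] + amp[:, None, None] * direction[None]
        traj = Trajectory(_topology(n), frames)
        # frames share a coordinate frame already; with alignment skipped
        # the single planted direction is the only source of variance
        dec = pca_modes(traj, align=False)
        assert dec.eigenvalues[0] > 0
        assert dec.eigenvalues[1] == pytest.approx(0.0, abs=1e-8)
        flat = direction.ravel() / np.linalg.norm(direction)
        assert abs(np.dot(dec.modes[0], flat)) > 0.999999

    def test_planted_modes_recovered(self):
        spec = PlantedTrajectorySpec(n_frames=10_000, n_residues=20,
                                     sigma=0.05, mode_amplitudes=(1.0, 0.5),
                                     seed=12)
        traj, gt = make_planted_trajectory(spec)
        dec = pca_modes(traj)
        for k in range(2):
            cos = abs(np.dot(dec.modes[k], gt.modes[k]))
            assert cos > 0.99
        ratio = dec.eigenvalues[0] / dec.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_eigenvalue_sum_is_total_variance(self):
        spec = PlantedTrajectorySpec(n_frames=300, n_residues=15, sigma=0.4,
                                     mode_amplitudes=(0.8,), seed=4)
        traj, _ = make_planted_trajectory(spec)
        dec = pca_modes(traj)
        from memsorb.fluctuation import align_frames
        aligned = align_frames(traj)
        x = aligned.reshape(300, -1)
        total = ((x - x.mean(axis=0)) ** 2).mean(axis=0).sum()
        assert dec.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_projections_zero_mean(self):
        spec = PlantedTrajectorySpec(n_frames=100, n_residues=10, sigma=0.3,
                                     seed=6)
        traj, _ = make_planted_trajectory(spec)
        dec = pca_modes(traj)
        np.testing.assert_allclose(dec.projections.mean(axis=0), 0.0,
                                   atol=1e-9)


class TestCorrelationMatrix:
    def _decomp(self):
        spec = PlantedTrajectorySpec(n_frames=500, n_residues=12, sigma=0.3,
                                     mode_amplitudes=(1.0,), seed=9)
        traj, _ = make_planted_trajectory(spec)
        return pca_modes(traj), traj

    def test_unit_diagonal_and_symmetry(self):
        dec, _ = self._decomp()
        c = correlation_matrix(dec)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-8)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert np.abs(c).max() <= 1.0 + 1e-9

    def test_all_modes_equal_direct_computation(self):
        dec, traj = self._decomp()
        c = correlation_matrix(dec)
        from memsorb.fluctuation import align_frames
        aligned = align_frames(traj)
        dx = aligned - aligned.mean(axis=0)
        n = dx.shape[1]
        cov = np.einsum("fia,fja->ij", dx, dx) / len(dx)
        ref = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        np.testing.assert_allclose(c, ref, atol=1e-8)

    def test_mode_limited_differs(self):
        dec, _ = self._decomp()
        c3 = correlation_matrix(dec, n_modes=1)
        call = correlation_matrix(dec)
        assert not np.allclose(c3, call, atol=1e-3)


class TestTICA:
    def test_two_state_process_recovered(self):
        spec = PlantedTrajectorySpec(n_frames=6000, n_residues=15,
                                     sigma=0.5, two_state_offset=3.0,
                                     switch_rate=0.01, seed=17)
        traj, gt = make_planted_trajectory(spec)
        dec = tica_modes(traj, lag=10)
        r = np.corrcoef(dec.projections[:, 0], gt.state_sequence)[0, 1]
        assert abs(r) > 0.9

    def test_white_noise_has_no_slow_modes(self, rng):
        x = rng.normal(size=(10_000, 8))
        dec = tica_modes(x, lag=10)
        assert np.abs(dec.eigenvalues).max() < 0.05

    def test_generalized_eigenproblem_residual(self, rng):
        # AR(1) features with genuine autocorrelation
        n, d, phi = 5000, 6, 0.8
        x = np.zeros((n, d))
        noise = rng.normal(size=(n, d))
        for t in range(1, n):
            x[t] = phi * x[t - 1] + noise[t]
        lag = 5
        dec = tica_modes(x, lag=lag, regularization=1e-8)
        mean = x.mean(axis=0)
        a, b = x[:-lag] - mean, x[lag:] - mean
        c0 = (a.T @ a + b.T @ b) / (2 * len(a))
        ct = (a.T @ b + b.T @ a) / (2 * len(a))
        c0r = c0 + 1e-8 * np.trace(c0) / d * np.eye(d)
        for k in range(dec.n_modes):
            v = dec.modes[k]
            resid = np.linalg.norm(ct @ v - dec.eigenvalues[k] * (c0r @ v))
            assert resid < 1e-8 * np.linalg.norm(ct @ v + 1e-30)

    def test_reversible_eigenvalues_bounded(self, rng):
        x = rng.normal(size=(3000, 5))
        dec = tica_modes(x, lag=3)
        assert np.all(dec.eigenvalues <= 1.0 + 1e-6)
        assert np.all(np.isreal(dec.eigenvalues))

    def test_segments_never_lag_across_boundaries(self, rng):
        """Segment-aware estimates equal an explicit within-segment oracle
        and differ from treating the concatenation as one time series."""
        seg_a = rng.normal(size=(900, 4))
        seg_b = rng.normal(size=(1100, 4)) * 2.0
        lag, reg = 10, 1e-5
        correct = tica_modes([seg_a, seg_b], lag=lag, regularization=reg)
        assert correct.segment_lengths == (900, 1100)

        # oracle: symmetrized covariances from within-segment pairs only
        total = np.vstack([seg_a, seg_b])
        mean = total.mean(axis=0)
        c0 = np.zeros((4, 4))
        ct = np.zeros((4, 4))
        n_pairs = 0
        for seg in (seg_a, seg_b):
            a, b = seg[:-lag] - mean, seg[lag:] - mean
            c0 += a.T @ a + b.T @ b
            ct += a.T @ b + b.T @ a
            n_pairs += 2 * len(a)
        c0 /= n_pairs
        ct /= n_pairs
        c0 += reg * np.trace(c0) / 4 * np.eye(4)
        import scipy.linalg
        ref = np.sort(scipy.linalg.eigh(ct, c0, eigvals_only=True))[::-1]
        np.testing.assert_allclose(correct.eigenvalues, ref, atol=1e-10)

        naive = tica_modes(total, lag=lag, regularization=reg)
        assert not np.allclose(naive.eigenvalues, correct.eigenvalues,
                               atol=1e-6)

    def test_lag_validation(self, rng):
        with pytest.raises(ValueError):
            tica_modes(rng.normal(size=(50, 3)), lag=0)
        with pytest.raises(ValueError):
            tica_modes(rng.normal(size=(5, 3)), lag=10)
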