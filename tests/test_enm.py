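import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from clefscope.enm import (ModeSet, build_hessian, compute_modes,
                           dccm_from_ensemble, dccm_from_modes, ensemble_rmsf,
                           mode_rmsf, normal_modes, sample_mode_ensemble)
from clefscope.errors import (DisconnectedStructureError, PreconditionError,
                              UndefinedCorrelationError)

from conftest import bead_structure


def _dimer():
    return bead_structure([(0, 0, 0), (1, 0, 0)])


def _enm_energy(coords, ref, cutoff, gamma):
    """Independent ENM potential: Σ_contacts (γ/2)(|r_ij| − |r⁰_ij|)²."""
    e = 0.0
    n = ref.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            d0 = np.linalg.norm(ref[j] - ref[i])
            if d0 <= cutoff:
                d = np.linalg.norm(coords[j] - coords[i])
                e += 0.5 * gamma * (d - d0) ** 2
    return e


class TestHessian:
    def test_dimer_closed_form(self):
        H = build_hessian(_dimer(), cutoff=2.0, gamma=1.0)
        expected = np.zeros((6, 6))
        expected[0, 0] = expected[3, 3] = 1.0
        expected[0, 3] = expected[3, 0] = -1.0
        assert np.allclose(H, expected)
        evals = np.linalg.eigvalsh(H)
        assert np.allclose(np.sort(evals), [0, 0, 0, 0, 0, 2], atol=1e-12)

    def test_no_contacts_gives_zero_matrix(self):
        s = bead_structure([(0, 0, 0), (50, 0, 0), (0, 70, 0)])
        assert np.count_nonzero(build_hessian(s, cutoff=10.0)) == 0

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 8, (10, 3))
        cutoff, gamma = 6.0, 1.3
        H = build_hessian(bead_structure(ref), cutoff=cutoff, gamma=gamma)
        x0 = ref.reshape(-1)
        h = 1e-4
        num = np.zeros((30, 30))
        for a in range(30):
            for b in range(a, 30):
                def e(da, db):
                    x = x0.copy()
                    x[a] += da
                    x[b] += db
                    return _enm_energy(x.reshape(-1, 3), ref, cutoff, gamma)
                num[a, b] = num[b, a] = (
                    e(h, h) - e(h, -h) - e(-h, h) + e(-h, -h)) / (4 * h * h)
        assert np.abs(H - num).max() < 1e-5

    def test_superblock_row_sums_vanish(self, small_structure):
        s, _ = small_structure
        H = build_hessian(s)
        n = len(s)
        blocks = H.reshape(n, 3, n, 3)
        assert np.abs(blocks.sum(axis=2)).max() < 1e-10


class TestNormalModes:
    def test_dimer_frequencies(self):
        # a dimer has 5 rigid-body modes (no rotation about its own axis)
        # and one stretch mode at ω = √2
        m = normal_modes(build_hessian(_dimer(), cutoff=2.0))
        assert np.allclose(m.frequencies[:5], 0.0, atol=1e-6)
        assert np.isclose(m.frequencies[5], np.sqrt(2.0))

    def test_disconnected_trimers_rejected(self):
        s = bead_structure(np.concatenate([
            np.random.default_rng(0).uniform(0, 3, (3, 3)),
            np.random.default_rng(1).uniform(0, 3, (3, 3)) + 100.0]))
        with pytest.raises(DisconnectedStructureError):
            normal_modes(build_hessian(s, cutoff=8.0))

    def test_matches_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(2)
        s = bead_structure(rng.uniform(0, 12, (30, 3)))
        H = build_hessian(s, cutoff=10.0)
        m = normal_modes(H)
        expected = np.linalg.eigvalsh(H)
        assert np.abs(m.eigenvalues - expected).max() < 1e-8
        # orthonormality of the eigenvector matrix
        G = m.eigenvectors.T @ m.eigenvectors
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-8

    def test_connected_structure_has_exactly_six_zero_modes(self, small_modes):
        assert small_modes.n_zero_modes == 6
        tol = 1e-8 * small_modes.eigenvalues[-1]
        assert small_modes.eigenvalues[6] > tol


class TestModeRmsf:
    def _single_mode_set(self, n=5, hot=2):
        evals = np.concatenate([np.zeros(6), [4.0], np.full(3 * n - 7, 100.0)])
        evecs = np.zeros((3 * n, 3 * n))
        evecs[3 * hot, 6] = 1.0  # all weight on residue `hot`, x-axis
        for k in range(3 * n):
            if k != 6:
                evecs[(k + 1) % (3 * n), k] = 1.0
        return ModeSet(evals, evecs, n, 15.0, 1.0)

    def test_single_mode_localized(self):
        m = self._single_mode_set()
        prof = mode_rmsf(m, (7, 7))
        assert prof.rmsf[2] > 0
        assert np.count_nonzero(prof.rmsf) == 1
        assert np.isclose(prof.rmsf[2], 1 / 2)  # √(1/λ) with λ=4

    def test_constant_profile_has_zero_delta(self):
        prof_rmsf = np.full(10, 0.7)
        from clefscope.enm import FluctuationProfile
        prof = FluctuationProfile(prof_rmsf, "modes")
        assert prof.delta == 0.0
        assert prof.sigma == 0.0

    def test_rigid_body_modes_excluded(self, small_modes):
        with pytest.raises(PreconditionError):
            mode_rmsf(small_modes, (5, 18))

    def test_sign_flip_invariance(self, small_modes):
        prof = mode_rmsf(small_modes)
        flipped = ModeSet(small_modes.eigenvalues.copy(),
                          -small_modes.eigenvectors,
                          small_modes.n_atoms, small_modes.cutoff,
                          small_modes.gamma)
        assert np.allclose(mode_rmsf(flipped).rmsf, prof.rmsf)

    def test_floppy_tail_fluctuates_more(self, small_structure, small_modes):
        s, ann = small_structure
        prof = mode_rmsf(small_modes)
        gh9 = np.array([ann.label_of(r.res_id) == "GH9" for r in s.residues])
        assert prof.rmsf[~gh9].mean() > 2 * prof.rmsf[gh9].mean()

    def test_linker_cbm_ranks_exceed_core(self, small_structure, small_modes):
        """Flexible linker/CBM residues outrank the catalytic core in RMSF."""
        s, ann = small_structure
        prof = mode_rmsf(small_modes)
        gh9 = np.array([ann.label_of(r.res_id) == "GH9" for r in s.residues])
        stat = mannwhitneyu(prof.rmsf[~gh9], prof.rmsf[gh9], alternative="greater")
        assert stat.pvalue < 0.01


class TestEnsembleRmsf:
    def test_identical_frames_zero(self):
        frames = np.tile(np.random.default_rng(0).uniform(0, 9, (7, 3)), (5, 1, 1))
        assert np.allclose(ensemble_rmsf(frames).rmsf, 0.0)

    def test_two_point_oscillation(self):
        base = np.zeros((4, 3))
        up = base.copy()
        up[1, 0] = 1.0
        down = base.copy()
        down[1, 0] = -1.0
        frames = np.array([up, down] * 10)
        prof = ensemble_rmsf(frames)
        assert np.isclose(prof.rmsf[1], 1.0)
        assert np.allclose(np.delete(prof.rmsf, 1), 0.0)

    def test_gaussian_ensemble_closed_form(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 20, (6, 3))
        frames = base + rng.normal(0, 0.5, (10_000, 6, 3))
        prof = ensemble_rmsf(frames)
        assert np.allclose(prof.rmsf, np.sqrt(3) * 0.5, rtol=0.02)

    def test_single_frame_rejected(self):
        with pytest.raises(PreconditionError):
            ensemble_rmsf(np.zeros((1, 5, 3)))


class TestDccm:
    def test_rigid_translations_fully_correlated(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 10, (6, 3))
        frames = base + rng.normal(0, 1, (200, 1, 3))  # shared displacement
        C = dccm_from_ensemble(frames)
        assert np.allclose(C.matrix, 1.0)

    def test_antiphase_pair(self):
        rng = np.random.default_rng(1)
        amp = rng.normal(0, 1, 500)
        frames = np.zeros((500, 2, 3))
        frames[:, 0, 0] = amp
        frames[:, 1, 0] = -amp
        C = dccm_from_ensemble(frames)
        assert np.isclose(C.matrix[0, 1], -1.0)

    def test_zero_variance_residue_rejected(self):
        frames = np.zeros((50, 3, 3))
        frames[:, 0, 0] = np.random.default_rng(2).normal(size=50)
        with pytest.raises(UndefinedCorrelationError, match="2"):
            dccm_from_ensemble(frames)

    def test_mode_dccm_matches_sampled_ensemble(self):
        rng = np.random.default_rng(3)
        s = bead_structure(rng.uniform(0, 10, (20, 3)))
        m = compute_modes(s, cutoff=8.0)
        C_mode = dccm_from_modes(m, (7, 18))
        frames = sample_mode_ensemble(m, 100_000, (7, 18),
                                      rng=np.random.default_rng(4))
        C_ens = dccm_from_ensemble(frames)
        assert np.abs(C_mode.matrix - C_ens.matrix).max() < 0.05

    def test_invariant_under_global_rotation(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(0, 1, (300, 8, 3)) + rng.uniform(0, 20, (1, 8, 3))
        C0 = dccm_from_ensemble(frames)
        q = rng.standard_normal(4)
        w, x, y, z = q / np.linalg.norm(q)
        R = np.array([[1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                      [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                      [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        C1 = dccm_from_ensemble(frames @ R.T)
        assert np.abs(C0.matrix - C1.matrix).max() < 1e-8

    def test_map_invariants(self, small_modes):
        C = dccm_from_modes(small_modes)
        M = C.matrix
        assert np.abs(M - M.T).max() < 1e-10
        assert np.abs(np.diag(M) - 1).max() < 1e-10
        assert M.min() >= -1 and M.max() <= 1
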