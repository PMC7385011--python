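import numpy as np
import pytest

from clefscope.errors import GeometryError, PreconditionError
from clefscope.superposition import (column_ellipsoid_volume, column_volumes,
                                     find_invariant_core, kabsch_superpose,
                                     superpose_ensemble)
from clefscope.synthetic import family_alignment

from conftest import bead_structure


def _rotation(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def _quat_to_matrix(q):
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def _quaternion_zoom_rmsd(mobile, reference, seed=0):
    """Brute-force minimal RMSD by zooming a quaternion grid (oracle)."""
    rng = np.random.default_rng(seed)
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(q):
        R = _quat_to_matrix(q)
        return np.sqrt(((mob @ R.T - ref) ** 2).sum(axis=1).mean())

    best_q, best = None, np.inf
    for q in rng.standard_normal((6000, 4)):
        r = rmsd_of(q)
        if r < best:
            best, best_q = r, q / np.linalg.norm(q)
    for scale in (0.3, 0.1, 0.03, 0.01, 0.003, 0.001, 3e-4):
        for dq in rng.standard_normal((2000, 4)) * scale:
            q = best_q + dq
            r = rmsd_of(q)
            if r < best:
                best, best_q = r, q / np.linalg.norm(q)
    return best


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).uniform(0, 10, (8, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd < 1e-10
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_recovered(self):
        pts = np.random.default_rng(1).uniform(0, 10, (12, 3))
        R = _rotation([0, 0, 1], np.pi / 2)
        moved = pts @ R.T + np.array([5.0, 0.0, 0.0])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd < 1e-6
        assert np.allclose(sup.apply(pts), moved, atol=1e-6)

    def test_proper_rotation_enforced(self):
        pts = np.random.default_rng(2).uniform(0, 10, (10, 3))
        reflected = pts * np.array([1, 1, -1])
        sup = kabsch_superpose(pts, reflected)
        assert np.isclose(np.linalg.det(sup.rotation), 1.0, atol=1e-8)

    def test_matches_quaternion_grid_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 10, (20, 3))
        b = a @ _rotation([1, 2, 3], 0.7).T + rng.normal(0, 0.5, (20, 3))
        sup = kabsch_superpose(a, b)
        assert abs(sup.rmsd - _quaternion_zoom_rmsd(a, b)) < 1e-3

    def test_rmsd_invariant_to_rigid_pretransform(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 10, (15, 3))
        b = rng.uniform(0, 10, (15, 3))
        base = kabsch_superpose(a, b).rmsd
        moved = a @ _rotation([1, 0, 1], 1.1).T + np.array([3, -7, 2.5])
        assert abs(kabsch_superpose(moved, b).rmsd - base) < 1e-8

    def test_too_few_or_degenerate_points(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.stack([np.arange(5.0)] * 3, axis=1)  # collinear
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)


class TestEnsembleSuperposition:
    def _family(self, rng, n=5, length=20, noise=0.0):
        base = rng.uniform(0, 20, (length, 3))
        members = []
        for i in range(n):
            coords = base + rng.normal(0, noise, base.shape)
            R = _rotation(rng.standard_normal(3), rng.uniform(0, np.pi))
            members.append(bead_structure(coords @ R.T + rng.uniform(-9, 9, 3),
                                          name=f"m{i}"))
        return members

    def test_rigid_copies_collapse(self):
        members = self._family(np.random.default_rng(0))
        amap = family_alignment(members)
        block = superpose_ensemble(members, amap)
        spread = block.max(axis=0) - block.min(axis=0)
        assert spread.max() < 1e-8

    def test_translation_removed_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 20, (10, 3))
        a = bead_structure(base, name="a")
        b = bead_structure(base + np.array([12.0, -3.0, 4.0]), name="b")
        amap = family_alignment([a, b])
        block = superpose_ensemble([a, b], amap)
        assert np.abs(block[1] - block[0]).max() < 1e-9

    def test_noisy_spread_matches_direct_covariance(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 30, (25, 3))
        # no rigid motion: superposition onto the first (noise-free) member is
        # near-identity, so column statistics match the direct computation
        members = [bead_structure(base, name="m0")] + [
            bead_structure(base + rng.normal(0, 0.2, base.shape), name=f"m{i}")
            for i in range(1, 30)]
        amap = family_alignment(members)
        block = superpose_ensemble(members, amap)
        direct = np.array([column_ellipsoid_volume(block[:, c]) for c in range(25)])
        assert np.allclose(column_volumes(block), direct, rtol=1e-9)

    def test_empty_fit_set_rejected(self):
        members = self._family(np.random.default_rng(3))
        amap = family_alignment(members)
        with pytest.raises(PreconditionError):
            superpose_ensemble(members, amap, fit_columns=[])


class TestEllipsoidVolume:
    def test_identical_points_zero(self):
        assert column_ellipsoid_volume(np.ones((4, 3))) == 0.0

    def test_unit_covariance_closed_form(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((200, 3))
        pts -= pts.mean(axis=0)
        # whiten so the population covariance is exactly the identity
        cov = pts.T @ pts / len(pts)
        w, v = np.linalg.eigh(cov)
        pts = pts @ v @ np.diag(1 / np.sqrt(w)) @ v.T
        assert np.isclose(column_ellipsoid_volume(pts), 4 / 3 * np.pi, rtol=1e-9)

    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (10, 3))
        centred = pts - pts.mean(axis=0)
        lam = np.linalg.eigvalsh(centred.T @ centred / 10)
        expected = 4 / 3 * np.pi * np.sqrt(np.prod(lam))
        assert np.isclose(column_ellipsoid_volume(pts), expected, rtol=1e-9)

    def test_rotation_invariant(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-5, 5, (12, 3))
        v0 = column_ellipsoid_volume(pts)
        for seed in range(5):
            R = _rotation(np.random.default_rng(seed).standard_normal(3), 1.0 + seed)
            assert np.isclose(column_ellipsoid_volume(pts @ R.T), v0, rtol=1e-9)

    def test_coplanar_points_zero(self):
        pts = np.random.default_rng(3).uniform(0, 5, (8, 3))
        pts[:, 2] = 0.0
        assert column_ellipsoid_volume(pts) < 1e-12


class TestInvariantCore:
    def _planted(self, seed=0, n_members=10, rigid=30, mobile=10):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 40, (rigid + mobile, 3))
        members = []
        for i in range(n_members):
            noise = np.concatenate([rng.normal(0, 0.05, (rigid, 3)),
                                    rng.normal(0, 3.0, (mobile, 3))])
            members.append(bead_structure(base + noise, name=f"m{i}"))
        return members, family_alignment(members)

    def test_identical_structures_keep_all_columns(self):
        base = np.random.default_rng(0).uniform(0, 30, (15, 3))
        members = [bead_structure(base, name=f"m{i}") for i in range(4)]
        amap = family_alignment(members)
        res = find_invariant_core(members, amap, cutoff=1.0, min_core=3)
        assert res.core_columns == list(range(15))
        assert max(res.volumes.values()) < 1e-12
        assert res.removal_order == []

    def test_planted_rigid_core_recovered(self):
        members, amap = self._planted()
        res = find_invariant_core(members, amap, cutoff=1.0, min_core=3)
        assert set(res.core_columns) >= set(range(30))
        assert set(res.core_columns) & set(range(30, 40)) == set()

    def test_infinite_cutoff_removes_nothing(self):
        members, amap = self._planted(seed=1)
        res = find_invariant_core(members, amap, cutoff=np.inf, min_core=3)
        assert res.core_columns == list(range(40))
        assert res.removal_order == []

    def test_removal_order_deterministic(self):
        members, amap = self._planted(seed=2)
        r1 = find_invariant_core(members, amap)
        r2 = find_invariant_core(members, amap)
        assert r1.removal_order == r2.removal_order
        assert r1.core_columns == r2.core_columns

    def test_core_volumes_do_not_grow_during_refinement(self):
        members, amap = self._planted(seed=3)
        res = find_invariant_core(members, amap)
        block0 = superpose_ensemble(members, amap)
        initial = column_volumes(block0)
        for c in res.core_columns:
            assert res.volumes[c] <= initial[c] + 1e-9

    def test_min_core_validated(self):
        members, amap = self._planted(seed=4)
        with pytest.raises(PreconditionError):
            find_invariant_core(members, amap, min_core=2)
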