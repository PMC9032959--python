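"""Cross-nobis RSA: whitening algebra, distance oracle, MDS, session change."""

import itertools

import numpy as np
import pytest

from handmap import rsa


class TestNoiseWhitener:
    def test_white_noise_gives_near_identity_transform(self):
        rng = np.random.default_rng(0)
        res = rng.standard_normal((5000, 10))
        w = rsa.noise_whitener(res, shrinkage=0.0)
        assert np.abs(w.transform - np.eye(10)).max() < 0.1

    def test_two_voxel_transform_matches_hand_inverse(self):
        # residuals with known covariance; fixed shrinkage so the shrunk
        # covariance can be inverted by hand
        rng = np.random.default_rng(1)
        chol = np.linalg.cholesky(np.array([[2.0, 0.6], [0.6, 1.0]]))
        res = rng.standard_normal((400, 2)) @ chol.T
        lam = 0.3
        w = rsa.noise_whitener(res, shrinkage=lam)
        x = res - res.mean(0)
        cov = x.T @ x / (len(res) - 1)
        shrunk = (1 - lam) * cov + lam * np.diag(np.diag(cov))
        assert np.allclose(w.transform.T @ w.transform, np.linalg.inv(shrunk), atol=1e-8)

    def test_whitened_residuals_have_identity_covariance(self):
        rng = np.random.default_rng(2)
        chol = np.linalg.cholesky(np.array([[1.0, 0.7], [0.7, 2.0]]))
        res = rng.standard_normal((300, 2)) @ chol.T
        w = rsa.noise_whitener(res, shrinkage=0.0)
        white = w.apply(res - res.mean(0))
        cov = white.T @ white / (len(res) - 1)
        assert np.abs(cov - np.eye(2)).max() < 1e-8

    def test_degenerate_residuals_floored_with_warning(self):
        res = np.zeros((5, 3))
        res[:, 0] = [1, -1, 2, -2, 0]
        with pytest.warns(RuntimeWarning):
            w = rsa.noise_whitener(res, shrinkage=0.0)
        assert np.isfinite(w.transform).all()


def brute_force_crossnobis(betas, transform, include_rest):
    """Direct run-pair summation oracle (loops only, no vectorization)."""
    n_runs, n_cond, n_vox = betas.shape
    u = np.einsum("rcv,wv->rcw", betas, transform)
    if include_rest:
        u = np.concatenate([u, np.zeros((n_runs, 1, n_vox))], axis=1)
        n_cond += 1
    mat = np.zeros((n_cond, n_cond))
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            vals = []
            for a in range(n_runs):
                for b in range(a + 1, n_runs):
                    da = u[a, i] - u[a, j]
                    db = u[b, i] - u[b, j]
                    vals.append(da @ db / n_vox)
            mat[i, j] = mat[j, i] = np.mean(vals)
    return mat


class TestCrossnobis:
    def test_identical_patterns_give_exactly_zero(self):
        rng = np.random.default_rng(3)
        betas = rng.standard_normal((3, 5, 6))
        betas[:, 1] = betas[:, 0]
        rdm = rsa.crossnobis_rdm(betas, include_rest=False)
        assert rdm.get("D1", "D2") == 0.0

    def test_hand_arithmetic_two_runs_two_voxels(self):
        # difference (1, 0) in both runs -> (1*1 + 0*0) / 2 voxels = 0.5
        betas = np.zeros((2, 2, 2))
        betas[:, 0, 0] = 1.0
        rdm = rsa.crossnobis_rdm(betas, include_rest=False)
        assert np.isclose(rdm.get("D1", "D2"), 0.5)

    @pytest.mark.parametrize("n_runs,n_vox", [(2, 2), (3, 4)])
    def test_matches_brute_force_oracle(self, n_runs, n_vox):
        rng = np.random.default_rng(4)
        betas = rng.standard_normal((n_runs, 5, n_vox))
        res = rng.standard_normal((50, n_vox))
        w = rsa.noise_whitener(res, shrinkage=0.2)
        rdm = rsa.crossnobis_rdm(betas, w, include_rest=True)
        oracle = brute_force_crossnobis(betas, w.transform, include_rest=True)
        assert np.abs(rdm.matrix - oracle).max() < 1e-12

    def test_scaling_patterns_scales_distances_quadratically(self):
        rng = np.random.default_rng(5)
        betas = rng.standard_normal((4, 5, 8))
        d1 = rsa.crossnobis_rdm(betas, include_rest=False).matrix
        d2 = rsa.crossnobis_rdm(3.0 * betas, include_rest=False).matrix
        assert np.allclose(d2, 9.0 * d1)

    def test_unbiased_at_zero_for_equal_condition_means(self):
        # same true pattern for two conditions: mean cross-validated
        # distance over many datasets is statistically zero
        rng = np.random.default_rng(6)
        n_sets, dists = 300, []
        for _ in range(n_sets):
            mean = rng.standard_normal(20)
            betas = mean + 0.5 * rng.standard_normal((4, 2, 20))
            dists.append(rsa.crossnobis_rdm(betas, include_rest=False).get("D1", "D2"))
        dists = np.asarray(dists)
        se = dists.std(ddof=1) / np.sqrt(n_sets)
        assert abs(dists.mean()) < 3 * se

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            rsa.crossnobis_rdm(np.zeros((1, 5, 4)))


class TestMdsGroup:
    def planar_rdm(self, pts):
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        conds = ["D1", "D2", "D3", "D4", "D5", "rest"][: len(pts)]
        return rsa.RDM(conditions=conds, matrix=d, estimator="euclidean"), d

    def test_mds_reproduces_planar_distances(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((6, 2))
        rdm, d = self.planar_rdm(pts)
        x = rsa.classical_mds(rdm)
        dd = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        assert np.allclose(dd, d, atol=1e-8)

    def test_pure_rotation_has_zero_disparity(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((6, 2))
        th = 0.8
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        aligned, disp = rsa.procrustes_align(a @ rot.T + 2.0, a)
        assert disp < 1e-20
        assert np.allclose(aligned, a)

    def test_alignment_preserves_interpoint_distances(self):
        rng = np.random.default_rng(9)
        rdms = [self.planar_rdm(rng.standard_normal((6, 2)))[0] for _ in range(3)]
        group = rsa.mds_group(rdms)
        for k, rdm in enumerate(rdms):
            pts = group.participant_points[k]
            dd = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            assert np.allclose(dd, rdm.matrix, atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            rsa.RDM(conditions=["a", "b"], matrix=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestSessionChange:
    def make_rdm(self, scale=1.0, seed=10):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)) * scale
        return rsa.RDM(["D1", "D2", "D3", "D4", "D5", "rest"], d, "euclidean")

    def test_identical_sessions_show_zero_change(self):
        rdm = self.make_rdm()
        out = rsa.rdm_session_change(rdm, rdm)
        assert np.isclose(out["pct_change_overall"], 0.0)
        assert np.isclose(out["pct_change_nonblocked"], 0.0)
        assert all(np.isclose(v, 0.0) for v in out["rest_distance_change"].values())

    def test_uniform_shrinkage_gives_expected_percent(self):
        base = self.make_rdm()
        block = rsa.RDM(base.conditions, 0.71 * base.matrix, "euclidean")
        out = rsa.rdm_session_change(base, block)
        assert np.isclose(out["pct_change_overall"], -29.0)
        assert np.isclose(out["rank_correlation_sessions"], 1.0)

    def test_self_rank_correlation_is_one_with_minimal_pvalue(self):
        rdm = self.make_rdm()
        rho, p = rsa.permutation_pvalue(rdm, rdm)
        assert np.isclose(rho, 1.0)
        assert p <= 1.0 / 100  # 120 label permutations enumerated

    def test_mismatched_conditions_rejected(self):
        a = self.make_rdm()
        b = rsa.RDM(["D1", "D2", "D3", "D4", "D5"], a.matrix[:5, :5], "euclidean")
        with pytest.raises(ValueError):
            rsa.rdm_session_change(a, b)
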