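"""Recurrent cortical model: settlement, fitting, gain recovery, model RDMs."""

import itertools

import numpy as np
import pytest

from handmap.config import FINGERS
from handmap import cortical, peripheral


def random_stable_model(rng):
    L = rng.uniform(-0.3, 0.3, size=(5, 5))
    L *= 0.9 / max(np.max(np.abs(np.linalg.eigvals(L))), 1e-9)
    return cortical.CorticalModel(
        alpha=rng.uniform(0.5, 1.5, 5),
        W=rng.standard_normal((5, 5)),
        b=float(rng.standard_normal()),
        L=L,
    )


class TestSettlement:
    def test_no_lateral_connections_settle_in_one_step(self, drives):
        m = cortical.CorticalModel(np.ones(5), np.eye(5), 0.2, np.zeros((5, 5)))
        r = cortical.settle(m, drives["D1"], tol=1e-9)
        assert r.iterations == 1
        assert np.allclose(r.c, drives["D1"].values + 0.2)

    def test_settled_state_matches_fixed_point_on_random_models(self, drives):
        rng = np.random.default_rng(0)
        tol = 1e-10
        for _ in range(200):
            m = random_stable_model(rng)
            p = rng.random(5)
            r = cortical.settle(m, p, tol=tol, max_iter=2000)
            assert np.abs(r.c - cortical.fixed_point(m, p)).max() < 1e-8

    def test_two_unit_toy_fixed_point_by_hand(self):
        # 2-unit system embedded in the 5-unit model: W=I, b=0, alpha=1,
        # lateral coupling 0.5 between units 1 and 2, drive (1, 0):
        # c1 = 1 + 0.5 c2, c2 = 0.5 c1 -> c = (4/3, 2/3)
        L = np.zeros((5, 5))
        L[0, 1] = L[1, 0] = 0.5
        m = cortical.CorticalModel(np.ones(5), np.eye(5), 0.0, L)
        c = cortical.fixed_point(m, np.array([1.0, 0, 0, 0, 0]))
        assert np.allclose(c[:2], [4 / 3, 2 / 3])
        assert np.allclose(c[2:], 0.0)

    def test_response_linear_in_drive_without_offset(self, drives):
        rng = np.random.default_rng(1)
        m = random_stable_model(rng)
        m = cortical.CorticalModel(m.alpha, m.W, 0.0, m.L)
        p = rng.random(5)
        assert np.allclose(cortical.fixed_point(m, 3.0 * p), 3.0 * cortical.fixed_point(m, p))

    def test_gain_scales_feedforward_contribution_linearly(self):
        # with b = 0 and L = 0 the settled activity of unit i is alpha_i w_i.p
        W = np.eye(5)
        p = np.array([1.0, 0.5, 0, 0, 0])
        for a in (0.5, 1.0, 2.0):
            m = cortical.CorticalModel(np.full(5, a), W, 0.0, np.zeros((5, 5)))
            assert np.allclose(cortical.fixed_point(m, p), a * p)

    def test_nonconvergence_error_carries_last_state(self):
        L = np.zeros((5, 5))
        L[0, 1] = L[1, 0] = 0.9
        m = cortical.CorticalModel(np.ones(5), np.eye(5), 0.0, L)
        with pytest.raises(cortical.NonConvergenceError) as err:
            cortical.settle(m, np.ones(5), tol=1e-12, max_iter=3)
        assert err.value.last_state.shape == (5,)

    def test_unstable_lateral_matrix_rejected_at_construction(self):
        with pytest.raises(ValueError):
            cortical.CorticalModel(np.ones(5), np.eye(5), 0.0, 1.5 * np.eye(5))


class TestBaselineFit:
    def test_noiseless_recovery_with_known_offset(self, true_model, drives, baseline_target):
        m = cortical.fit_baseline(baseline_target, drives, b=true_model.b)
        assert np.abs(m.W - true_model.W).max() < 1e-9
        assert m.b == true_model.b

    def test_iterative_refinement_equals_closed_form(self, true_model, drives, baseline_target):
        a = cortical.fit_baseline(baseline_target, drives, b=true_model.b, method="regression")
        b = cortical.fit_baseline(baseline_target, drives, b=true_model.b, method="iterative")
        assert np.abs(a.W - b.W).max() < 1e-9

    def test_fitted_model_reproduces_training_targets(self, drives, baseline_target):
        m = cortical.fit_baseline(baseline_target, drives, b=None)
        settled = np.column_stack(
            [cortical.fixed_point(m, drives[f]) for f in FINGERS]
        ).T
        assert np.abs(settled - baseline_target).max() < 1e-8

    def test_rank_deficient_drives_rejected(self, baseline_target):
        flat = {
            f: peripheral.PeripheralDrive(condition=f, values=np.ones(5))
            for f in FINGERS
        }
        with pytest.raises(np.linalg.LinAlgError):
            cortical.fit_baseline(baseline_target, flat)


class TestStaticBlock:
    def test_full_fraction_reproduces_baseline(self, true_model, drives):
        responses, _ = cortical.predict_static_block(
            true_model, peripheral.blocked_drives(drives, "D2", 1.0)
        )
        for f in FINGERS:
            base = cortical.fixed_point(true_model, drives[f])
            assert np.allclose(responses[f].c, base, atol=1e-7)

    def test_block_suppresses_blocked_units_response(self, true_model, drives, blocked_drives):
        base = cortical.fixed_point(true_model, drives["D2"])
        responses, _ = cortical.predict_static_block(true_model, blocked_drives)
        assert responses["D2"].c[1] < base[1]

    def test_static_model_collapses_d2_representation_most(
        self, true_model, drives, blocked_drives
    ):
        base_resp = cortical.settle_all(true_model, drives, tol=1e-10)
        base_rdm = cortical.model_rdm(base_resp)
        _, static_rdm = cortical.predict_static_block(true_model, blocked_drives)
        rel = {
            f: static_rdm.get(f, "rest") / base_rdm.get(f, "rest") for f in FINGERS
        }
        assert rel["D2"] < 1.0
        assert all(rel["D2"] < rel[f] for f in FINGERS if f != "D2")

    def test_requires_baseline_gains(self, true_model, blocked_drives):
        with pytest.raises(ValueError):
            cortical.predict_static_block(true_model.with_gains(0.75, 1.25), blocked_drives)


class TestGainFit:
    def test_unchanged_targets_recover_unit_gains(self, true_model, drives, baseline_target):
        g, gb = cortical.fit_gains(true_model, drives, baseline_target)
        assert abs(g - 1.0) < 1e-4 and abs(gb - 1.0) < 1e-4

    def test_generating_gains_recovered_from_noiseless_block_activity(
        self, true_model, blocked_drives
    ):
        gen = true_model.with_gains(0.75, 1.25)
        target = np.column_stack(
            [cortical.fixed_point(gen, blocked_drives[f]) for f in FINGERS]
        ).T
        g, gb = cortical.fit_gains(true_model, blocked_drives, target)
        assert abs(g - 0.75) < 1e-3
        assert abs(gb - 1.25) < 1e-3

    def test_optimum_matches_fine_grid_oracle(self, true_model, blocked_drives):
        gen = true_model.with_gains(0.8, 1.1)
        target = np.column_stack(
            [cortical.fixed_point(gen, blocked_drives[f]) for f in FINGERS]
        ).T
        g, gb = cortical.fit_gains(true_model, blocked_drives, target)
        grid = np.arange(0.25, 2.0001, 0.005)
        sse = {
            (a, c): cortical.gain_sse(true_model, (a, c), blocked_drives, target, "D2")
            for a, c in itertools.product(grid, grid)
        }
        best = min(sse, key=sse.get)
        assert abs(g - best[0]) <= 0.005 and abs(gb - best[1]) <= 0.005


class TestModelRdm:
    def test_identical_responses_give_zero_distances(self):
        r = [
            cortical.CorticalResponse(f, np.ones(5), 1, True)
            for f in FINGERS
        ]
        rdm = cortical.model_rdm(r, include_rest=False)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(rdm.matrix[off], 0.0)

    def test_unit_vector_pair_distance_sqrt2(self):
        a = cortical.CorticalResponse("D1", np.eye(5)[0], 1, True)
        b = cortical.CorticalResponse("D2", np.eye(5)[1], 1, True)
        rdm = cortical.model_rdm([a, b], include_rest=False)
        assert np.isclose(rdm.get("D1", "D2"), np.sqrt(2))

    def test_symmetric_with_zero_diagonal_and_rest(self, true_model, drives):
        rdm = cortical.model_rdm(cortical.settle_all(true_model, drives, tol=1e-9))
        assert rdm.conditions[-1] == "rest"
        assert np.allclose(np.diag(rdm.matrix), 0.0)
        assert np.allclose(rdm.matrix, rdm.matrix.T)


def test_homeostatic_gains_shrink_without_collapsing_d2(
    true_model, drives, blocked_drives
):
    """With gains (0.75, 1.25) and 20% residual drive the model RDM shrinks
    overall, but D2's distance from rest survives far better than under the
    static (no gain change) prediction."""
    base_rdm = cortical.model_rdm(cortical.settle_all(true_model, drives, tol=1e-10))
    _, static_rdm = cortical.predict_static_block(true_model, blocked_drives)
    homeo = true_model.with_gains(0.75, 1.25)
    homeo_rdm = cortical.model_rdm(cortical.settle_all(homeo, blocked_drives, tol=1e-10))
    assert homeo_rdm.mean_interfinger() < base_rdm.mean_interfinger()

    def d2_relative_collapse(rdm):
        # D2's rest-distance retention relative to the nonblocked fingers'
        ratios = {f: rdm.get(f, "rest") / base_rdm.get(f, "rest") for f in FINGERS}
        others = np.mean([ratios[f] for f in FINGERS if f != "D2"])
        return ratios["D2"] / others

    assert d2_relative_collapse(homeo_rdm) > d2_relative_collapse(static_rdm)
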