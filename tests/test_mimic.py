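import numpy as np
import pytest
import scipy.sparse as sp

from protoplan import dose_engine as de, mimic
from protoplan.grid_core import DoseGrid, RoiMask, StructureSet
from protoplan.mimic import MimicConfig, VoxelWeights


def one_voxel_structures(target=True, oar=True):
    shape = (1, 1, 1)
    masks = [RoiMask("External", np.ones(shape, bool), role="external")]
    if target:
        masks.insert(0, RoiMask("PTV chest wall", np.ones(shape, bool), role="target"))
    if oar:
        masks.insert(-1, RoiMask("lungs", np.ones(shape, bool), role="oar"))
    return StructureSet(masks)


class TestAssignWeights:
    def test_oar_only_voxel_has_zero_underdose_weight(self):
        s = one_voxel_structures(target=False, oar=True)
        w = mimic.assign_voxel_weights(s, MimicConfig(roi_weights={"lungs": (10.0, 7.0)}))
        assert w.w_plus[0, 0, 0] == 10.0
        assert w.w_minus[0, 0, 0] == 0.0  # forced, despite configured 7

    def test_uncovered_voxel_gets_default_pair(self):
        s = one_voxel_structures(target=False, oar=False)
        w = mimic.assign_voxel_weights(
            s, MimicConfig(roi_weights={}, default_weights=(2.0, 0.5))
        )
        assert (w.w_plus[0, 0, 0], w.w_minus[0, 0, 0]) == (2.0, 0.5)

    def test_target_oar_overlap_takes_elementwise_max(self):
        s = one_voxel_structures(target=True, oar=True)
        cfg = MimicConfig(roi_weights={"PTV chest wall": (1.0, 50.0), "lungs": (10.0, 0.0)})
        w = mimic.assign_voxel_weights(s, cfg)
        # w+ from the lung, w- kept from the target (overlap is still target)
        assert (w.w_plus[0, 0, 0], w.w_minus[0, 0, 0]) == (10.0, 50.0)


class TestObjective:
    def test_zero_when_dose_matches(self, rng):
        d = rng.uniform(size=(3, 3, 3))
        w = VoxelWeights(np.ones((3, 3, 3)), np.ones((3, 3, 3)))
        assert mimic.mimic_objective(d, d, w) == 0.0

    def test_hand_evaluated_single_voxel(self):
        w = VoxelWeights(np.full((1, 1, 1), 2.0), np.full((1, 1, 1), 5.0))
        f = mimic.mimic_objective(np.full((1, 1, 1), 1.1), np.ones((1, 1, 1)), w)
        assert f == pytest.approx(2.0 * 0.1**2)
        f_under = mimic.mimic_objective(np.full((1, 1, 1), 0.9), np.ones((1, 1, 1)), w)
        assert f_under == pytest.approx(5.0 * 0.1**2)

    def test_oar_underdose_not_penalized(self):
        # w- = 0: dose below reference costs nothing
        w = VoxelWeights(np.ones((1, 1, 1)), np.zeros((1, 1, 1)))
        assert mimic.mimic_objective(np.zeros((1, 1, 1)), np.ones((1, 1, 1)), w) == 0.0

    def test_weight_scaling_scales_objective(self, rng):
        d = rng.uniform(size=(4, 4, 4))
        ref = rng.uniform(size=(4, 4, 4))
        w = VoxelWeights(rng.uniform(size=(4, 4, 4)), rng.uniform(size=(4, 4, 4)))
        w3 = VoxelWeights(3 * w.w_plus, 3 * w.w_minus)
        assert mimic.mimic_objective(d, ref, w3) == pytest.approx(
            3 * mimic.mimic_objective(d, ref, w), rel=1e-12
        )

    def test_shape_mismatch_rejected(self):
        w = VoxelWeights(np.ones((2, 2, 2)), np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="shape"):
            mimic.mimic_objective(np.ones((2, 2, 2)), np.ones((3, 2, 2)), w)

    def test_gradient_matches_finite_differences(self, rng):
        """Central differences on the piecewise-quadratic objective, away
        from the d = d_ref kinks."""
        n_vox, n_spots = 40, 6
        A = sp.csr_matrix(rng.uniform(size=(n_vox, n_spots)))
        ref = rng.uniform(0.5, 1.5, size=n_vox)
        w = VoxelWeights(rng.uniform(0.5, 2, size=n_vox), rng.uniform(0.5, 2, size=n_vox))
        x = rng.uniform(0.1, 1.0, size=n_spots)

        def f(v):
            return mimic.robust_objective(v, [A], ref, w)

        d = np.asarray(A @ x)
        assert np.abs(d - ref).min() > 1e-4  # not at a kink
        res = np.where(d > ref, w.w_plus, np.where(d < ref, w.w_minus, 0)) * (d - ref)
        analytic = 2.0 * (A.T @ res)
        eps = 1e-6
        for j in range(n_spots):
            e = np.zeros(n_spots); e[j] = eps
            num = (f(x + e) - f(x - e)) / (2 * eps)
            assert num == pytest.approx(analytic[j], rel=1e-5)


class TestRobustObjective:
    def test_reduces_to_plain_objective_without_robust_mask(self, rng):
        A = sp.csr_matrix(rng.uniform(size=(27, 4)))
        ref = rng.uniform(size=27)
        w = VoxelWeights(rng.uniform(size=27), rng.uniform(size=27))
        x = rng.uniform(size=4)
        expected = mimic.mimic_objective(np.asarray(A @ x), ref, w)
        assert mimic.robust_objective(x, [A], ref, w) == pytest.approx(expected)

    def test_identical_scenarios_reduce_to_nominal(self, rng):
        A = sp.csr_matrix(rng.uniform(size=(27, 4)))
        ref = rng.uniform(size=27)
        w = VoxelWeights(rng.uniform(size=27), rng.uniform(size=27))
        x = rng.uniform(size=4)
        full_mask = np.ones(27, dtype=bool)
        got = mimic.robust_objective(x, [A, A.copy(), A.copy()], ref, w, full_mask)
        assert got == pytest.approx(mimic.mimic_objective(np.asarray(A @ x), ref, w))

    def test_two_scenario_hand_computation(self):
        # 2 voxels, 1 spot, both voxels robust
        A1 = sp.csr_matrix(np.array([[1.0], [1.0]]))
        A2 = sp.csr_matrix(np.array([[2.0], [0.5]]))
        ref = np.array([1.0, 1.0])
        w = VoxelWeights(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        x = np.array([1.0])
        # scenario doses: (1,1) -> f=0 ; (2,0.5) -> f = 1 + 0.25
        expected = 0.5 * (0.0 + 1.25)
        got = mimic.robust_objective(x, [A1, A2], ref, w, np.ones(2, bool))
        assert got == pytest.approx(expected)

    def test_empty_influence_list_rejected(self):
        w = VoxelWeights(np.ones(2), np.ones(2))
        with pytest.raises(ValueError, match="nominal"):
            mimic.robust_objective(np.ones(1), [], np.ones(2), w)


class TestOptimize:
    @pytest.fixture()
    def recovery_problem(self, water_box, rng):
        tgt = np.zeros(water_box.shape, dtype=bool)
        tgt[7:13, 6:12, 7:13] = True
        plan = de.place_spots(RoiMask("t", tgt, role="target"), water_box,
                              margin_mm=2.5, lateral_spacing_mm=5.0, layer_spacing_mm=5.0)
        A = de.influence_matrix(plan, water_box)
        w_star = rng.uniform(0.5, 2.0, size=len(plan.spots))
        d_ref = np.asarray(A @ w_star).reshape(water_box.shape)
        weights = VoxelWeights(np.ones(water_box.shape), np.ones(water_box.shape))
        return plan, A, d_ref, weights, tgt

    def test_zero_iterations_returns_initial_weights(self, recovery_problem):
        plan, A, d_ref, w, _ = recovery_problem
        res = mimic.optimize(plan, [A], d_ref, w, MimicConfig(iterations=0))
        assert (res.weights == 0).all()
        assert len(res.trace) == 1

    def test_trace_monotone_non_increasing(self, recovery_problem):
        plan, A, d_ref, w, _ = recovery_problem
        res = mimic.optimize(plan, [A], d_ref, w, MimicConfig(iterations=50))
        assert (np.diff(res.trace) <= 1e-12).all()

    def test_achievable_reference_recovered(self, recovery_problem):
        plan, A, d_ref, w, tgt = recovery_problem
        res = mimic.optimize(plan, [A], d_ref, w, MimicConfig(iterations=300))
        assert res.trace[-1] < 1e-4 * res.trace[0]
        dose = np.asarray(A @ res.weights).reshape(d_ref.shape)
        rel = np.abs(dose[tgt] - d_ref[tgt]) / d_ref[tgt]
        assert rel.mean() < 0.02
        assert res.weights.min() >= 0

    def test_all_zero_influence_rejected(self, recovery_problem):
        plan, A, d_ref, w, _ = recovery_problem
        Z = sp.csr_matrix(A.shape)
        with pytest.raises(ValueError, match="all-zero"):
            mimic.optimize(plan, [Z], d_ref, w, MimicConfig(iterations=5))

    def test_weight_scaling_leaves_argmin_unchanged(self, recovery_problem):
        plan, A, d_ref, w, _ = recovery_problem
        res1 = mimic.optimize(plan, [A], d_ref, w, MimicConfig(iterations=80))
        w10 = VoxelWeights(10 * w.w_plus, 10 * w.w_minus)
        res10 = mimic.optimize(plan, [A], d_ref, w10, MimicConfig(iterations=80))
        np.testing.assert_allclose(res10.weights, res1.weights, rtol=1e-3, atol=1e-9)
        assert res10.trace[0] == pytest.approx(10 * res1.trace[0], rel=1e-12)
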