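import numpy as np
import pytest
import scipy.ndimage as ndi

from protoplan import evaluate as ev
from protoplan.evaluate import ClinicalGoal, GammaParams
from protoplan.grid_core import DoseGrid, RoiMask, StructureSet

RX = 50.4
SPACING = (2.5, 2.5, 2.5)
VOXEL_CC = 2.5**3 / 1000.0


def roi_with_doses(values):
    """A 1D ROI holding exactly the given voxel doses."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    dose = DoseGrid(arr, SPACING)
    mask = RoiMask("roi", np.ones(arr.shape, dtype=bool))
    return dose, mask


class TestDvhCurve:
    def test_uniform_dose_step_curve(self):
        dose, mask = roi_with_doses([RX] * 8)
        levels, vol = ev.compute_dvh(dose, mask, bin_width_gy=0.5)
        assert vol[0] == 100.0
        assert vol[levels <= RX].min() == 100.0
        assert vol[levels > RX].max() == 0.0

    def test_hand_counted_half_volume(self):
        dose, mask = roi_with_doses([10.0, 20.0, 30.0, 40.0])
        levels, vol = ev.compute_dvh(dose, mask, bin_width_gy=1.0)
        assert vol[np.searchsorted(levels, 25.0)] == 50.0

    def test_monotone_and_order_invariant(self, rng):
        vals = rng.uniform(0, 60, size=32)
        d1, m = roi_with_doses(vals)
        d2, _ = roi_with_doses(vals[::-1])
        l1, v1 = ev.compute_dvh(d1, m)
        l2, v2 = ev.compute_dvh(d2, m)
        np.testing.assert_array_equal(v1, v2)
        assert (np.diff(v1) <= 0).all()

    def test_empty_mask_rejected(self):
        dose, _ = roi_with_doses([1.0])
        with pytest.raises(ValueError, match="empty"):
            ev.compute_dvh(dose, RoiMask("x", np.zeros((1, 1, 1), bool)))


class TestDvhMetrics:
    def test_uniform_dose_metrics(self):
        dose, mask = roi_with_doses([20.0] * 4)
        davg = ClinicalGoal("roi", "D_mean", 1.0, 1.25, "<=")
        hot = ClinicalGoal("roi", "D_hotspot", 0.03, 40.0, "<=")
        assert ev.dvh_metric(dose, mask, davg, RX) == 20.0
        assert ev.dvh_metric(dose, mask, hot, RX) == 20.0

    def test_hotspot_interpolates_partial_voxel(self):
        # 2.5 mm voxels = 0.015625 cc; hottest two at 40 and 38 Gy
        dose, mask = roi_with_doses([40.0, 38.0, 10.0, 5.0])
        goal = ClinicalGoal("roi", "D_hotspot", 0.03, 40.0, "<=")
        # 0.03 cc = 1.92 voxels: linear interpolation into the second voxel
        frac = (0.03 - VOXEL_CC) / VOXEL_CC
        expected = 40.0 + frac * (38.0 - 40.0)
        assert ev.dvh_metric(dose, mask, goal, RX) == pytest.approx(expected)

    def test_hotspot_smaller_roi_warns_and_returns_min(self):
        dose, mask = roi_with_doses([30.0])
        goal = ClinicalGoal("roi", "D_hotspot", 0.03, 40.0, "<=")
        with pytest.warns(UserWarning, match="smaller"):
            assert ev.dvh_metric(dose, mask, goal, RX) == 30.0

    def test_v95_boundary_inclusive(self):
        dose, mask = roi_with_doses([0.95 * RX, 0.2 * RX])
        goal = ClinicalGoal("roi", "V_pct_rx", 95.0, 95.0, ">=")
        assert ev.dvh_metric(dose, mask, goal, RX) == 50.0  # boundary voxel counts

    def test_metric_invariant_under_permutation(self, rng):
        vals = rng.uniform(0, 60, size=16)
        goal = ClinicalGoal("roi", "D_mean", 1.0, 1.0, "<=")
        d1, m = roi_with_doses(vals)
        d2, _ = roi_with_doses(np.random.default_rng(0).permutation(vals))
        assert ev.dvh_metric(d1, m, goal, RX) == pytest.approx(
            ev.dvh_metric(d2, m, goal, RX)
        )
        assert ev.dvh_metric(d1, m, goal, RX) == pytest.approx(vals.mean())


class TestGoals:
    def make_structures(self, shape=(6, 6, 6)):
        ext = np.ones(shape, bool)
        ptv = np.zeros(shape, bool); ptv[1:4, 1:4, 1:4] = True
        heart = np.zeros(shape, bool); heart[4:6, 4:6, 4:6] = True
        return StructureSet(
            [RoiMask("PTV chest wall", ptv, role="target"),
             RoiMask("heart", heart, role="oar"),
             RoiMask("External", ext, role="external")],
            spacing=SPACING,
        )

    def goals(self):
        return [
            ClinicalGoal("PTV chest wall", "V_pct_rx", 95.0, 95.0, ">="),
            ClinicalGoal("heart", "D_mean", 1.0, 1.25, "<="),
        ]

    def test_uniform_rx_passes_target_goal(self):
        s = self.make_structures()
        dose = DoseGrid(np.full(s.shape, RX), SPACING)
        table = ev.evaluate_goals(dose, s, self.goals()[:1], RX)
        assert table.loc[0, "value"] == 100.0 and bool(table.loc[0, "passed"])

    def test_zero_dose_oar_passes_target_fails(self):
        s = self.make_structures()
        dose = DoseGrid(np.zeros(s.shape), SPACING)
        table = ev.evaluate_goals(dose, s, self.goals(), RX)
        assert not bool(table.loc[0, "passed"])  # target coverage fails
        assert bool(table.loc[1, "passed"])  # OAR trivially passes

    def test_heart_mean_above_threshold_fails(self):
        s = self.make_structures()
        vals = np.zeros(s.shape)
        vals[s["heart"].values] = 1.3
        table = ev.evaluate_goals(DoseGrid(vals, SPACING), s, self.goals(), RX)
        assert table.loc[1, "value"] == pytest.approx(1.3)
        assert not bool(table.loc[1, "passed"])

    def test_missing_roi_not_evaluable_but_run_continues(self):
        s = self.make_structures()
        goals = self.goals() + [ClinicalGoal("esophagus", "D_mean", 1.0, 40.0, "<=")]
        table = ev.evaluate_goals(DoseGrid(np.zeros(s.shape), SPACING), s, goals, RX)
        assert len(table) == 3
        assert not table.loc[2, "evaluable"]


class TestRobustnessPassRate:
    def test_counting(self):
        s = TestGoals().make_structures()
        goals = [ClinicalGoal("heart", "D_mean", 1.0, 1.25, "<=")]
        lo = DoseGrid(np.zeros(s.shape), SPACING)
        hi_vals = np.zeros(s.shape); hi_vals[s["heart"].values] = 2.0
        hi = DoseGrid(hi_vals, SPACING)
        table = ev.robustness_pass_rate([lo] * 6 + [hi] * 6, s, goals, RX)
        assert table.loc[0, "pass_rate_pct"] == 50.0
        assert table.loc[0, "n_scenarios"] == 12
        all_pass = ev.robustness_pass_rate([lo] * 3, s, goals, RX)
        assert all_pass.loc[0, "pass_rate_pct"] == 100.0

    def test_single_scenario_equals_binary_outcome(self):
        s = TestGoals().make_structures()
        goals = [ClinicalGoal("heart", "D_mean", 1.0, 1.25, "<=")]
        lo = DoseGrid(np.zeros(s.shape), SPACING)
        table = ev.robustness_pass_rate([lo], s, goals, RX)
        assert table.loc[0, "pass_rate_pct"] in (0.0, 100.0)


def smooth_positive_field(shape, rng, lo=5.0, hi=60.0, blur=2.5):
    f = ndi.gaussian_filter(rng.normal(size=shape), blur)
    f = (f - f.min()) / (f.max() - f.min())
    return lo + (hi - lo) * f


class TestGamma:
    def test_identity_pair_passes_everywhere(self, rng):
        ref = DoseGrid(smooth_positive_field((15, 15, 15), rng), SPACING)
        res = ev.gamma(ref, ref)
        assert res.pass_rate_pct == 100.0
        assert np.nanmax(res.values) == 0.0

    def test_uniform_local_offset_sits_on_boundary(self):
        ref = DoseGrid(np.full((10, 10, 10), RX), SPACING)
        res = ev.gamma(ref, DoseGrid(1.03 * ref.values, SPACING))
        vals = res.values[np.isfinite(res.values)]
        np.testing.assert_allclose(vals, 1.0, rtol=1e-9)
        assert res.pass_rate_pct == 100.0

    def test_low_dose_voxels_excluded(self, rng):
        ref_vals = np.full((8, 8, 8), 1.0)
        ref_vals[0] = 100.0
        ref = DoseGrid(ref_vals, SPACING)
        res = ev.gamma(ref, ref)
        assert res.n_evaluated == int((ref_vals >= 10.0).sum())

    def test_asymmetric_in_reference_and_evaluated(self, rng):
        """Swapping roles changes the result (documents the convention)."""
        ref = DoseGrid(smooth_positive_field((12, 12, 12), rng), SPACING)
        widened = ndi.maximum_filter(ref.values, size=3)
        ev_grid = DoseGrid(widened, SPACING)
        ab = ev.gamma(ref, ev_grid).pass_rate_pct
        ba = ev.gamma(ev_grid, ref).pass_rate_pct
        assert ab != ba

    def test_fast_agrees_with_dense_oracle(self, rng):
        params = GammaParams(search_radius_factor=2.0, step_divisor=5)
        ref = DoseGrid(smooth_positive_field((12, 12, 12), rng), SPACING)
        pert = 1.0 + 0.06 * ndi.gaussian_filter(rng.normal(size=(12, 12, 12)), 1.5)
        evg = DoseGrid(np.abs(ref.values * pert), SPACING)
        fast = ev.gamma(ref, evg, params)
        dense = ev.gamma_dense(ref, evg, params)
        diff = np.abs(fast.values - dense.values)
        assert np.nanmax(diff) <= 0.02

    def test_non_congruent_grids_rejected(self, rng):
        a = DoseGrid(np.ones((4, 4, 4)), SPACING)
        b = DoseGrid(np.ones((4, 4, 5)), SPACING)
        with pytest.raises(ValueError, match="congruent"):
            ev.gamma(a, b)

    def test_2d_slab_supported(self, rng):
        ref = DoseGrid(smooth_positive_field((16, 16, 1), rng, blur=1.5), SPACING)
        res = ev.gamma(ref, ref)
        assert res.pass_rate_pct == 100.0


class TestPairedCompare:
    def test_identical_lists_degenerate(self):
        res = ev.paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0 and res.n_effective == 0

    def test_constant_shift_n12_exact_p(self, rng):
        a = rng.uniform(size=12)
        res = ev.paired_compare(a, a + 1.0)
        # all 12 signs agree: exact two-sided p = 2 / 2^12
        assert res.p_value == pytest.approx(2.0 / 4096.0)
        assert res.n_effective == 12

    def test_two_sided_symmetry(self, rng):
        a = rng.uniform(size=10)
        b = a + rng.normal(size=10)
        assert ev.paired_compare(a, b).p_value == pytest.approx(
            ev.paired_compare(b, a).p_value
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.paired_compare([1.0], [1.0, 2.0])
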