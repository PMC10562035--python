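import numpy as np
import pytest

from protoplan import dose_engine as de
from protoplan.grid_core import DoseGrid, RoiMask


class TestScenarios:
    @pytest.mark.parametrize(
        "mode,expected", [("optimization", 21), ("evaluation", 12), ("nominal", 1)]
    )
    def test_set_sizes(self, mode, expected):
        assert len(de.make_scenarios(5.0, 3.0, mode)) == expected

    def test_nominal_is_identity(self):
        (s,) = de.make_scenarios(0.0, 0.0, "nominal")
        assert s.is_nominal

    def test_optimization_contains_nominal_once(self):
        scens = de.make_scenarios(5.0, 3.0, "optimization")
        assert sum(s.is_nominal for s in scens) == 1

    def test_evaluation_set_spans_all_combinations(self):
        scens = de.make_scenarios(5.0, 3.0, "evaluation")
        shifts = {s.shift_mm for s in scens}
        scales = {s.density_scale for s in scens}
        assert len(shifts) == 6 and scales == {0.97, 1.03}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            de.make_scenarios(5.0, 3.0, "bogus")


class TestWed:
    def test_uniform_water_closed_form(self, water_box):
        wed = de.wed_grid(water_box)
        k = np.arange(20)
        np.testing.assert_allclose(wed.values[3, :, 7], 2.5 * (k + 0.5))

    def test_density_scale_is_multiplicative(self, water_box):
        nominal = de.wed_grid(water_box)
        scaled = de.wed_grid(water_box, de.Scenario(density_scale=1.03))
        np.testing.assert_allclose(scaled.values, 1.03 * nominal.values)

    def test_lung_column_accumulates_at_lung_rate(self):
        rho = np.ones((4, 10, 4))
        rho[:, 4:, :] = 0.26  # lung past 10 mm depth
        wed = de.wed_grid(DoseGrid(rho, (2.5, 2.5, 2.5)))
        # hand integration: 4 tissue voxels then lung voxels
        expected = 2.5 * (4 * 1.0) + 2.5 * (0.26 * 1.5)  # center of voxel j=5
        assert wed.values[0, 5, 0] == pytest.approx(expected)

    def test_monotone_along_beam_axis(self, rng):
        rho = rng.uniform(0, 1.2, size=(6, 12, 6))
        wed = de.wed_grid(DoseGrid(rho, (2.5, 2.5, 2.5)))
        assert (np.diff(wed.values, axis=1) >= 0).all()


class TestSpotDose:
    def test_peak_at_nominal_range(self, water_box):
        wed = de.wed_grid(water_box)
        spot = de.Spot(u=25.0, v=25.0, range_mm=30.0)
        dose = de.spot_dose(spot, wed)
        i = int(round(25.0 / 2.5))
        profile = dose.values[i, :, i]
        expected = int(np.argmin(np.abs(wed.values[i, :, i] - 30.0)))
        assert int(np.argmax(profile)) == expected

    def test_lateral_symmetry(self, water_box):
        wed = de.wed_grid(water_box)
        dose = de.spot_dose(de.Spot(u=25.0, v=25.0, range_mm=30.0), wed).values
        i0 = int(round(25.0 / 2.5))
        # +-3 voxels off axis at fixed depth
        np.testing.assert_allclose(dose[i0 + 3, 5, i0], dose[i0 - 3, 5, i0], rtol=1e-12)

    def test_distal_dose_falls_off(self, water_box):
        wed = de.wed_grid(water_box)
        dose = de.spot_dose(de.Spot(u=25.0, v=25.0, range_mm=15.0), wed).values
        i0 = int(round(25.0 / 2.5))
        # far beyond the peak the proton has stopped
        assert dose[i0, -1, i0] < 0.02 * dose.max()


class TestInfluence:
    @pytest.fixture()
    def small_problem(self, water_box):
        tgt = np.zeros(water_box.shape, dtype=bool)
        tgt[8:12, 8:12, 8:12] = True
        plan = de.place_spots(
            RoiMask("t", tgt, role="target"), water_box,
            margin_mm=2.5, lateral_spacing_mm=7.5, layer_spacing_mm=7.5,
        )
        A = de.influence_matrix(plan, water_box)
        return plan, A

    def test_zero_weights_zero_dose(self, small_problem):
        plan, A = small_problem
        assert np.abs(A @ np.zeros(len(plan.spots))).max() == 0

    def test_linearity_in_weights(self, small_problem, rng):
        plan, A = small_problem
        w = rng.uniform(size=len(plan.spots))
        np.testing.assert_allclose(A @ (2 * w), 2 * (A @ w), rtol=1e-12)

    def test_columns_match_individual_spot_doses(self, water_box):
        """Dense reconstruction against voxelwise sum of spot_dose calls."""
        spots = [de.Spot(20.0, 20.0, 25.0), de.Spot(30.0, 25.0, 30.0),
                 de.Spot(25.0, 30.0, 20.0), de.Spot(22.5, 22.5, 35.0)]
        plan = de.SpotPlan(spots)
        cfg = de.EngineConfig(sparsity_cutoff=0.0)
        A = de.influence_matrix(plan, water_box, cfg)
        wed = de.wed_grid(water_box)
        w = np.array([1.0, 0.5, 2.0, 0.25])
        expected = sum(
            wi * de.spot_dose(s, wed).values for wi, s in zip(w, plan.spots)
        )
        np.testing.assert_allclose(
            (A @ w).reshape(water_box.shape), expected, atol=1e-10
        )

    def test_memory_guard(self, water_box):
        plan = de.SpotPlan([de.Spot(0, 0, 10.0)])
        with pytest.raises(MemoryError):
            de.influence_matrix(plan, water_box, de.EngineConfig(max_voxels=10))

    def test_nominal_scenario_bit_identical(self, water_box):
        plan = de.SpotPlan([de.Spot(25.0, 25.0, 30.0)])
        A0 = de.influence_matrix(plan, water_box)
        A1 = de.influence_matrix(plan, water_box, scenario=de.Scenario((0.0, 0.0, 0.0), 1.0))
        assert (A0 != A1).nnz == 0

    def test_mirrored_shifts_mirror_dose(self, water_box):
        """On a symmetric phantom, +x and -x setup shifts give mirrored dose."""
        plan = de.SpotPlan([de.Spot(23.75, 23.75, 30.0)])  # grid-symmetric center
        plus = de.influence_matrix(plan, water_box, scenario=de.Scenario((5.0, 0, 0)))
        minus = de.influence_matrix(plan, water_box, scenario=de.Scenario((-5.0, 0, 0)))
        dp = np.asarray(plus.todense()).reshape(water_box.shape)
        dm = np.asarray(minus.todense()).reshape(water_box.shape)
        np.testing.assert_allclose(dp, dm[::-1], atol=1e-12)


class TestPlaceSpots:
    def test_single_voxel_target_is_covered(self, water_box):
        tgt = np.zeros(water_box.shape, dtype=bool)
        tgt[10, 10, 10] = True
        plan = de.place_spots(RoiMask("t", tgt, role="target"), water_box,
                              margin_mm=2.5, lateral_spacing_mm=5.0, layer_spacing_mm=5.0)
        x = 10 * 2.5
        assert any(abs(s.u - x) <= 5.0 and abs(s.v - x) <= 5.0 for s in plan.spots)

    def test_margin_monotone_in_spot_count(self, water_box):
        tgt = np.zeros(water_box.shape, dtype=bool)
        tgt[8:12, 8:12, 8:12] = True
        m = RoiMask("t", tgt, role="target")
        n_small = len(de.place_spots(m, water_box, margin_mm=2.5).spots)
        n_large = len(de.place_spots(m, water_box, margin_mm=10.0).spots)
        assert n_large >= n_small

    def test_empty_target_rejected(self, water_box):
        with pytest.raises(ValueError, match="empty"):
            de.place_spots(RoiMask("t", np.zeros(water_box.shape, bool)), water_box)

    def test_range_layer_coverage_on_default_phantom(self, default_phantom):
        structures, density = default_phantom
        tgt = structures["PTV chest wall"].values | structures["PTV nodes"].values
        spacing = 7.5
        plan = de.place_spots(
            RoiMask("t", tgt, role="target"), density,
            margin_mm=12.0, lateral_spacing_mm=spacing, layer_spacing_mm=spacing,
        )
        wed = de.wed_grid(density).values
        ranges = np.array([s.range_mm for s in plan.spots])
        worst = max(np.abs(ranges - w).min() for w in wed[tgt])
        assert worst <= spacing
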