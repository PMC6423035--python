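"""Loading scenarios on the desk phantom: load bookkeeping, region
statistics, scenario comparisons, superposition, damage response."""

import numpy as np
import pytest

from nestmech import scenarios as sc
from nestmech.voxfem import FEError, MaterialModel


class TestLoadConversion:
    def test_bird_weight_truncates_to_4_decimals(self):
        assert sc.mass_to_force(16.0) == 0.1569

    def test_egg_weight_truncates_to_4_decimals(self):
        assert sc.mass_to_force(1.2) == 0.0117

    def test_truncation_not_rounding(self):
        # 16 g * 9.80665 = 0.1569064 N: rounding and truncation agree;
        # 1.2 g * 9.80665 = 0.01176798 N: rounding would give 0.0118
        assert sc.mass_to_force(1.2) != round(1.2e-3 * 9.80665, 4)


class TestScenarioConstruction:
    def test_worst_case_has_four_load_sets_with_exact_total(self, desk_scenarios):
        model, _ = desk_scenarios.model("worst_case")
        assert len(model.load_sets) == 4
        total = model.total_applied_force(gravity=False)
        assert total[0] == pytest.approx(-(2 * 0.1569 + 2 * 0.0117), abs=1e-12)
        assert total[1] == total[2] == 0.0

    def test_eggs_only_totals_two_egg_weights(self, desk_scenarios):
        model, _ = desk_scenarios.model("eggs_only")
        assert len(model.load_sets) == 2
        total = model.total_applied_force(gravity=False)
        assert total[0] == pytest.approx(-0.0234, abs=1e-12)

    def test_nodal_shares_sum_to_roi_force(self, desk_scenarios):
        from nestmech.voxfem import load_vector
        model, _ = desk_scenarios.model("worst_case")
        f = load_vector(model, gravity=False)
        assert f.reshape(-1, 3)[:, 0].sum() == pytest.approx(
            -(2 * 0.1569 + 2 * 0.0117), abs=1e-10)

    def test_construction_is_deterministic(self, desk_seg, desk_gray):
        mask, _, _ = desk_seg
        m1, p1 = sc.make_scenario("worst_case", mask, desk_gray,
                                  MaterialModel(total_mass_g=5.93))
        m2, p2 = sc.make_scenario("worst_case", mask, desk_gray,
                                  MaterialModel(total_mass_g=5.93))
        for name in m1.load_sets:
            np.testing.assert_array_equal(m1.load_sets[name][0],
                                          m2.load_sets[name][0])
        np.testing.assert_array_equal(m1.pinned_nodes, m2.pinned_nodes)

    def test_bird_rois_sit_on_the_rim_band(self, desk_scenarios):
        model, placement = desk_scenarios.model("worst_case")
        rim_start = placement["rim_start_index"]
        for name, (ids, _f) in model.load_sets.items():
            if name.startswith("bird"):
                # all loaded nodes in the top band of the structure
                assert (model.nodes[ids, 0] / model.spacing
                        >= rim_start).all()

    def test_unknown_scenario_rejected(self, desk_seg):
        mask, _, _ = desk_seg
        with pytest.raises(FEError, match="unknown scenario"):
            sc.make_scenario("hurricane", mask)


class TestScenarioPhysics:
    def test_peak_stress_below_fracture_strength(self, desk_scenarios):
        _, _, report, _ = desk_scenarios.solved("worst_case", gravity=True)
        assert report.global_max_principal < 2.75
        assert report.safety_factor > 1.0

    def test_egg_region_quieter_than_rim(self, desk_scenarios):
        _, _, report, _ = desk_scenarios.solved("worst_case", gravity=True)
        rs = report.region_stats
        assert rs["egg_region"].mean < rs["rim_band"].mean

    def test_anchor_band_isolated_from_rim_stress(self, desk_scenarios):
        _, _, report, _ = desk_scenarios.solved("worst_case", gravity=True)
        rs = report.region_stats
        assert rs["anchor_band"].mean < rs["rim_band"].mean

    def test_region_maxima_bounded_by_global_max(self, desk_scenarios):
        _, _, report, _ = desk_scenarios.solved("worst_case", gravity=True)
        for st in report.region_stats.values():
            assert st.max <= report.global_max_principal + 1e-12

    def test_stress_decays_rim_to_anchor_along_bf(self, desk_scenarios):
        model, _, _, field = desk_scenarios.solved("worst_case", gravity=True)
        # per-slice mean max-principal stress along B-F: the rim third (far
        # from the wall, where the birds load the lip) runs hotter than the
        # anchor third against the wall
        j = model.elem_index[:, 1]
        depth = j.max() + 1
        slice_means = np.array([field.max_principal[j == jj].mean()
                                for jj in range(depth)])
        third = depth // 3
        assert slice_means[2 * third:].mean() > slice_means[:third].mean()

    def test_eggs_only_peak_below_worst_case(self, desk_scenarios):
        _, _, worst, _ = desk_scenarios.solved("worst_case", gravity=True)
        _, _, eggs, _ = desk_scenarios.solved("eggs_only", gravity=True)
        assert eggs.global_max_principal < worst.global_max_principal

    def test_superposition_of_load_cases(self, desk_scenarios):
        # linear solver: worst-case field (no gravity) equals the sum of
        # the eggs-only and birds-only fields element-wise
        _, _, _, fw = desk_scenarios.solved("worst_case", gravity=False)
        _, _, _, fe = desk_scenarios.solved("eggs_only", gravity=False)
        _, _, _, fb = desk_scenarios.solved("birds_only", gravity=False)
        scale = np.abs(fw.stress_tensor).max()
        np.testing.assert_allclose(fe.stress_tensor + fb.stress_tensor,
                                   fw.stress_tensor, atol=5e-6 * scale)

    def test_zero_load_scenario_reports_infinite_safety(self, desk_seg,
                                                        desk_gray):
        mask, _, _ = desk_seg
        cfg = sc.ScenarioConfig(bird_force=0.0, egg_force=0.0)
        model, placement = sc.make_scenario(
            "worst_case", mask, desk_gray,
            MaterialModel(total_mass_g=5.93), cfg)
        report, field = sc.run_scenario(model, placement, "zero",
                                        gravity=False)
        assert report.global_max_principal == 0.0
        assert report.safety_infinite
        assert report.safety_factor == np.inf

    def test_damage_concentrates_stress(self, desk_scenarios, desk_seg,
                                        desk_gray):
        mask, _, _ = desk_seg
        _, _, worst, _ = desk_scenarios.solved("worst_case", gravity=True)
        # carve a damage ball just below the rim near a bird position
        model_w, placement = desk_scenarios.model("worst_case")
        bird_ids, _ = model_w.load_sets["bird_1"]
        c = model_w.nodes[bird_ids].mean(axis=0)
        site = ((c[0] - 4.0, c[1], c[2]), 3.0)
        model_d, placement_d = sc.make_scenario(
            "damaged", mask, desk_gray, MaterialModel(total_mass_g=5.93),
            damage_sites=[site])
        damaged, _ = sc.run_scenario(model_d, placement_d, "damaged")
        assert damaged.global_max_principal >= worst.global_max_principal


class TestComparison:
    def test_identical_reports_ratio_one(self, desk_scenarios):
        _, _, report, _ = desk_scenarios.solved("worst_case", gravity=True)
        df = sc.compare_scenarios([report, report])
        assert df.max_ratio_to_first.iloc[1] == pytest.approx(1.0)

    def test_scenario_table_ratios(self, desk_scenarios):
        _, _, worst, _ = desk_scenarios.solved("worst_case", gravity=True)
        _, _, eggs, _ = desk_scenarios.solved("eggs_only", gravity=True)
        df = sc.compare_scenarios([worst, eggs])
        assert df.max_ratio_to_first.iloc[1] < 1.0
        assert {"rim_band_mean_MPa", "egg_region_mean_MPa"} <= set(df.columns)

    def test_report_serializes_to_json(self, desk_scenarios, tmp_path):
        import json
        _, _, report, _ = desk_scenarios.solved("worst_case", gravity=True)
        d = report.to_dict()
        json.dumps(d)
        assert d["region_stats"]["rim_band"]["n_elements"] > 0
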