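import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmspar import (
    DemandUnit,
    ModeSpec,
    Scene,
    SupplySite,
    TravelTimeMatrix,
    default_modes,
    e2sfca_single_mode,
    run_access,
    spai_multimodal,
    spar,
    supply_ratio_multimodal,
)
from mmspar.access import compile_scene
from mmspar.decay import CAR_SCHEME

from conftest import random_scene

W_CAR_5 = math.exp(-25 / 140)  # 0.83646...
W_BUS_45 = math.exp(-2025 / 440)  # 0.01003...


def conservation_sides(scene, modes):
    """Independent brute-force evaluation of the conservation identity."""
    result = run_access(scene, modes)
    lhs = 0.0
    for unit in scene.demand:
        for spec in modes:
            lhs += unit.populations.get(spec.name, 0.0) * result.spai_by_mode.loc[
                unit.id, spec.name
            ]
    # sites with positive step-1 denominator, by direct summation
    rhs = 0.0
    for i, site in enumerate(scene.supply):
        denom = 0.0
        for unit in scene.demand:
            for spec in modes:
                t = scene.matrices[spec.name].get(unit.id, site.id)
                if t is not None and t <= spec.threshold:
                    from mmspar.decay import subzone_weight

                    denom += unit.populations.get(spec.name, 0.0) * subzone_weight(
                        t, spec.scheme, spec.beta
                    )
        if denom > 0:
            rhs += site.capacity
    return lhs, rhs


class TestSupplyRatio:
    def test_single_unit_car_only(self):
        scene = Scene(
            supply=[SupplySite("s0", 10.0)],
            demand=[DemandUnit("u0", {"car": 100.0, "bus": 0.0})],
            matrices={
                "car": TravelTimeMatrix("car", {("u0", "s0"): 5.0}),
                "bus": TravelTimeMatrix("bus", {}),
            },
        )
        r = supply_ratio_multimodal(scene, default_modes(140, 440))
        assert r[0] == pytest.approx(10 / (100 * W_CAR_5), rel=1e-9)
        assert r[0] == pytest.approx(0.11955, abs=5e-6)

    def test_single_unit_two_modes(self, two_mode_unit_scene):
        r = supply_ratio_multimodal(two_mode_unit_scene, default_modes(140, 440))
        expected = 10 / (100 * W_CAR_5 + 50 * W_BUS_45)
        assert r[0] == pytest.approx(expected, rel=1e-12)
        assert r[0] == pytest.approx(0.11884, abs=5e-6)

    def test_zero_denominator_site_gets_zero_ratio(self):
        scene = Scene(
            supply=[SupplySite("s0", 10.0)],
            demand=[DemandUnit("u0", {"car": 100.0})],
            matrices={"car": TravelTimeMatrix("car", {("u0", "s0"): 99.0})},
        )
        r = supply_ratio_multimodal(scene, [default_modes()[0]])
        assert r[0] == 0.0

    def test_missing_matrix_mode_rejected(self, two_mode_unit_scene):
        modes = default_modes() + [ModeSpec("bike", 30.0, CAR_SCHEME, 200.0)]
        with pytest.raises(ValueError, match="bike"):
            supply_ratio_multimodal(two_mode_unit_scene, modes)

    def test_unknown_od_id_rejected(self):
        scene = Scene(
            supply=[SupplySite("s0", 10.0)],
            demand=[DemandUnit("u0", {"car": 1.0})],
            matrices={"car": TravelTimeMatrix("car", {("ghost", "s0"): 5.0})},
        )
        with pytest.raises(ValueError, match="ghost"):
            supply_ratio_multimodal(scene, [default_modes()[0]])


class TestSpai:
    def test_single_unit_two_modes(self, two_mode_unit_scene):
        modes = default_modes(140, 440)
        r = supply_ratio_multimodal(two_mode_unit_scene, modes)
        spai, integrated = spai_multimodal(r, two_mode_unit_scene, modes)
        assert spai.loc["u0", "car"] == pytest.approx(0.09940, abs=5e-6)
        assert spai.loc["u0", "bus"] == pytest.approx(0.00119, abs=5e-6)
        assert integrated["u0"] == pytest.approx(0.10059, abs=1e-5)

    def test_integrated_is_exact_sum(self):
        scene = random_scene(3)
        result = run_access(scene, default_modes())
        np.testing.assert_array_equal(
            result.spai_integrated.to_numpy(),
            result.spai_by_mode.sum(axis=1).to_numpy(),
        )

    def test_unreachable_unit_scores_zero(self):
        scene = Scene(
            supply=[SupplySite("s0", 10.0)],
            demand=[
                DemandUnit("near", {"car": 10.0}),
                DemandUnit("far", {"car": 10.0}),
            ],
            matrices={"car": TravelTimeMatrix("car", {("near", "s0"): 5.0})},
        )
        result = run_access(scene, [default_modes()[0]])
        assert result.spai_integrated["far"] == 0.0
        assert result.spai_integrated["near"] > 0.0

    def test_wrong_ratio_length_rejected(self, two_mode_unit_scene):
        with pytest.raises(ValueError, match="site"):
            spai_multimodal(np.zeros(3), two_mode_unit_scene, default_modes())

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_scenes(self, seed):
        scene = random_scene(seed, n_sites=12, n_units=30)
        lhs, rhs = conservation_sides(scene, default_modes())
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_conservation_large_scene(self):
        scene = random_scene(99, n_sites=50, n_units=100)
        lhs, rhs = conservation_sides(scene, default_modes())
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_adding_supply_site_never_decreases_scores(self):
        scene = random_scene(7, n_sites=8, n_units=25)
        base = run_access(scene, default_modes())
        extra_entries = dict(scene.matrices["car"].entries)
        for unit in scene.demand:
            extra_entries[(unit.id, "s_new")] = 12.0
        bigger = Scene(
            supply=scene.supply + [SupplySite("s_new", 5.0)],
            demand=scene.demand,
            matrices={
                "car": TravelTimeMatrix("car", extra_entries),
                "bus": scene.matrices["bus"],
            },
        )
        more = run_access(bigger, default_modes())
        assert (
            more.spai_by_mode.to_numpy() >= base.spai_by_mode.to_numpy() - 1e-15
        ).all()


class TestSpar:
    def test_simple_vector(self):
        ratios, mean, flag = spar([2.0, 4.0])
        assert ratios.tolist() == [2 / 3, 4 / 3]
        assert mean == 3.0
        assert not flag

    def test_constant_vector_all_ones(self):
        ratios, _, _ = spar([5.0, 5.0, 5.0])
        assert ratios.tolist() == [1.0, 1.0, 1.0]

    def test_mean_is_one(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 10, size=200)
        ratios, _, _ = spar(values)
        assert ratios.mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_flags_no_access(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            ratios, mean, flag = spar([0.0, 0.0])
        assert flag
        assert mean == 0.0
        assert ratios.tolist() == [0.0, 0.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spar([])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            spar([1.0, -0.1])


class TestRunAccess:
    def test_single_unit_spar_is_one(self, two_mode_unit_scene):
        result = run_access(two_mode_unit_scene, default_modes(140, 440))
        assert result.spar_integrated["u0"] == 1.0
        assert not result.no_access_flags["integrated"]

    def test_mean_spar_one_per_family(self):
        scene = random_scene(11, n_sites=15, n_units=40)
        result = run_access(scene, default_modes())
        for mode in result.modes:
            assert result.spar_by_mode[mode].mean() == pytest.approx(1.0, abs=1e-12)
        assert result.spar_integrated.mean() == pytest.approx(1.0, abs=1e-12)

    def test_permuting_demand_order_is_invariant(self):
        scene = random_scene(13, n_sites=8, n_units=20)
        shuffled = Scene(
            supply=scene.supply,
            demand=list(reversed(scene.demand)),
            matrices=scene.matrices,
        )
        a = run_access(scene, default_modes())
        b = run_access(shuffled, default_modes())
        # scores are permutation-invariant up to float summation order
        for uid in a.unit_ids:
            assert a.spai_integrated[uid] == pytest.approx(
                b.spai_integrated[uid], rel=1e-12
            )
            assert a.spar_integrated[uid] == pytest.approx(
                b.spar_integrated[uid], rel=1e-12
            )

    def test_capacity_scaling(self):
        scene = random_scene(17, n_sites=10, n_units=25)
        doubled = Scene(
            supply=[
                SupplySite(s.id, s.capacity * 2, s.x, s.y) for s in scene.supply
            ],
            demand=scene.demand,
            matrices=scene.matrices,
        )
        a = run_access(scene, default_modes())
        b = run_access(doubled, default_modes())
        np.testing.assert_allclose(
            b.spai_by_mode.to_numpy(), 2 * a.spai_by_mode.to_numpy(), rtol=1e-12
        )
        np.testing.assert_allclose(
            b.spar_integrated.to_numpy(),
            a.spar_integrated.to_numpy(),
            rtol=1e-12,
        )

    def test_population_scaling_leaves_spar_unchanged(self):
        scene = random_scene(19, n_sites=10, n_units=25)
        scaled = Scene(
            supply=scene.supply,
            demand=[
                DemandUnit(u.id, {m: 3 * p for m, p in u.populations.items()})
                for u in scene.demand
            ],
            matrices=scene.matrices,
        )
        a = run_access(scene, default_modes())
        b = run_access(scaled, default_modes())
        np.testing.assert_allclose(
            b.spar_by_mode.to_numpy(), a.spar_by_mode.to_numpy(), rtol=1e-12
        )

    def test_sd_spar_equals_cv_spai(self):
        scene = random_scene(23, n_sites=12, n_units=30)
        result = run_access(scene, default_modes())
        for mode in result.modes:
            spai = result.spai_by_mode[mode]
            spar_v = result.spar_by_mode[mode]
            cv = spai.std(ddof=1) / spai.mean()
            assert spar_v.std(ddof=1) == pytest.approx(cv, rel=1e-12)
            assert spar_v.std(ddof=1) / spar_v.mean() == pytest.approx(cv, rel=1e-12)

    def test_all_scores_non_negative(self):
        scene = random_scene(29)
        result = run_access(scene, default_modes())
        assert (result.spai_by_mode.to_numpy() >= 0).all()
        assert (result.spar_by_mode.to_numpy() >= 0).all()
        assert (result.site_ratios >= 0).all()

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariants_hold_for_any_seed(self, seed):
        scene = random_scene(seed, n_sites=6, n_units=12)
        result = run_access(scene, default_modes())
        lhs, rhs = conservation_sides(scene, default_modes())
        assert lhs == pytest.approx(rhs, rel=1e-9)
        if result.spai_integrated.mean() > 0:
            assert result.spar_integrated.mean() == pytest.approx(1.0, abs=1e-12)


class TestSingleModeBaseline:
    def test_one_site_one_unit(self):
        scene = Scene(
            supply=[SupplySite("s0", 10.0)],
            demand=[DemandUnit("u0", {"car": 100.0})],
            matrices={"car": TravelTimeMatrix("car", {("u0", "s0"): 15.0})},
        )
        mode = default_modes(140, 440)[0]
        result = e2sfca_single_mode(scene, mode)
        w15 = math.exp(-225 / 140)
        assert result.site_ratios[0] == pytest.approx(10 / (100 * w15), rel=1e-12)
        assert result.site_ratios[0] == pytest.approx(0.4989, abs=1e-4)
        # algebraically (C / (P w)) * w = C / P exactly
        assert result.spai_integrated["u0"] == pytest.approx(0.1, abs=1e-12)

    def test_reduces_to_multimodal_with_one_mode(self):
        scene = random_scene(31, modes=("car",))
        mode = default_modes()[0]
        single = e2sfca_single_mode(scene, mode)
        multi = run_access(scene, [mode])
        np.testing.assert_array_equal(
            single.spai_integrated.to_numpy(), multi.spai_integrated.to_numpy()
        )
        np.testing.assert_array_equal(single.site_ratios, multi.site_ratios)

    def test_uses_total_population(self, two_mode_unit_scene):
        mode = default_modes(140, 440)[0]
        result = e2sfca_single_mode(two_mode_unit_scene, mode)
        # denominator uses 150 people at 5 car-min
        assert result.site_ratios[0] == pytest.approx(10 / (150 * W_CAR_5), rel=1e-12)

    def test_car_only_baseline_below_multimodal_car_spai(self, default_scene):
        modes = default_modes(140, 440)
        multi = run_access(default_scene, modes)
        single = e2sfca_single_mode(default_scene, modes[0])
        assert (
            single.spai_integrated.mean() < multi.spai_by_mode["car"].mean()
        )


class TestContinuousWeighting:
    def test_continuous_uses_exact_times(self):
        scene = Scene(
            supply=[SupplySite("s0", 10.0)],
            demand=[DemandUnit("u0", {"car": 100.0})],
            matrices={"car": TravelTimeMatrix("car", {("u0", "s0"): 8.0})},
        )
        mode = ModeSpec("car", 30.0, CAR_SCHEME, 140.0, continuous=True)
        r = supply_ratio_multimodal(scene, [mode])
        assert r[0] == pytest.approx(10 / (100 * math.exp(-64 / 140)), rel=1e-12)


class TestSceneValidation:
    def test_duplicate_site_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Scene(
                supply=[SupplySite("s0", 1.0), SupplySite("s0", 2.0)],
                demand=[DemandUnit("u0", {"car": 1.0})],
                matrices={},
            )

    def test_duplicate_unit_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Scene(
                supply=[SupplySite("s0", 1.0)],
                demand=[DemandUnit("u0", {"car": 1.0}), DemandUnit("u0", {"car": 2.0})],
                matrices={},
            )

    def test_negative_capacity_rejected(self):
        with pytest.raises(ValueError):
            SupplySite("s0", -1.0)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            DemandUnit("u0", {"car": -5.0})

    def test_negative_travel_time_rejected(self):
        with pytest.raises(ValueError):
            TravelTimeMatrix("car", {("u0", "s0"): -1.0})

    def test_compiled_scene_mismatch_rejected(self):
        scene_a = random_scene(1)
        scene_b = random_scene(2)
        comp = compile_scene(scene_a, default_modes())
        with pytest.raises(ValueError, match="compiled"):
            run_access(scene_b, default_modes(), comp)
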