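"""Carbon economy, Michaelis-Menten uptake and the N-stress index."""

import dataclasses

import numpy as np
import pytest

from rhizosim import (
    ImpedanceField,
    PlantState,
    ScenarioConfig,
    allocate_carbon,
    build_density_profile,
    elongate_tips,
    initialize_root_system,
    nitrate_uptake,
    nitrogen_stress,
    photosynthesis,
    respiration,
    run_simulation,
    stress_feedback,
)
from rhizosim.config import (
    ConfigurationError,
    EmergenceEvent,
    PlantParams,
    default_root_classes,
)
from rhizosim.plant import n_demand

PP = PlantParams()
GROUND = 60.0 * 26.0


def one_segment_system(length=10.0, rng_seed=0):
    """A system holding a single vertical primary segment of given length."""
    classes = dict(default_root_classes())
    classes["primary"] = dataclasses.replace(
        classes["primary"], potential_elongation=length, wobble_sd=0.0,
        gravitropism=0.0)
    system = initialize_root_system(
        classes, (EmergenceEvent(0.0, "primary", 0.0),),
        np.random.default_rng(rng_seed))
    field = ImpedanceField.from_table([(0.0, 0.0), (150.0, 0.0)])
    elongate_tips(system, field, 100.0, 1.0, 1.0, np.random.default_rng(0))
    return system


class TestPhotosynthesis:
    def test_no_leaves_no_carbon(self):
        plant = PlantState(shoot_c=0.1, leaf_area=0.0, reserve_c=0.0)
        assert photosynthesis(plant, PP, 1.0, 1.0, GROUND) == 0.0

    def test_full_stress_shuts_down_fixation(self):
        plant = PlantState(shoot_c=0.1, leaf_area=500.0, reserve_c=0.0)
        assert photosynthesis(plant, PP, 0.0, 1.0, GROUND) == 0.0

    def test_saturates_with_canopy_closure(self):
        big = PlantState(shoot_c=1.0, leaf_area=6.0 * GROUND, reserve_c=0.0)
        huge = PlantState(shoot_c=1.0, leaf_area=12.0 * GROUND, reserve_c=0.0)
        p1 = photosynthesis(big, PP, 1.0, 1.0, GROUND)
        p2 = photosynthesis(huge, PP, 1.0, 1.0, GROUND)
        assert (p2 - p1) / p1 < 0.05


class TestRespiration:
    def test_empty_system_only_shoot_maintenance(self):
        plant = PlantState(shoot_c=2.0, leaf_area=100.0, reserve_c=0.0)
        root, shoot = respiration(None, plant, PP, 1.0)
        assert root == 0.0
        assert shoot == pytest.approx(PP.shoot_maint_resp * 2.0)

    def test_linear_in_segment_biomass(self):
        plant = PlantState(shoot_c=0.0, leaf_area=0.0, reserve_c=0.0)
        r1, _ = respiration(one_segment_system(5.0), plant, PP, 1.0)
        r2, _ = respiration(one_segment_system(10.0), plant, PP, 1.0)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-9)

    def test_hand_ledger_single_segment(self):
        system = one_segment_system(10.0)
        cls = system.classes["primary"]
        biomass = np.pi / 4.0 * cls.base_diameter ** 2 * 10.0 * cls.tissue_density
        expected = cls.respiration_coeff * biomass
        plant = PlantState(shoot_c=0.0, leaf_area=0.0, reserve_c=0.0)
        root, _ = respiration(system, plant, PP, 1.0)
        assert root == pytest.approx(expected, abs=1e-12)


class TestAllocation:
    @pytest.mark.parametrize("available,root,shoot,expected", [
        (10.0, 2.0, 3.0, (2.0, 3.0)),      # unconstrained
        (2.5, 2.0, 3.0, (1.0, 1.5)),       # proportional rationing
        (5.0, 0.0, 3.0, (0.0, 3.0)),       # all to shoot
    ])
    def test_examples(self, available, root, shoot, expected):
        assert allocate_carbon(available, root, shoot) == pytest.approx(expected)

    def test_never_exceeds_available(self):
        to_root, to_shoot = allocate_carbon(1.0, 5.0, 7.0)
        assert to_root + to_shoot <= 1.0 + 1e-12


class TestUptake:
    def test_no_nitrate_no_uptake(self):
        grid = build_density_profile("uniform")
        grid.nitrate_mass[:] = 0.0
        per_layer, total = nitrate_uptake(one_segment_system(), grid, 1.0)
        assert total == 0.0

    def test_half_saturation_identity(self):
        system = one_segment_system(length=1.0)
        grid = build_density_profile("uniform")
        cls = system.classes["primary"]
        layer = int(grid.layer_index(float(system.seg_end[0, 2]
                                           + system.seg_start[0, 2]) / 2.0))
        # set the segment's layer to exactly C = Km
        solution = grid.theta[layer] * grid.layer_volume_cm3[layer]
        grid.nitrate_mass[:] = 0.0
        grid.nitrate_mass[layer] = cls.uptake_Km * solution
        surface = np.pi * cls.base_diameter * 1.0
        _, total = nitrate_uptake(system, grid, 1.0)
        assert total == pytest.approx(cls.uptake_Imax / 2.0 * surface, rel=1e-9)

    def test_layer_never_overdrawn_and_split_pro_rata(self):
        system = one_segment_system(length=30.0)  # large demand
        grid = build_density_profile("uniform")
        layers = np.unique(grid.layer_index(
            0.5 * (system.seg_start[:, 2] + system.seg_end[:, 2])))
        grid.nitrate_mass[:] = 0.0
        grid.nitrate_mass[layers] = 1e-3  # nearly empty layers
        per_layer, total = nitrate_uptake(system, grid, 1.0)
        assert total == pytest.approx(1e-3 * len(layers), rel=1e-9)
        assert np.all(grid.nitrate_mass >= -1e-15)

    def test_grid_decrement_matches_reported_uptake(self):
        system = one_segment_system()
        grid = build_density_profile("uniform")
        grid.nitrate_mass[:] = 50.0
        before = grid.nitrate_mass.sum()
        _, total = nitrate_uptake(system, grid, 1.0)
        assert before - grid.nitrate_mass.sum() == pytest.approx(total, rel=1e-12)


class TestNitrogenStress:
    @pytest.mark.parametrize("u,o,m,expected", [
        (2.0, 2.0, 1.0, 0.0),      # acquired = optimal: no stress
        (1.0, 2.0, 1.0, 100.0),    # acquired = minimal: severe stress
        (1.5, 2.0, 1.0, 50.0),     # linear midpoint
        (3.0, 2.0, 1.0, 0.0),      # clamped above optimal
        (0.0, 2.0, 1.0, 100.0),    # clamped below minimal
    ])
    def test_index_examples(self, u, o, m, expected):
        assert nitrogen_stress(u, o, m) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_demand_rejected(self):
        with pytest.raises(ConfigurationError):
            nitrogen_stress(1.0, 1.0, 1.0)

    def test_demand_curves_monotone_in_biomass(self):
        dws = np.linspace(0.1, 30.0, 20)
        os_, ms = zip(*(n_demand(dw, PP) for dw in dws))
        assert np.all(np.diff(os_) > 0) and np.all(np.diff(ms) > 0)
        assert all(m < o for o, m in zip(os_, ms))


class TestStressFeedback:
    def test_endpoints_and_midpoint(self):
        assert stress_feedback(0.0, PP) == (1.0, 1.0, 1.0)
        assert stress_feedback(100.0, PP) == pytest.approx(
            (PP.photo_floor, PP.leaf_floor, PP.root_floor))
        mid = stress_feedback(50.0, PP)
        assert mid == pytest.approx(
            ((1 + PP.photo_floor) / 2, (1 + PP.leaf_floor) / 2,
             (1 + PP.root_floor) / 2))

    def test_roots_penalized_least(self):
        photo, leaf, root = stress_feedback(80.0, PP)
        assert root > photo and root > leaf


class TestStarvation:
    def test_zero_nitrate_drives_stress_to_maximum(self):
        """With essentially no soil N, stress saturates and shoot growth
        approaches the floor-limited minimum."""
        cfg = ScenarioConfig(duration=18.0, seed=0, n_layers=75,
                             initial_nitrate_kg_ha=1e-6)
        cfg.plant = dataclasses.replace(cfg.plant, seed_n_umol=1.0)
        starved = run_simulation(cfg)
        fed = run_simulation(ScenarioConfig(duration=18.0, seed=0, n_layers=75))
        assert starved.daily.stress_pct.iloc[-1] == pytest.approx(100.0, abs=1e-9)
        assert starved.daily.shoot_dw.iloc[-1] < fed.daily.shoot_dw.iloc[-1]
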