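"""Root system growth: elongation contracts, branching bookkeeping,
reflection and the impedance-only soil coupling."""

import dataclasses

import numpy as np
import pytest

from rhizosim import (
    ImpedanceField,
    ImpedanceParams,
    branch,
    elongate_tips,
    initialize_root_system,
    reflect_heading,
)
from rhizosim.config import (
    ConfigurationError,
    EmergenceEvent,
    default_emergence_schedule,
    default_root_classes,
)

FLAT_SOFT = ImpedanceField.from_table([(0.0, 0.0), (150.0, 0.0)])       # R_I = 1
FLAT_HALF = ImpedanceField.from_table([(0.0, 1000.0), (150.0, 1000.0)])  # R_I = 0.5
PRIMARY_ONLY = (EmergenceEvent(0.0, "primary", 0.0),)


def primary_system(rate=2.0, rng=None, spacing=None):
    classes = dict(default_root_classes())
    overrides = dict(potential_elongation=rate, wobble_sd=0.0, gravitropism=0.0)
    if spacing is not None:
        overrides["branch_spacing"] = spacing
    classes["primary"] = dataclasses.replace(classes["primary"], **overrides)
    return initialize_root_system(classes, PRIMARY_ONLY,
                                  rng or np.random.default_rng(0))


class TestInitialization:
    def test_primary_tip_present_at_day_zero(self):
        system = initialize_root_system(default_root_classes(),
                                        default_emergence_schedule(),
                                        np.random.default_rng(0))
        assert len(system.tip_age) == 1
        assert system.root_class_of[0] == "primary"
        assert np.allclose(system.tip_heading[0], [0, 0, 1])

    def test_identical_seed_gives_identical_system(self):
        kw = dict(classes=default_root_classes(),
                  schedule=default_emergence_schedule())
        a = initialize_root_system(rng=np.random.default_rng(11), **kw)
        b = initialize_root_system(rng=np.random.default_rng(11), **kw)
        assert [e.day for e in a.emergence_queue] == [e.day for e in b.emergence_queue]
        assert np.array_equal(a.tip_heading, b.tip_heading)

    def test_scheduled_seminals_emerge_by_their_day(self):
        rng = np.random.default_rng(0)
        system = initialize_root_system(default_root_classes(),
                                        default_emergence_schedule(), rng)
        for day in range(1, 4):
            system.time = float(day)
            branch(system, 1.0, rng)
        assert system.root_class_of.count("seminal") == 4

    def test_missing_lateral_class_rejected(self):
        classes = {k: v for k, v in default_root_classes().items() if k != "lateral"}
        with pytest.raises(ConfigurationError):
            initialize_root_system(classes, PRIMARY_ONLY, np.random.default_rng(0))


class TestElongation:
    def test_unimpeded_growth_matches_potential_rate(self):
        system = primary_system(rate=2.0)
        elongate_tips(system, FLAT_SOFT, carbon_budget=1.0, stress_multiplier=1.0,
                      dt=1.0, rng=np.random.default_rng(0))
        assert system.total_length() == pytest.approx(2.0, rel=1e-9)

    def test_halved_at_characteristic_hardness(self):
        system = primary_system(rate=2.0)
        elongate_tips(system, FLAT_HALF, carbon_budget=1.0, stress_multiplier=1.0,
                      dt=1.0, rng=np.random.default_rng(0))
        assert system.total_length() == pytest.approx(1.0, rel=1e-9)

    def test_half_budget_halves_every_tip(self):
        rng = np.random.default_rng(0)
        system = initialize_root_system(default_root_classes(),
                                        default_emergence_schedule(), rng)
        system.time = 3.0
        branch(system, 1.0, rng)  # release the seminals
        full = initialize_root_system(default_root_classes(),
                                      default_emergence_schedule(),
                                      np.random.default_rng(0))
        full.time = 3.0
        branch(full, 1.0, np.random.default_rng(0))

        from rhizosim.architecture import root_carbon_demand
        demand = root_carbon_demand(system, FLAT_SOFT, 1.0, 1.0)
        used = elongate_tips(system, FLAT_SOFT, demand / 2.0, 1.0, 1.0,
                             np.random.default_rng(1))
        elongate_tips(full, FLAT_SOFT, demand, 1.0, 1.0,
                      np.random.default_rng(1))
        assert used == pytest.approx(demand / 2.0, rel=1e-9)
        ratio = system.seg_length / full.seg_length
        assert np.allclose(ratio, 0.5, rtol=1e-9)

    def test_determinate_laterals_stop_after_growth_duration(self):
        classes = dict(default_root_classes())
        system = initialize_root_system(classes, PRIMARY_ONLY,
                                        np.random.default_rng(0))
        # convert the only tip into an over-age lateral
        system.tip_class[0] = system._class_code["lateral"]
        system.tip_age[0] = classes["lateral"].growth_duration + 1.0
        used = elongate_tips(system, FLAT_SOFT, 1.0, 1.0, 1.0,
                             np.random.default_rng(0))
        assert used == 0.0
        assert system.n_segments == 0

    def test_zero_budget_means_zero_growth(self):
        system = primary_system()
        used = elongate_tips(system, FLAT_SOFT, 0.0, 1.0, 1.0,
                             np.random.default_rng(0))
        assert used == 0.0
        assert system.total_length() == 0.0

    def test_higher_q50_never_grows_less(self):
        lengths = {}
        for q50 in (1000.0, 4000.0):
            system = primary_system(rate=3.0)
            params = ImpedanceParams({"axial": q50, "lateral": q50})
            field = ImpedanceField.from_table([(0.0, 2000.0), (150.0, 2000.0)])
            elongate_tips(system, field, 10.0, 1.0, 1.0,
                          np.random.default_rng(0), impedance_params=params)
            lengths[q50] = system.total_length()
        assert lengths[4000.0] > lengths[1000.0]


class TestBranching:
    def test_one_lateral_per_spacing_of_new_length(self):
        system = primary_system(rate=10.0, spacing=1.0)
        rng = np.random.default_rng(0)
        elongate_tips(system, FLAT_SOFT, 10.0, 1.0, 1.0, rng)
        branch(system, 1.0, rng)
        assert system.root_class_of.count("lateral") == 10

    def test_sub_spacing_remainder_carries_across_steps(self):
        system = primary_system(rate=0.4, spacing=1.0)
        rng = np.random.default_rng(0)
        for _ in range(2):
            elongate_tips(system, FLAT_SOFT, 10.0, 1.0, 1.0, rng)
            branch(system, 1.0, rng)
        assert system.root_class_of.count("lateral") == 0
        assert system.tip_since_branch[0] == pytest.approx(0.8, abs=1e-9)

    def test_laterals_never_branch(self):
        rng = np.random.default_rng(2)
        system = initialize_root_system(default_root_classes(),
                                        default_emergence_schedule(), rng)
        for day in range(12):
            system.time = float(day + 1)
            elongate_tips(system, FLAT_SOFT, 10.0, 1.0, 1.0, rng)
            branch(system, 1.0, rng)
        lateral_ids = {i for i, c in enumerate(system.root_class_of)
                       if c == "lateral"}
        parents_of_laterals = {system.root_parent[i] for i in lateral_ids}
        assert parents_of_laterals.isdisjoint(lateral_ids)


class TestReflection:
    @pytest.mark.parametrize("pos,heading,expected", [
        ((60.0, 13.0, 50.0), (1.0, 0.0, 0.0), (-1.0, 0.0, 0.0)),
        ((30.0, 13.0, 50.0), (0.0, 0.0, 1.0), (0.0, 0.0, 1.0)),
        ((60.0, 13.0, 50.0), (0.6, 0.0, 0.8), (-0.6, 0.0, 0.8)),
    ])
    def test_wall_mirroring(self, pos, heading, expected):
        out = reflect_heading(pos, heading, (60.0, 26.0, 150.0))
        assert np.allclose(out, expected)

    def test_all_segments_stay_inside_the_box(self, default_run):
        system = default_run.system
        for arr in (system.seg_start, system.seg_end):
            assert np.all(arr[:, 0] >= 0) and np.all(arr[:, 0] <= 60.0)
            assert np.all(arr[:, 1] >= 0) and np.all(arr[:, 1] <= 26.0)
            assert np.all(arr[:, 2] >= 0) and np.all(arr[:, 2] <= 150.0)


class TestSystemInvariants:
    def test_total_length_non_decreasing(self, default_run):
        lengths = default_run.daily["total_root_length"].to_numpy()
        assert np.all(np.diff(lengths) >= -1e-9)

    def test_diameters_at_least_class_base(self, default_run):
        system = default_run.system
        base = np.array([system.classes[c].base_diameter
                         for c in system.class_names])
        assert np.all(system.seg_diameter >= base[system.seg_class_code] - 1e-12)
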