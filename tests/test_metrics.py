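"""Depth profiles, quantile metrics and format round-trips."""

import numpy as np
import pandas as pd
import pytest

from rhizosim import (
    DepthProfile,
    build_density_profile,
    d50_nitrate_depth,
    d90_depth,
    export,
    length_by_depth,
    nitrate_by_depth,
    quantile_depth,
    read_rsml,
    summary_metrics,
    write_rsml,
    write_vtk,
)
from rhizosim.architecture import RootSystem
from rhizosim.config import default_root_classes


def system_with_segments(segments):
    """Build a bare system holding the given (start, end, class) segments."""
    system = RootSystem(classes=default_root_classes())
    for start, end, cls in segments:
        rid = system._new_roots([cls], [-1])
        system._append_segments(
            np.array([start]), np.array([end]),
            np.array([system._class_code[cls]]),
            np.array([system.classes[cls].base_diameter]), rid)
    return system


class TestLengthByDepth:
    def test_vertical_segment_split_across_bins(self):
        system = system_with_segments(
            [((30, 13, 0), (30, 13, 10), "primary")])
        profile = length_by_depth(system, edges=np.arange(0, 155, 5))
        assert profile.values[0] == pytest.approx(5.0)
        assert profile.values[1] == pytest.approx(5.0)
        assert profile.values[2:].sum() == 0.0

    def test_horizontal_segment_lands_in_its_bin(self):
        system = system_with_segments(
            [((10, 13, 42), (20, 13, 42), "lateral")])
        profile = length_by_depth(system, edges=np.arange(0, 155, 5))
        assert profile.values[8] == pytest.approx(10.0)  # bin [40, 45)

    def test_profile_sums_to_filtered_total(self, default_run):
        system = default_run.system
        for group in (None, "axial", "lateral"):
            profile = length_by_depth(system, class_filter=group)
            assert profile.total == pytest.approx(system.total_length(group),
                                                  rel=1e-9)

    def test_axial_and_lateral_partition_the_total(self, default_run):
        system = default_run.system
        ax = length_by_depth(system, class_filter="axial").total
        lat = length_by_depth(system, class_filter="lateral").total
        assert ax + lat == pytest.approx(system.total_length(), rel=1e-9)


class TestQuantileDepths:
    def test_uniform_profile_closed_forms(self):
        edges = np.arange(0, 101, 5)
        uniform = DepthProfile(edges, np.full(20, 3.0))
        assert d90_depth(uniform) == pytest.approx(90.0)
        edges30 = np.arange(0, 31, 5)
        assert d50_nitrate_depth(DepthProfile(edges30, np.full(6, 1.0))) \
            == pytest.approx(15.0)

    def test_single_loaded_bin_brackets_quantile(self):
        edges = np.arange(0, 155, 5)
        values = np.zeros(30)
        values[9] = 7.0  # bin [45, 50)
        d = d90_depth(DepthProfile(edges, values))
        assert 45.0 <= d <= 50.0

    def test_empty_profile_flagged_as_missing(self):
        prof = DepthProfile(np.arange(0, 155, 5), np.zeros(30))
        assert np.isnan(d90_depth(prof))

    def test_matches_brute_force_on_random_profiles(self):
        """Interpolated quantile vs an independent cumulative scan,
        1000 random profiles for each of the two quantiles."""
        rng = np.random.default_rng(42)
        edges = np.arange(0, 155, 5.0)
        for q in (0.9, 0.5):
            for _ in range(1000):
                values = rng.uniform(0, 1, 30) * (rng.uniform(0, 1, 30) > 0.3)
                if values.sum() == 0:
                    continue
                prof = DepthProfile(edges, values)
                got = quantile_depth(prof, q)
                # brute force: walk bins accumulating mass
                target = q * values.sum()
                acc = 0.0
                for b, v in enumerate(values):
                    if acc + v >= target:
                        inside = (target - acc) / v if v > 0 else 0.0
                        expected = edges[b] + inside * (edges[b + 1] - edges[b])
                        break
                    acc += v
                assert got == pytest.approx(expected, abs=1e-9)

    def test_adding_mass_below_cannot_raise_the_quantile(self):
        edges = np.arange(0, 155, 5.0)
        values = np.zeros(30)
        values[:6] = 1.0
        base = quantile_depth(DepthProfile(edges, values), 0.9)
        deeper = values.copy()
        deeper[20] = 5.0
        assert quantile_depth(DepthProfile(edges, deeper), 0.9) >= base


class TestNitrateProfile:
    def test_sums_to_grid_total(self):
        grid = build_density_profile("uniform")
        grid.nitrate_mass = np.linspace(0, 10, grid.n_layers)
        prof = nitrate_by_depth(grid)
        assert prof.total == pytest.approx(grid.nitrate_mass.sum(), rel=1e-9)


class TestSummaryMetrics:
    def test_ratio_definitions_and_bounds(self, default_run):
        table = summary_metrics(default_run)
        last = table.iloc[-1]
        assert last["uptake_per_m_root"] == pytest.approx(
            last["u_umol"] / (last["total_root_length"] / 100.0))
        assert 0.0 <= last["pct_c_to_roots"] <= 100.0

    def test_final_row_consistent_with_ledger_state(self, default_run):
        last = default_run.daily.iloc[-1]
        assert last["cumulative_root_c"] == pytest.approx(
            default_run.plant.cumulative_root_c, rel=1e-12)
        assert last["u_umol"] == pytest.approx(default_run.plant.u_umol, rel=1e-12)


class TestExports:
    def test_rsml_round_trip_preserves_geometry(self, default_run, tmp_path):
        path = tmp_path / "system.rsml"
        system = default_run.system
        write_rsml(system, path)
        roots = read_rsml(path)
        with_segments = len(np.unique(system.seg_root_id))
        assert len(roots) == with_segments  # newborn tips have no geometry yet
        n_read = sum(len(r["points"]) - 1 for r in roots)
        assert n_read == system.n_segments
        # spot-check the primary axis coordinates
        primary = next(r for r in roots if r["label"] == "primary")
        sel = system.seg_root_id == 0
        ends = system.seg_end[sel][np.argsort(system.seg_birthday[sel],
                                              kind="stable")]
        assert np.allclose(primary["points"][1:], ends, atol=1e-6)

    def test_vtk_has_one_polyline_per_root(self, default_run, tmp_path):
        path = tmp_path / "system.vtk"
        write_vtk(default_run.system, path)
        text = path.read_text().splitlines()
        lines_hdr = next(l for l in text if l.startswith("LINES"))
        expected = len(np.unique(default_run.system.seg_root_id))
        assert int(lines_hdr.split()[1]) == expected

    def test_csv_bundle_matches_manifest_schema(self, default_run, tmp_path):
        manifest = export(default_run, tmp_path)
        daily = pd.read_csv(tmp_path / manifest["daily"])
        for col in ("day", "total_root_length", "stress_pct", "d90_axial",
                    "d50_nitrate", "pct_c_to_roots", "uptake_per_m_root"):
            assert col in daily.columns
        profiles = pd.read_csv(tmp_path / manifest["depth_profiles"])
        root_total = profiles[(profiles.kind == "root_length")
                              & (profiles.class_filter == "all")].value.sum()
        assert root_total == pytest.approx(
            default_run.system.total_length(), rel=1e-9)
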