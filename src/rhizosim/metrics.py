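"""Summary metrics and standard-format output.

Depth profiles bin root length (geometric apportionment of each segment's
z-extent) and nitrate mass; D90-roots and D50-nitrate are interpolated
quantile depths of those profiles. Architecture snapshots export as RSML 1.0
(XML, round-trippable through the bundled reader) and legacy-ASCII VTK
polydata (one polyline per root axis); time series export as tidy CSV.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import RootSystem
from .soil import SoilGrid

__all__ = [
    "DepthProfile", "length_by_depth", "nitrate_by_depth", "quantile_depth",
    "d90_depth", "d50_nitrate_depth", "summary_metrics", "export",
    "write_rsml", "read_rsml", "write_vtk",
]


@dataclass
class DepthProfile:
    """Binned depth distribution of root length (cm) or nitrate mass (umol)."""

    edges: np.ndarray          # bin edges, cm, increasing
    values: np.ndarray         # one value per bin
    day: float = 0.0
    kind: str = "root_length"
    class_filter: str | None = None

    @property
    def total(self) -> float:
        return float(np.sum(self.values))


def default_edges(depth: float = 150.0, width: float = 5.0) -> np.ndarray:
    return np.arange(0.0, depth + width / 2, width)


def length_by_depth(system: RootSystem, edges=None,
                    class_filter: str | None = None) -> DepthProfile:
    """Root length per depth bin, apportioning each segment by z-extent.

    A segment spanning several bins contributes to each in proportion to the
    fraction of its vertical extent there; horizontal segments fall entirely
    in the bin containing their depth. The profile sums to the filtered total
    length exactly.
    """
    edges = np.asarray(edges if edges is not None else default_edges(system.domain[2]),
                       dtype=float)
    mask = system.class_mask(class_filter)
    values = np.zeros(len(edges) - 1)
    if mask.any():
        z0 = np.minimum(system.seg_start[mask, 2], system.seg_end[mask, 2])
        z1 = np.maximum(system.seg_start[mask, 2], system.seg_end[mask, 2])
        length = system.seg_length[mask]
        span = z1 - z0
        flat = span <= 1e-12
        if np.any(~flat):
            zl, zh = z0[~flat], z1[~flat]
            ln, sp = length[~flat], span[~flat]
            for b in range(len(values)):
                overlap = np.clip(np.minimum(zh, edges[b + 1])
                                  - np.maximum(zl, edges[b]), 0.0, None)
                values[b] += np.sum(ln * overlap / sp)
        if np.any(flat):
            idx = np.clip(np.searchsorted(edges, z0[flat], side="right") - 1,
                          0, len(values) - 1)
            np.add.at(values, idx, length[flat])
    return DepthProfile(edges, values, day=system.time, kind="root_length",
                        class_filter=class_filter)


def nitrate_by_depth(grid: SoilGrid, edges=None, day: float = 0.0) -> DepthProfile:
    """Nitrate mass per depth bin (apportioned by layer overlap)."""
    edges = np.asarray(edges if edges is not None else default_edges(grid.depth),
                       dtype=float)
    values = np.zeros(len(edges) - 1)
    tops = grid.depth_top
    bots = grid.depth_top + grid.thickness
    for b in range(len(values)):
        overlap = np.clip(np.minimum(bots, edges[b + 1]) - np.maximum(tops, edges[b]),
                          0.0, None)
        values[b] = np.sum(grid.nitrate_mass * overlap / grid.thickness)
    return DepthProfile(edges, values, day=day, kind="nitrate")


def quantile_depth(profile: DepthProfile, q: float) -> float:
    """Shallowest depth above which a fraction q of the profile mass lies.

    Linear interpolation within the crossing bin; NaN for an empty profile.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    total = profile.total
    if total <= 0.0:
        return float("nan")
    cum = np.concatenate(([0.0], np.cumsum(profile.values))) / total
    return float(np.interp(q, cum, profile.edges))


def d90_depth(profile: DepthProfile) -> float:
    """Depth of 90 % of the root length."""
    return quantile_depth(profile, 0.90)


def d50_nitrate_depth(profile: DepthProfile) -> float:
    """Depth of 50 % of the available nitrate."""
    return quantile_depth(profile, 0.50)


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def summary_metrics(result) -> pd.DataFrame:
    """Per-day metric table derived from a simulation's daily ledger.

    Ratios (uptake per m root, uptake per g root C, % plant C to roots) are
    computed from ledger values, never re-derived from geometry.
    """
    daily = result.daily.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        daily["uptake_per_m_root"] = np.where(
            daily["total_root_length"] > 0,
            daily["u_umol"] / (daily["total_root_length"] / 100.0), np.nan)
        daily["uptake_per_g_root_c"] = np.where(
            daily["cumulative_root_c"] > 0,
            daily["u_umol"] / daily["cumulative_root_c"], np.nan)
        total_c = daily["cumulative_root_c"] + daily["shoot_c"]
        daily["pct_c_to_roots"] = 100.0 * daily["cumulative_root_c"] / total_c
    return daily


# ---------------------------------------------------------------------------
# RSML
# ---------------------------------------------------------------------------

def _root_polyline(system: RootSystem, root_id: int):
    """Ordered node coordinates and diameters for one root axis."""
    sel = system.seg_root_id == root_id
    if not sel.any():
        return None
    order = np.argsort(system.seg_birthday[sel], kind="stable")
    starts = system.seg_start[sel][order]
    ends = system.seg_end[sel][order]
    diam = system.seg_diameter[sel][order]
    pts = np.vstack([starts[:1], ends])
    diams = np.concatenate([diam[:1], diam])
    return pts, diams


def write_rsml(system: RootSystem, path) -> None:
    """Write the architecture as an RSML 1.0 scene (laterals nested in parents)."""
    rsml = ET.Element("rsml", version="1.0")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "cm"
    ET.SubElement(meta, "last-modified").text = f"day {system.time:g}"
    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", id="1", label="maize")

    def add_root(parent_el, rid: int):
        poly = _root_polyline(system, rid)
        if poly is None:
            return
        pts, diams = poly
        root_el = ET.SubElement(parent_el, "root", ID=str(rid),
                                label=system.root_class_of[rid])
        geom = ET.SubElement(root_el, "geometry")
        pl = ET.SubElement(geom, "polyline")
        for x, y, z in pts:
            ET.SubElement(pl, "point", x=f"{x:.6f}", y=f"{y:.6f}", z=f"{z:.6f}")
        fns = ET.SubElement(root_el, "functions")
        fn = ET.SubElement(fns, "function", name="diameter", domain="polyline")
        for d in diams:
            ET.SubElement(fn, "sample", value=f"{d:.6f}")
        for child in range(system.n_roots):
            if system.root_parent[child] == rid:
                add_root(root_el, child)

    for rid in range(system.n_roots):
        if system.root_parent[rid] == -1:
            add_root(plant, rid)
    ET.ElementTree(rsml).write(path, xml_declaration=True, encoding="unicode")


def read_rsml(path) -> list[dict]:
    """Read an RSML file into a flat list of root records.

    Each record has id, label, points (n, 3) and diameters (n,).
    """
    tree = ET.parse(path)
    roots: list[dict] = []

    def walk(el):
        for root_el in el.findall("root"):
            pts = np.array([[float(p.get(k)) for k in ("x", "y", "z")]
                            for p in root_el.find("geometry/polyline")])
            fn = root_el.find("functions/function[@name='diameter']")
            diam = (np.array([float(s.get("value")) for s in fn])
                    if fn is not None else np.full(len(pts), np.nan))
            roots.append(dict(id=root_el.get("ID"), label=root_el.get("label"),
                              points=pts, diameters=diam))
            walk(root_el)

    for plant in tree.getroot().iter("plant"):
        walk(plant)
    return roots


def write_vtk(system: RootSystem, path) -> None:
    """Legacy-ASCII VTK polydata: one polyline per root axis, diameter as
    point data (Paraview-compatible)."""
    polylines = []
    diam_data = []
    for rid in range(system.n_roots):
        poly = _root_polyline(system, rid)
        if poly is None:
            continue
        polylines.append(poly[0])
        diam_data.append(poly[1])
    n_points = sum(len(p) for p in polylines)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nroot system\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {n_points} float\n")
        for pts in polylines:
            for x, y, z in pts:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        size = sum(len(p) + 1 for p in polylines)
        fh.write(f"LINES {len(polylines)} {size}\n")
        offset = 0
        for pts in polylines:
            idx = " ".join(str(offset + i) for i in range(len(pts)))
            fh.write(f"{len(pts)} {idx}\n")
            offset += len(pts)
        fh.write(f"POINT_DATA {n_points}\nSCALARS diameter float 1\n"
                 "LOOKUP_TABLE default\n")
        for diams in diam_data:
            for d in diams:
                fh.write(f"{d:.6f}\n")


# ---------------------------------------------------------------------------
# bundle export
# ---------------------------------------------------------------------------

def export(result, outdir, formats=("csv", "rsml", "vtk")) -> dict[str, str]:
    """Write a run's outputs under a directory; returns a manifest of files.

    csv: daily.csv (time series incl. metric ratios), depth_profiles.csv
    (root-length and nitrate profiles at the final day); rsml/vtk:
    architecture snapshot.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    if "csv" in formats:
        daily = summary_metrics(result)
        daily.to_csv(outdir / "daily.csv", index=False)
        manifest["daily"] = "daily.csv"
        frames = []
        for cf in (None, "axial", "lateral"):
            p = length_by_depth(result.system, class_filter=cf)
            frames.append(pd.DataFrame({
                "depth_top": p.edges[:-1], "depth_bottom": p.edges[1:],
                "value": p.values, "kind": "root_length",
                "class_filter": cf or "all", "day": p.day}))
        pn = nitrate_by_depth(result.grid, day=result.daily["day"].iloc[-1])
        frames.append(pd.DataFrame({
            "depth_top": pn.edges[:-1], "depth_bottom": pn.edges[1:],
            "value": pn.values, "kind": "nitrate", "class_filter": "all",
            "day": pn.day}))
        pd.concat(frames).to_csv(outdir / "depth_profiles.csv", index=False)
        manifest["depth_profiles"] = "depth_profiles.csv"
    if "rsml" in formats:
        write_rsml(result.system, outdir / "architecture.rsml")
        manifest["rsml"] = "architecture.rsml"
    if "vtk" in formats:
        write_vtk(result.system, outdir / "architecture.vtk")
        manifest["vtk"] = "architecture.vtk"
    manifest["provenance"] = "manifest.json"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"files": manifest, "seed": result.seed,
                   "config_hash": result.provenance.get("config_hash", ""),
                   "version": result.provenance.get("version", "")}, fh, indent=2)
    return manifest
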