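"""Shared fixtures: small soil grids and the session-scoped simulation runs
used by the engine and scenario-comparison tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rhizosim import ScenarioConfig, build_density_profile, run_simulation

SEEDS = (1, 2, 3)

# scenario cells exercised by the directional comparisons, all at full
# default resolution (1-cm layers, 40 d); phenotype contrasts use the
# high-N/high-leach regime, the stress-onset comparison the low-N one
DIRECTIONAL_CELLS = [
    ("uniform", "1000-1000", "highN_highLeach"),
    ("gradient", "1000-1000", "highN_highLeach"),
    ("plow_pan", "1000-1000", "highN_highLeach"),
    ("gradient", "4000-1000", "highN_highLeach"),
    ("gradient", "1000-4000", "highN_highLeach"),
    ("gradient", "4000-4000", "highN_highLeach"),
    ("plow_pan", "4000-1000", "highN_highLeach"),
    ("plow_pan", "1000-4000", "highN_highLeach"),
    ("plow_pan", "4000-4000", "highN_highLeach"),
    ("uniform", "1000-1000", "lowN_highLeach"),
    ("gradient", "1000-1000", "lowN_highLeach"),
    ("plow_pan", "1000-1000", "lowN_highLeach"),
]


@pytest.fixture(scope="session")
def directional_results():
    """Final-day metrics and stress trajectories for the comparison cells.

    Returns (finals DataFrame, stress dict): finals has one row per
    (cell, seed); stress maps cell -> replicate-mean stress time series.
    """
    rows = []
    stress = {}
    for cell in DIRECTIONAL_CELLS:
        soil, pheno, regime = cell
        series = []
        for seed in SEEDS:
            res = run_simulation(ScenarioConfig(
                soil_profile=soil, phenotype=pheno, nitrate_regime=regime,
                duration=40.0, seed=seed))
            final = res.daily.iloc[-1].to_dict()
            final.update(soil_profile=soil, phenotype=pheno,
                         nitrate_regime=regime, seed=seed)
            rows.append(final)
            series.append(res.daily.set_index("day")["stress_pct"])
        stress[cell] = pd.concat(series, axis=1).mean(axis=1)
    return pd.DataFrame(rows), stress


def cell_mean(finals: pd.DataFrame, soil: str, pheno: str, regime: str,
              column: str) -> float:
    sel = finals[(finals.soil_profile == soil) & (finals.phenotype == pheno)
                 & (finals.nitrate_regime == regime)]
    assert len(sel) == len(SEEDS)
    return float(sel[column].mean())


def onset_day(stress_series: pd.Series, threshold: float = 10.0) -> float:
    """First day the replicate-mean stress exceeds the threshold (41 = never)."""
    hit = stress_series[stress_series >= threshold]
    return float(hit.index[0]) if len(hit) else 41.0


@pytest.fixture(scope="session")
def default_run():
    """One full default scenario (uniform soil, 1000-1000, high N/high leach)."""
    return run_simulation(ScenarioConfig(duration=40.0, seed=1))


@pytest.fixture()
def uniform_grid():
    return build_density_profile("uniform", n_layers=150, depth=150.0)


@pytest.fixture()
def gradient_grid():
    return build_density_profile("gradient", n_layers=150, depth=150.0)
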