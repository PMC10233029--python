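"""Shared fixtures: expensive solves and calibrations are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import paceopt as po
from paceopt import experiments as ex


@pytest.fixture(scope="session")
def wr_params() -> po.RunnerParams:
    return po.RunnerParams.world_record()


@pytest.fixture(scope="session")
def good_default() -> po.GlycProfile:
    """Uncalibrated good-VLa fuel curve (for tests not about distances)."""
    return po.build_glyc("good")


@pytest.fixture(scope="session")
def profiles() -> dict:
    """The three anchor-calibrated fuel curves (calibrated once per run)."""
    return po.calibrated_profiles()


@pytest.fixture(scope="session")
def wr_solution(profiles):
    """Solved world-record scenario plus its metrics."""
    cfg = ex.world_record_scenario()
    sol, metrics = ex.run_scenario(cfg, profile=profiles["good"])
    return cfg, sol, metrics


@pytest.fixture(scope="session")
def t135_catalog_solutions(profiles):
    """Optimized distances for all 16 strategies at T=135, average VLa."""
    params = po.RunnerParams.world_record().replace(vla_type="average")
    grid = po.Grid.minute_mesh(135.0)
    table, sols = po.optimize_over_strategies(
        params, profiles["average"], po.catalog(), grid, p=0.5
    )
    return table, sols


@pytest.fixture(scope="session")
def t135_vla_solutions(profiles):
    """good/average/bad x {no gels, four 100-kcal gels} at T=135."""
    params = po.RunnerParams.world_record()
    grid = po.Grid.minute_mesh(135.0)
    cat = po.catalog()
    out = {}
    for vla in ("good", "average", "bad"):
        for strat in (cat[0], cat[4]):
            spec = po.assemble_ocp(
                params.replace(vla_type=vla), profiles[vla], strat, grid, p=0.5
            )
            out[(vla, strat.id)] = po.solve_ocp(spec)
    return out
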