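"""Scenario configurations, metrics, and report generation.

This module wires the model together into named race scenarios: the
world-record marathon simulation (55 kg runner, VVO2max 402 m/min, good
VLa, four 200-kcal gels at minutes 20/46/71/97, T=120) and the strategy
and VLa comparison sweeps at T=135, plus a grid of runner-level scenarios
at other durations.  Each fuel-allocation curve carries one figure-derived
degree of freedom, pinned by calibrating against a printed anchor outcome
(world record for "good", the zero-nutrition T=135 distances for
"average" and "bad"); the remaining table rows are then validations, not
fits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .glyc import GlycProfile, calibrate_profile
from .model_core import Grid, RunnerParams, VLA_TYPES
from .nutrition import NutritionStrategy, catalog
from .ocp import OCPSolution, assemble_ocp, solve_ocp

__all__ = [
    "ScenarioConfig",
    "world_record_scenario",
    "run_scenario",
    "calibrated_profiles",
    "marathon_equiv_time",
    "percent_improvement",
    "reproduce_tables",
    "make_fixtures",
    "MARATHON_M",
    "WORLD_RECORD_MIN",
]

log = logging.getLogger("paceopt")

MARATHON_M = 42195.0
#: Fastest marathon on record, 1:59:40, in minutes.
WORLD_RECORD_MIN = 119.0 + 40.0 / 60.0

#: Gel schedule of the world-record simulation (minute, kcal).
WORLD_RECORD_GELS = ((20.0, 200.0), (46.0, 200.0), (71.0, 200.0), (97.0, 200.0))

#: Plateau-statistics window as fractions of T (excludes the start ramp
#: and any terminal transient).
PLATEAU_WINDOW = (0.25, 0.90)

#: Calibration anchors: vla_type -> (scenario builder, target km).
ANCHOR_TARGETS = {"good": 42.5, "average": 40.0, "bad": 37.8}

_CAL_TOL = 0.002          # relative distance tolerance used for anchors


@dataclass
class ScenarioConfig:
    """One named, fully specified race scenario."""

    name: str
    params: RunnerParams
    grid: Grid
    strategy: NutritionStrategy
    vla_type: str = "good"
    p: float = 0.5
    expected_km: Optional[float] = None

    def __post_init__(self) -> None:
        if self.vla_type not in VLA_TYPES:
            raise ValueError(f"unknown vla_type {self.vla_type}")
        for t, _ in self.strategy.pulse_times(self.grid.T):
            if t >= self.grid.T:
                raise ValueError("strategy pulse after race end")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "params": self.params.to_dict(),
                "T": self.grid.T,
                "M": self.grid.M,
                "strategy": self.strategy.to_dict(),
                "vla": self.vla_type,
                "p": self.p,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def world_record_scenario() -> ScenarioConfig:
    """The world-record simulation: T=120, good VLa, 4x200 kcal gels."""
    return ScenarioConfig(
        name="world_record",
        params=RunnerParams.world_record(),
        grid=Grid.minute_mesh(120.0),
        strategy=NutritionStrategy.explicit("s11@20,46,71,97", WORLD_RECORD_GELS),
        vla_type="good",
        p=0.5,
        expected_km=42.5,
    )


def _t135_scenario(strategy: NutritionStrategy, vla_type: str, expected_km=None) -> ScenarioConfig:
    return ScenarioConfig(
        name=f"T135_{vla_type}_{strategy.id}",
        params=RunnerParams.world_record().replace(vla_type=vla_type),
        grid=Grid.minute_mesh(135.0),
        strategy=strategy,
        vla_type=vla_type,
        p=0.5,
        expected_km=expected_km,
    )


def run_scenario(
    config: ScenarioConfig,
    profile: Optional[GlycProfile] = None,
) -> Tuple[OCPSolution, Dict[str, float]]:
    """Solve one scenario and report its headline metrics.

    Metrics: distance (km), marathon-equivalent time (min), plateau
    velocity and force (medians over the plateau window), percent of
    VVO2max at the plateau, terminal glycogen, and fat used.
    """
    if profile is None:
        profile = calibrated_profiles()[config.vla_type]
    spec = assemble_ocp(config.params, profile, config.strategy, config.grid, p=config.p)
    sol = solve_ocp(spec)
    traj = sol.trajectory
    T = config.grid.T
    lo, hi = PLATEAU_WINDOW[0] * T, PLATEAU_WINDOW[1] * T
    in_win = (traj.t >= lo) & (traj.t <= hi)
    in_win_f = in_win[:-1]
    plateau_v = float(np.median(traj.V[in_win])) if np.any(in_win) else float("nan")
    plateau_f = float(np.median(traj.f[in_win_f])) if np.any(in_win_f) else float("nan")
    metrics = {
        "distance_km": sol.distance_km,
        "marathon_equiv_min": (
            marathon_equiv_time(sol.distance_m, T) if sol.distance_m > 0 else float("nan")
        ),
        "plateau_velocity_m_per_min": plateau_v,
        "plateau_force_m_per_min2": plateau_f,
        "plateau_pct_vvo2max": 100.0 * plateau_v / config.params.vvo2max,
        "terminal_EG_KJ_per_kg": float(traj.EG[-1]),
        "terminal_EF_KJ_per_kg": float(traj.EF[-1]),
        "fat_used_KJ_per_kg": float(traj.EF[0] - traj.EF[-1]),
        "status": sol.status,
    }
    if sol.status != "converged":
        log.warning("scenario %s: solver status %s", config.name, sol.status)
    return sol, metrics


# ---------------------------------------------------------------------------
# calibration

_PROFILE_CACHE: Dict[Tuple[str, str], GlycProfile] = {}


def anchor_scenario(vla_type: str) -> ScenarioConfig:
    """The printed outcome each fuel curve is pinned to."""
    if vla_type == "good":
        return world_record_scenario()
    s0 = catalog()[0]
    return _t135_scenario(s0, vla_type, expected_km=ANCHOR_TARGETS[vla_type])


def calibrated_profiles(
    vla_types: Iterable[str] = VLA_TYPES,
    tolerance: float = _CAL_TOL,
    cache: bool = True,
) -> Dict[str, GlycProfile]:
    """Calibrate (once per process) and return the three fuel curves."""
    out: Dict[str, GlycProfile] = {}
    for vla in vla_types:
        key = (vla, f"{tolerance:.4g}")
        if cache and key in _PROFILE_CACHE:
            out[vla] = _PROFILE_CACHE[key]
            continue
        cfg = anchor_scenario(vla)
        profile = calibrate_profile(vla, cfg, ANCHOR_TARGETS[vla], tolerance=tolerance)
        log.info(
            "calibrated %s profile: knot x=%.2f -> y=%.4f (achieved %.3f km)",
            vla,
            profile.calibration["free_knot_x"],
            profile.calibration["free_knot_y"],
            profile.calibration["achieved_km"],
        )
        if cache:
            _PROFILE_CACHE[key] = profile
        out[vla] = profile
    return out


# ---------------------------------------------------------------------------
# metrics


def marathon_equiv_time(distance_m: float, T_min: float) -> float:
    """Constant-pace extrapolation of a fixed-time distance to 42.195 km."""
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    return T_min * MARATHON_M / distance_m


def format_hms(minutes: float) -> str:
    total = int(round(minutes * 60.0))
    hh, rem = divmod(total, 3600)
    mm, ss = divmod(rem, 60)
    return f"{hh}:{mm:02d}:{ss:02d}"


def percent_improvement(d_new: float, d_ref: float) -> float:
    """``100 (d_new - d_ref) / d_ref``."""
    if d_ref <= 0:
        raise ValueError("reference distance must be positive")
    return 100.0 * (d_new - d_ref) / d_ref


# ---------------------------------------------------------------------------
# table reproduction

#: Printed distances used as regression targets (km).
TABLE3_EXPECTED = {
    "s0": 40.0, "s1": 40.7, "s2": 41.4, "s3": 42.0, "s4": 42.6, "s5": 43.1,
    "s6": 46.0, "s7": 52.9, "s8": 40.7, "s9": 40.5, "s10": 42.5, "s11": 45.1,
    "s12": 43.2, "s13": 45.6, "s14": 43.1, "s15": 43.7,
}
TABLE4_EXPECTED = {
    ("good", "s0"): 41.7, ("average", "s0"): 40.0, ("bad", "s0"): 37.8,
    ("good", "s4"): 44.1, ("average", "s4"): 42.6, ("bad", "s4"): 40.5,
}
#: (T, vvo2max, mass, vla, n 100-kcal gels, EG0) -> km
TABLE5_ROWS = [
    (155.0, 320.0, 73.0, "average", 4, 150.0, 42.9),
    (155.0, 320.0, 73.0, "average", 0, 150.0, 40.1),
    (155.0, 320.0, 73.0, "good", 4, 150.0, 44.4),
    (155.0, 320.0, 73.0, "bad", 4, 150.0, 41.6),
    (180.0, 250.0, 80.0, "average", 0, 140.0, 41.0),
    (180.0, 250.0, 80.0, "average", 4, 140.0, 42.7),
    (215.0, 200.0, 80.0, "bad", 0, 140.0, 41.6),
    (210.0, 200.0, 80.0, "average", 4, 140.0, 44.3),
]

_ANCHORS = {("good", "world_record"), ("average", "s0"), ("bad", "s0")}


def table5_scenario(T, vvo2max, mass, vla, n_gels, EG0) -> ScenarioConfig:
    params = RunnerParams.world_record().replace(
        m=mass, vvo2max=vvo2max, EG0=EG0, vla_type=vla
    )
    strategy = NutritionStrategy.evenly(f"s{'4' if n_gels == 4 else '0'}", n_gels, 100.0)
    return ScenarioConfig(
        name=f"T{T:g}_{vla}_{n_gels}gels",
        params=params,
        grid=Grid.minute_mesh(T),
        strategy=strategy,
        vla_type=vla,
        p=0.5,
    )


def reproduce_tables(
    which: str,
    out_dir: Union[str, Path],
    profiles: Optional[Dict[str, GlycProfile]] = None,
    anchor_tol: float = 0.01,
    validation_tol: float = 0.03,
) -> int:
    """Regenerate one of the reported tables as CSV (plus deltas).

    ``which`` is one of ``table3``, ``table4``, ``table5``,
    ``world_record``, or ``all``.  Returns a nonzero exit status if any
    row with an expected value deviates beyond tolerance (anchors 1%,
    validations 3%).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if profiles is None:
        profiles = calibrated_profiles()
    cal_version = {
        v: profiles[v].calibration.get("achieved_km") if profiles[v].calibration else None
        for v in profiles
    }
    status = 0

    def _check(expected, achieved, is_anchor) -> bool:
        tol = anchor_tol if is_anchor else validation_tol
        return abs(achieved - expected) <= tol * expected

    if which in ("table3", "all"):
        rows = []
        grid = Grid.minute_mesh(135.0)
        params = RunnerParams.world_record().replace(vla_type="average")
        for strat in catalog():
            sol = solve_ocp(assemble_ocp(params, profiles["average"], strat, grid, p=0.5))
            expected = TABLE3_EXPECTED[strat.id]
            anchor = ("average", strat.id) in _ANCHORS
            ok = _check(expected, sol.distance_km, anchor)
            status |= int(not ok)
            rows.append(
                {
                    "strategy": strat.id,
                    "total_kcal": strat.total_kcal,
                    "distance_km": round(sol.distance_km, 3),
                    "expected_km": expected,
                    "delta_km": round(sol.distance_km - expected, 3),
                    "anchor": anchor,
                    "within_tol": ok,
                    "status": sol.status,
                    "tv": round(sol.tv, 1),
                }
            )
            log.info("table3 %s: %.2f km (printed %.1f)", strat.id, sol.distance_km, expected)
        df = pd.DataFrame(rows)
        df.attrs["calibration"] = cal_version
        _write_csv(df, out_dir / "table3.csv", profiles)

    if which in ("table4", "all"):
        rows = []
        s0, s4 = catalog()[0], catalog()[4]
        for vla in VLA_TYPES:
            for strat in (s0, s4):
                cfg = _t135_scenario(strat, vla)
                sol, _ = run_scenario(cfg, profile=profiles[vla])
                expected = TABLE4_EXPECTED[(vla, strat.id)]
                anchor = (vla, strat.id) in _ANCHORS and strat.id == "s0"
                ok = _check(expected, sol.distance_km, anchor)
                status |= int(not ok)
                rows.append(
                    {
                        "vla_type": vla,
                        "nutrition": f"{int(strat.total_kcal)} kcal",
                        "distance_km": round(sol.distance_km, 3),
                        "expected_km": expected,
                        "delta_km": round(sol.distance_km - expected, 3),
                        "anchor": anchor,
                        "within_tol": ok,
                        "status": sol.status,
                    }
                )
        _write_csv(pd.DataFrame(rows), out_dir / "table4.csv", profiles)

    if which in ("table5", "all"):
        rows = []
        for T, vv, mass, vla, n_gels, EG0, expected in TABLE5_ROWS:
            cfg = table5_scenario(T, vv, mass, vla, n_gels, EG0)
            sol, met = run_scenario(cfg, profile=profiles[vla])
            # a printed distance above vvo2max*T cannot be reached under the
            # velocity state bound; such rows are flagged, not failed
            bound_limited = expected * 1000.0 > vv * T
            ok = bound_limited or _check(expected, sol.distance_km, False)
            status |= int(not ok)
            rows.append(
                {
                    "T_min": T,
                    "vvo2max": vv,
                    "mass_kg": mass,
                    "vla_type": vla,
                    "n_100cal_gels": n_gels,
                    "EG0": EG0,
                    "distance_km": round(sol.distance_km, 3),
                    "expected_km": expected,
                    "delta_km": round(sol.distance_km - expected, 3),
                    "within_tol": ok,
                    "velocity_bound_limited": bound_limited,
                    "pct_vvo2max": round(met["plateau_pct_vvo2max"], 1),
                    "status": sol.status,
                }
            )
        _write_csv(pd.DataFrame(rows), out_dir / "table5.csv", profiles)

    if which in ("world_record", "all"):
        cfg = world_record_scenario()
        sol, met = run_scenario(cfg, profile=profiles["good"])
        equiv = met["marathon_equiv_min"]
        summary = {
            "distance_km": sol.distance_km,
            "marathon_equiv_min": equiv,
            "marathon_equiv_hms": format_hms(equiv),
            "gap_vs_record_pct": percent_improvement(WORLD_RECORD_MIN, equiv),
            "plateau_velocity_m_per_min": met["plateau_velocity_m_per_min"],
            "plateau_force_m_per_min2": met["plateau_force_m_per_min2"],
            "terminal_EF_KJ_per_kg": met["terminal_EF_KJ_per_kg"],
            "terminal_EG_KJ_per_kg": met["terminal_EG_KJ_per_kg"],
            "status": sol.status,
            "config_hash": cfg.config_hash(),
            "calibration": cal_version,
        }
        ok = _check(42.5, sol.distance_km, True)
        status |= int(not ok)
        with open(out_dir / "world_record.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        sol.trajectory.to_csv(out_dir / "world_record_trajectory.csv")

    return status


def _write_csv(df: pd.DataFrame, path: Path, profiles) -> None:
    with open(path, "w") as fh:
        cal = {
            v: (profiles[v].calibration or {}).get("free_knot_y") for v in profiles
        }
        fh.write(f"# calibration: {json.dumps(cal, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int, n_runners: int = 20, n_strategies: int = 10) -> dict:
    """Deterministic randomized runner profiles and pulse strategies.

    Used by property-based tests: masses 50-85 kg, VVO2max 200-410 m/min,
    EG0 130-150 KJ/kg, random VLa types, and random pulse schedules.
    """
    rng = np.random.default_rng(seed)
    runners = []
    for _ in range(n_runners):
        runners.append(
            RunnerParams(
                m=float(np.round(rng.uniform(50.0, 85.0), 3)),
                vvo2max=float(np.round(rng.uniform(200.0, 410.0), 3)),
                EG0=float(np.round(rng.uniform(130.0, 150.0), 3)),
                vla_type=str(rng.choice(VLA_TYPES)),
            ).to_dict()
        )
    strategies = []
    for i in range(n_strategies):
        n_pulses = int(rng.integers(0, 7))
        times = sorted(rng.choice(np.arange(5, 115), size=n_pulses, replace=False).tolist())
        kcal = rng.choice([50.0, 100.0, 200.0, 250.0], size=n_pulses).tolist()
        strategies.append(
            NutritionStrategy.explicit(
                f"fixture_{i}", list(zip(map(float, times), kcal))
            ).to_dict()
        )
    return {"seed": int(seed), "runners": runners, "strategies": strategies}
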