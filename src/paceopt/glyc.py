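"""Velocity-dependent fuel allocation between glycogen and fat.

``glyc(x)`` is the fraction of the instantaneous work rate drawn from the
glycogen store, as a function of relative intensity ``x = V / VVO2max``;
``1 - glyc`` is drawn from fat.  Physiological anchors: ~30% of energy
comes from glycogen at rest, the anaerobic contribution grows past ~60%
VO2max, and at 100% VO2max glycogen is the sole fuel (``glyc(1) = 1``).

Lactate capacity (VLa) shifts the curve: a runner with a low maximal
lactate production rate ("good") spares glycogen and burns a smaller
glycogen fraction at the same relative intensity than an "average" or
"bad" runner, so the three curves are pointwise ordered
good <= average <= bad.

The curve is a monotone shape-preserving piecewise cubic (PCHIP) through a
small knot table, clamped to its endpoint values outside [0, 1].  A plain
(natural) cubic-spline mode is kept for fidelity experiments, but the
default interpolant cannot overshoot [0, 1] between knots, which keeps the
allocation physical.  The knot ordinate nearest a scenario's race
intensity is the one degree of freedom the printed record does not pin
down; :func:`calibrate_profile` tunes it by bisection so that an anchor
scenario's optimized distance matches a target.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .model_core import VLA_TYPES

__all__ = [
    "GlycProfile",
    "DEFAULT_KNOTS",
    "build_glyc",
    "eval_glyc",
    "calibrate_profile",
]

#: Starting knot tables (relative intensity -> glycogen fraction), one per
#: VLa type.  Shapes honor the physiology anchors above; the ordinate near
#: the anchor scenario's race intensity is refined by calibration and is
#: never treated as ground truth.
DEFAULT_KNOTS = {
    "good": ((0.0, 0.3, 0.6, 0.8, 1.0), (0.30, 0.35, 0.50, 0.72, 1.0)),
    "average": ((0.0, 0.3, 0.6, 0.8, 1.0), (0.30, 0.38, 0.56, 0.78, 1.0)),
    "bad": ((0.0, 0.3, 0.6, 0.8, 1.0), (0.30, 0.46, 0.63, 0.85, 1.0)),
}

_CHECK_GRID = np.linspace(0.0, 1.0, 1000)


@dataclass(frozen=True)
class GlycProfile:
    """A validated, evaluable fuel-allocation curve.

    Instances are callable on scalar or array relative intensities and
    clamp to ``knots_y[0]`` below 0 and to 1 above 1 (the optimizer may
    probe velocities slightly above VVO2max before bounds bind, and the
    fat share must never go negative).
    """

    vla_type: str
    knots_x: np.ndarray
    knots_y: np.ndarray
    kind: str = "pchip"          # "pchip" (monotone, default) or "spline"
    calibration: Optional[dict] = None
    _interp: Callable = field(repr=False, compare=False, default=None)
    _deriv: Callable = field(repr=False, compare=False, default=None)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.asarray(self._interp(np.clip(x, 0.0, 1.0)))
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def derivative(self, x):
        """d glyc / dx, zero where the clamp is active."""
        x = np.asarray(x, dtype=float)
        inside = (x >= 0.0) & (x <= 1.0)
        out = np.where(inside, self._deriv(np.clip(x, 0.0, 1.0)), 0.0)
        return float(out) if out.ndim == 0 else out

    def with_ordinate(self, index: int, value: float) -> "GlycProfile":
        """A new profile with one knot ordinate replaced (re-validated)."""
        y = self.knots_y.copy()
        y[index] = value
        return build_glyc(
            vla_type=self.vla_type, knots_x=self.knots_x, knots_y=y, kind=self.kind,
            calibration=self.calibration,
        )

    def to_dict(self) -> dict:
        out = {
            "vla_type": self.vla_type,
            "knots_x": list(map(float, self.knots_x)),
            "knots_y": list(map(float, self.knots_y)),
            "kind": self.kind,
        }
        if self.calibration is not None:
            out["calibration"] = self.calibration
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GlycProfile":
        return build_glyc(
            vla_type=data["vla_type"],
            knots_x=np.asarray(data["knots_x"], dtype=float),
            knots_y=np.asarray(data["knots_y"], dtype=float),
            kind=data.get("kind", "pchip"),
            calibration=data.get("calibration"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "GlycProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_glyc(
    vla_type: Optional[str] = None,
    knots_x=None,
    knots_y=None,
    kind: str = "pchip",
    calibration: Optional[dict] = None,
) -> GlycProfile:
    """Construct a profile from a VLa type's default table or explicit knots.

    The resulting curve is verified on a dense grid: it must be
    nondecreasing and stay inside [0, 1]; violations raise with the
    offending interval named.
    """
    if knots_x is None or knots_y is None:
        if vla_type not in DEFAULT_KNOTS:
            raise ValueError(f"unknown vla_type {vla_type!r} and no explicit knots given")
        kx, ky = DEFAULT_KNOTS[vla_type]
        knots_x = np.asarray(kx, dtype=float) if knots_x is None else knots_x
        knots_y = np.asarray(ky, dtype=float) if knots_y is None else knots_y
    knots_x = np.asarray(knots_x, dtype=float)
    knots_y = np.asarray(knots_y, dtype=float)
    vla_type = vla_type or "average"

    if knots_x.shape != knots_y.shape or knots_x.ndim != 1 or len(knots_x) < 2:
        raise ValueError("knot vectors must be 1-D, equal length, >= 2 points")
    if np.any(np.diff(knots_x) <= 0):
        raise ValueError("knots_x must be strictly increasing")
    if knots_x[0] != 0.0 or knots_x[-1] != 1.0:
        raise ValueError("knots_x must start at 0 and end at 1")
    if np.any(np.diff(knots_y) < 0):
        i = int(np.argmax(np.diff(knots_y) < 0))
        raise ValueError(
            f"knots_y must be nondecreasing; decrease on knot interval "
            f"[{knots_x[i]:.3g}, {knots_x[i + 1]:.3g}]"
        )
    if not (0.25 <= knots_y[0] <= 0.35):
        raise ValueError("resting glycogen fraction glyc(0) must lie in [0.25, 0.35]")
    if knots_y[-1] != 1.0:
        raise ValueError("glyc(1) must equal 1 (glycogen is the sole fuel at 100% VO2max)")

    if kind == "pchip":
        interp = PchipInterpolator(knots_x, knots_y, extrapolate=False)
    elif kind == "spline":
        interp = CubicSpline(knots_x, knots_y, bc_type="natural", extrapolate=False)
    else:
        raise ValueError("kind must be 'pchip' or 'spline'")
    deriv = interp.derivative()

    dense = interp(_CHECK_GRID)
    if np.any(dense < -1e-12) or np.any(dense > 1.0 + 1e-12):
        j = int(np.argmax((dense < -1e-12) | (dense > 1.0 + 1e-12)))
        raise ValueError(
            f"interpolated curve escapes [0, 1] near x={_CHECK_GRID[j]:.3f}"
        )
    diffs = np.diff(dense)
    if np.any(diffs < -1e-10):
        j = int(np.argmax(diffs < -1e-10))
        raise ValueError(
            f"interpolated curve is decreasing near x={_CHECK_GRID[j]:.3f}"
        )

    return GlycProfile(
        vla_type=vla_type,
        knots_x=knots_x,
        knots_y=knots_y,
        kind=kind,
        calibration=calibration,
        _interp=interp,
        _deriv=deriv,
    )


def eval_glyc(profile: GlycProfile, v_ratio) -> float:
    """Evaluate a profile at a relative intensity (clamped outside [0, 1])."""
    v_ratio = np.asarray(v_ratio, dtype=float)
    if np.any(v_ratio < 0):
        raise ValueError("v_ratio must be nonnegative")
    return profile(v_ratio)


def _free_knot_index(profile: GlycProfile, plateau_ratio: float) -> int:
    """The tunable ordinate: the knot nearest the scenario's race intensity
    (never the pinned endpoint at x=1)."""
    idx = int(np.argmin(np.abs(profile.knots_x - plateau_ratio)))
    if idx == len(profile.knots_x) - 1:
        idx -= 1
    if idx == 0:
        idx = 1
    return idx


def calibrate_profile(
    vla_type: Union[str, GlycProfile],
    anchor,
    target_km: float,
    tolerance: float = 0.01,
    max_iter: int = 40,
) -> GlycProfile:
    """Tune one knot ordinate so an anchor scenario hits a target distance.

    ``anchor`` is either a callable ``profile -> distance_km`` (typically a
    closure around the trajectory optimizer) or a scenario configuration
    accepted by :func:`paceopt.experiments.run_scenario`.  The optimized
    distance is monotone decreasing in the ordinate (a larger glycogen
    fraction drains the limited store faster), so a scalar bisection
    suffices.  ``tolerance`` is relative on distance.

    The returned profile carries a ``calibration`` record (anchor label,
    target and achieved km, free knot, date) so serialized tables are
    self-describing and downstream runs deterministic.
    """
    profile = vla_type if isinstance(vla_type, GlycProfile) else build_glyc(vla_type)

    if callable(anchor):
        distance_km = anchor
        anchor_label = getattr(anchor, "__name__", "callable")
        T_anchor = None
    else:
        from . import experiments  # deferred: experiments imports this module

        cfg = anchor
        anchor_label = getattr(cfg, "name", "scenario")
        T_anchor = cfg.grid.T

        def distance_km(prof, _cfg=cfg):
            sol, _ = experiments.run_scenario(_cfg, profile=prof)
            return sol.distance_km

    # race intensity implied by the target -> free ordinate
    if T_anchor is None:
        plateau_ratio = 0.8
    else:
        vv = anchor.params.vvo2max
        plateau_ratio = (target_km * 1000.0 / T_anchor) / vv
    idx = _free_knot_index(profile, plateau_ratio)

    lo = float(profile.knots_y[idx - 1]) + 1e-6            # monotonicity floor
    hi = float(profile.knots_y[idx + 1]) - 1e-6            # monotonicity ceiling

    def achieved(y: float) -> float:
        return distance_km(profile.with_ordinate(idx, y))

    d_lo, d_hi = achieved(lo), achieved(hi)
    if not (min(d_lo, d_hi) <= target_km <= max(d_lo, d_hi)):
        raise RuntimeError(
            f"calibration bracket failure for {profile.vla_type}: distances "
            f"[{d_hi:.2f}, {d_lo:.2f}] km at ordinate bounds do not bracket "
            f"target {target_km:.2f} km"
        )

    y_lo, y_hi = lo, hi          # distance(y_lo) >= target >= distance(y_hi)
    y_mid, d_mid = lo, d_lo
    for _ in range(max_iter):
        y_mid = 0.5 * (y_lo + y_hi)
        d_mid = achieved(y_mid)
        if abs(d_mid - target_km) <= tolerance * target_km:
            break
        if d_mid > target_km:
            y_lo = y_mid
        else:
            y_hi = y_mid
    else:
        raise RuntimeError(
            f"calibration did not reach {tolerance:.1%} of {target_km} km "
            f"within {max_iter} bisection steps (best {d_mid:.3f} km)"
        )

    record = {
        "anchor": str(anchor_label),
        "target_km": float(target_km),
        "achieved_km": float(d_mid),
        "free_knot_x": float(profile.knots_x[idx]),
        "free_knot_y": float(y_mid),
        "tolerance": float(tolerance),
        "date": _dt.date.today().isoformat(),
    }
    calibrated = profile.with_ordinate(idx, y_mid)
    return GlycProfile(
        vla_type=calibrated.vla_type,
        knots_x=calibrated.knots_x,
        knots_y=calibrated.knots_y,
        kind=calibrated.kind,
        calibration=record,
        _interp=calibrated._interp,
        _deriv=calibrated._deriv,
    )
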