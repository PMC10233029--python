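"""In-race nutrition strategies and their realization as source vectors.

A strategy is a named schedule of calorie pulses (gels).  Each pulse is
either pinned to an explicit minute or placed by a rule once the race
duration is known:

* ``even``   — the j-th of n pulses at ``round(j T/(n+1))`` minutes;
* ``early``  — ``round(0.15 T)``;  ``late`` — ``round(0.85 T)``;
* ``early2late2`` — four pulses at 10%, 20%, 80% and 90% of ``T``.

The early/late fractions are a convention (the catalogue descriptions are
qualitative); rounding is half-up so pulse times in minutes are stable
under mesh refinement.  On a mesh, each pulse delivers its full energy
(1 kcal = 4.184 KJ) within exactly one step, so the per-step source value
is ``kcal * 4.184 / h`` KJ/min and total calories are conserved exactly.
Absorption dynamics live in the nutrition compartment, not in the pulse
shape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .model_core import Grid

__all__ = [
    "KCAL_TO_KJ",
    "DEFAULT_S_MAX",
    "Pulse",
    "NutritionStrategy",
    "catalog",
    "realize",
]

KCAL_TO_KJ = 4.184

#: Per-step source bound (KJ/min): one 250-kcal gel per minute, the
#: largest catalogued gel.  The bound exists to keep the admissible
#: control set compact; it never binds in the catalogued scenarios.
DEFAULT_S_MAX = 1046.0

_EARLY_FRAC = 0.15
_LATE_FRAC = 0.85
_E2L2_FRACS = (0.10, 0.20, 0.80, 0.90)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Pulse:
    """One calorie pulse: ``kcal`` plus either an explicit minute or a
    placement rule (with ``j of n`` bookkeeping for ``even``)."""

    kcal: float
    t_min: Optional[float] = None
    rule: Optional[str] = None
    j: Optional[int] = None      # 1-based index among the evenly spread pulses
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.kcal > 0:
            raise ValueError("pulse kcal must be positive")
        if (self.t_min is None) == (self.rule is None):
            raise ValueError("pulse needs exactly one of t_min or rule")

    def time(self, T: float) -> float:
        if self.t_min is not None:
            return float(self.t_min)
        if self.rule == "even":
            return float(_round_half_up(self.j * T / (self.n + 1)))
        if self.rule == "early":
            return float(_round_half_up(_EARLY_FRAC * T))
        if self.rule == "late":
            return float(_round_half_up(_LATE_FRAC * T))
        if self.rule == "early2late2":
            return float(_round_half_up(_E2L2_FRACS[self.j - 1] * T))
        raise ValueError(f"unknown pulse rule {self.rule!r}")


@dataclass(frozen=True)
class NutritionStrategy:
    """A named schedule of calorie pulses with a per-step source bound."""

    id: str
    pulses: Tuple[Pulse, ...]
    s_max: float = DEFAULT_S_MAX

    def __post_init__(self) -> None:
        if not self.s_max > 0:
            raise ValueError("s_max must be positive")

    @property
    def total_kcal(self) -> float:
        return float(sum(p.kcal for p in self.pulses))

    @property
    def total_kj(self) -> float:
        return self.total_kcal * KCAL_TO_KJ

    def pulse_times(self, T: float) -> List[Tuple[float, float]]:
        """Realized ``(minute, kcal)`` pairs for a race of duration ``T``."""
        out = [(p.time(T), p.kcal) for p in self.pulses]
        for t, _ in out:
            if not (0.0 <= t < T):
                raise ValueError(f"strategy {self.id}: pulse time {t} outside [0, T)")
        return out

    @classmethod
    def evenly(cls, id: str, n: int, kcal: Union[float, Sequence[float]], **kw):
        """``n`` pulses spread evenly; ``kcal`` scalar or per-pulse sequence."""
        kcals = [kcal] * n if np.isscalar(kcal) else list(kcal)
        if len(kcals) != n:
            raise ValueError("kcal sequence length must equal n")
        pulses = tuple(Pulse(kcal=c, rule="even", j=j, n=n) for j, c in enumerate(kcals, 1))
        return cls(id=id, pulses=pulses, **kw)

    @classmethod
    def explicit(cls, id: str, schedule: Sequence[Tuple[float, float]], **kw):
        """Pulses at explicit minutes: ``schedule`` is ``[(t_min, kcal), ...]``."""
        pulses = tuple(Pulse(kcal=c, t_min=t) for t, c in schedule)
        return cls(id=id, pulses=pulses, **kw)

    def to_dict(self) -> dict:
        items = []
        for p in self.pulses:
            d = {"kcal": p.kcal}
            if p.t_min is not None:
                d["t_min"] = p.t_min
            else:
                d["rule"] = p.rule
                if p.j is not None:
                    d["j"], d["n"] = p.j, p.n
            items.append(d)
        return {"id": self.id, "pulses": items, "s_max": self.s_max}

    @classmethod
    def from_dict(cls, data: dict) -> "NutritionStrategy":
        pulses = tuple(Pulse(**p) for p in data["pulses"])
        return cls(id=data["id"], pulses=pulses, s_max=data.get("s_max", DEFAULT_S_MAX))


def catalog() -> List[NutritionStrategy]:
    """The sixteen catalogued strategies s0..s15.

    s0–s7: {0,1,2,3,4,5,11,24} 100-kcal gels evenly; s8/s9: one 100-kcal
    gel early/late; s10: four 100-kcal gels, two early and two late;
    s11: four 200-kcal gels evenly; s12/s13: {2,4} 250-kcal gels evenly;
    s14: ten 50-kcal gels evenly; s15: a 250/100/250-kcal sequence evenly.
    """
    out: List[NutritionStrategy] = []
    for i, n in enumerate((0, 1, 2, 3, 4, 5, 11, 24)):
        out.append(NutritionStrategy.evenly(f"s{i}", n, 100.0))
    out.append(NutritionStrategy("s8", (Pulse(kcal=100.0, rule="early"),)))
    out.append(NutritionStrategy("s9", (Pulse(kcal=100.0, rule="late"),)))
    out.append(
        NutritionStrategy(
            "s10",
            tuple(Pulse(kcal=100.0, rule="early2late2", j=j, n=4) for j in range(1, 5)),
        )
    )
    out.append(NutritionStrategy.evenly("s11", 4, 200.0))
    out.append(NutritionStrategy.evenly("s12", 2, 250.0))
    out.append(NutritionStrategy.evenly("s13", 4, 250.0))
    out.append(NutritionStrategy.evenly("s14", 10, 50.0))
    out.append(NutritionStrategy.evenly("s15", 3, (250.0, 100.0, 250.0)))
    return out


def realize(strategy: NutritionStrategy, grid: Grid) -> np.ndarray:
    """The per-step source vector ``s`` (length ``M-1``, KJ/min).

    Each pulse lands in the mesh step containing its minute; colliding
    pulses are summed with a warning; a per-step value above ``s_max``
    raises, naming the strategy.  ``sum(s) * h`` equals the strategy's
    total KJ exactly.
    """
    h = grid.h
    s = np.zeros(grid.M - 1)
    seen: dict = {}
    for t, kcal in strategy.pulse_times(grid.T):
        k = min(int(math.floor(t / h + 1e-9)), grid.M - 2)
        if k in seen:
            warnings.warn(
                f"strategy {strategy.id}: pulses at minutes {seen[k]} and {t} "
                f"land in the same mesh step {k}; amounts summed",
                stacklevel=2,
            )
        else:
            seen[k] = t
        s[k] += kcal * KCAL_TO_KJ / h
    if np.any(s > strategy.s_max + 1e-9):
        k = int(np.argmax(s))
        raise ValueError(
            f"strategy {strategy.id}: per-step source {s[k]:.1f} KJ/min at step "
            f"{k} exceeds s_max={strategy.s_max:.1f}"
        )
    return s
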