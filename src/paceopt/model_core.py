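"""Runner bioenergetics: states, discrete dynamics, and the energy ledger.

The model tracks four states of a runner in a fixed-duration race:

* ``V``  — velocity (m/min), driven by propulsion force ``f`` (m/min^2)
  against a linear resistance ``V/tau``;
* ``E_F`` — fat energy (KJ/kg), drained by the aerobic share of the work
  rate and never replenished during the race;
* ``E_G`` — glycogen energy (KJ/kg), drained by the glycolytic share of
  the work rate and replenished by absorbed in-race nutrition;
* ``N``  — nutrition in transit (KJ), fed by calorie pulses ``s`` (KJ/min)
  and leaving by first-order absorption (``c4 N``, into glycogen) and
  first-order loss (``d N``, unavailable to the muscles).

The work rate is ``a * sm * f * V`` in KJ/(kg min); the split between the
two energy stores is set by the velocity-dependent glycogen fraction
``glyc(V / VVO2max)`` (see :mod:`paceopt.glyc`).

The race dynamics are defined by their forward-Euler discretization on a
mesh of ``M`` nodes (controls piecewise constant per mesh interval).  The
velocity time constant ``tau`` is of order one second, far below the
one-minute control mesh, so each mesh interval is integrated with interior
Euler sub-steps small enough that every state recursion is a contraction;
see :func:`substep_count`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RunnerParams",
    "Grid",
    "Trajectory",
    "LedgerReport",
    "work_rate",
    "substep_count",
    "step",
    "simulate_forward",
    "closed_form_velocity",
    "energy_ledger",
]

VLA_TYPES = ("good", "average", "bad")

#: CSV header used for trajectory export (one row per mesh node; the
#: control columns are empty on the final node).
TRAJECTORY_CSV_COLUMNS = (
    "t_min",
    "V_m_per_min",
    "EF_KJ_per_kg",
    "EG_KJ_per_kg",
    "N_KJ",
    "f_m_per_min2",
    "s_KJ_per_min",
)


@dataclass(frozen=True)
class RunnerParams:
    """Physiological and unit-conversion constants for one runner.

    Units: ``m`` kg, ``tau`` min, ``d`` 1/min, ``a`` KJ/J, ``sm`` 1/3600
    (squared seconds-per-minute), ``c4`` 1/min, ``vvo2max`` m/min,
    ``f_max`` m/min^2, ``EF0``/``EG0`` KJ/kg.  ``c3`` is always ``1/m``.
    """

    m: float
    tau: float = 1.0 / 60.0
    d: float = 0.005
    a: float = 1.0 / 1000.0
    sm: float = 1.0 / 3600.0
    c4: float = 1.0 / 6.0
    vvo2max: float = 402.0
    f_max: float = 36000.0
    EF0: float = 3439.0
    EG0: float = 144.0
    vla_type: str = "good"

    def __post_init__(self) -> None:
        for name in ("m", "tau", "a", "sm", "c4", "vvo2max", "f_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"RunnerParams.{name} must be strictly positive")
        if self.d < 0:
            raise ValueError("RunnerParams.d must be nonnegative")
        if self.EF0 < 0 or self.EG0 < 0:
            raise ValueError("initial energies must be nonnegative")
        if self.vla_type not in VLA_TYPES:
            raise ValueError(f"vla_type must be one of {VLA_TYPES}")

    @property
    def c3(self) -> float:
        """Mass conversion constant, exactly ``1/m`` (1/kg)."""
        return 1.0 / self.m

    @classmethod
    def world_record(cls) -> "RunnerParams":
        """Parameter set of the world-record marathon scenario (55 kg,
        VVO2max 402 m/min, good VLa, full glycogen stores)."""
        return cls(m=55.0)

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["c3"] = self.c3
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunnerParams":
        data = dict(data)
        c3 = data.pop("c3", None)
        params = cls(**{f.name: data[f.name] for f in fields(cls) if f.name in data})
        if c3 is not None and not math.isclose(c3, params.c3, rel_tol=1e-12):
            raise ValueError("c3 inconsistent with 1/m")
        return params

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RunnerParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kw) -> "RunnerParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class Grid:
    """Uniform time mesh on ``[0, T]`` with ``M`` nodes including ``t=0``.

    ``h = T/(M-1)`` is the step between nodes; ``delta = T/M`` is retained
    separately as the quadrature weight used in the penalized objective.
    """

    T: float
    M: int

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("Grid.T must be positive")
        if self.M < 2:
            raise ValueError("Grid.M must be >= 2")

    @property
    def h(self) -> float:
        return self.T / (self.M - 1)

    @property
    def delta(self) -> float:
        return self.T / self.M

    @property
    def t(self) -> np.ndarray:
        return np.linspace(0.0, self.T, self.M)

    @classmethod
    def minute_mesh(cls, T: float) -> "Grid":
        """The default race mesh: one-minute steps, ``M = T + 1`` nodes."""
        return cls(T=float(T), M=int(round(T)) + 1)


@dataclass
class Trajectory:
    """Discrete states on the mesh plus the per-interval controls.

    ``work``, ``absorbed``, ``glyc_drain`` and ``fat_drain`` are the
    per-interval energy flows (KJ/kg) accumulated by the sub-stepped
    integrator; they are what the energy ledger audits.
    ``first_negative`` is the first node index where an energy store went
    negative (feasibility is the optimizer's job, the simulator only flags).
    """

    t: np.ndarray
    V: np.ndarray
    EF: np.ndarray
    EG: np.ndarray
    N: np.ndarray
    f: np.ndarray
    s: np.ndarray
    work: Optional[np.ndarray] = None
    absorbed: Optional[np.ndarray] = None
    glyc_drain: Optional[np.ndarray] = None
    fat_drain: Optional[np.ndarray] = None
    first_negative: Optional[int] = None

    @property
    def M(self) -> int:
        return len(self.t)

    def distance(self, h: Optional[float] = None) -> float:
        """Left-rectangle distance ``h * sum_{k<M-1} V_k`` in meters."""
        if h is None:
            h = float(self.t[1] - self.t[0])
        return float(h * np.sum(self.V[:-1]))

    def to_frame(self) -> pd.DataFrame:
        pad = [np.nan]
        return pd.DataFrame(
            {
                "t_min": self.t,
                "V_m_per_min": self.V,
                "EF_KJ_per_kg": self.EF,
                "EG_KJ_per_kg": self.EG,
                "N_KJ": self.N,
                "f_m_per_min2": np.concatenate([self.f, pad]),
                "s_KJ_per_min": np.concatenate([self.s, pad]),
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "Trajectory":
        df = pd.read_csv(path_or_buf)
        missing = set(TRAJECTORY_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
        return cls(
            t=df["t_min"].to_numpy(),
            V=df["V_m_per_min"].to_numpy(),
            EF=df["EF_KJ_per_kg"].to_numpy(),
            EG=df["EG_KJ_per_kg"].to_numpy(),
            N=df["N_KJ"].to_numpy(),
            f=df["f_m_per_min2"].to_numpy()[:-1],
            s=df["s_KJ_per_min"].to_numpy()[:-1],
        )


def work_rate(f_k, V_k, params: RunnerParams):
    """Mass-specific mechanical power ``a * sm * f * V`` in KJ/(kg min).

    ``f*V`` has units m^2/min^3 = J/(kg min) * (min/s)^2; ``sm`` converts
    the squared time unit and ``a`` converts J to KJ.
    """
    f_k = np.asarray(f_k, dtype=float)
    V_k = np.asarray(V_k, dtype=float)
    if np.any(f_k < 0) or np.any(V_k < 0):
        raise ValueError("work_rate requires f >= 0 and V >= 0")
    out = params.a * params.sm * f_k * V_k
    return float(out) if out.ndim == 0 else out


def substep_count(params: RunnerParams, h: float) -> int:
    """Interior Euler sub-steps per mesh interval.

    The velocity recursion contracts iff the sub-step is below ``tau``, the
    nutrition recursion iff below ``1/(d+c4)``.  We target half the tighter
    bound, which for the standard one-minute mesh and ``tau = 1/60`` min
    gives 120 sub-steps (0.5 s each).
    """
    stable = min(params.tau, 1.0 / (params.d + params.c4))
    return max(1, int(math.ceil(h / (0.5 * stable))))


def step(state_k, f_k, s_k, params: RunnerParams, glyc_profile, h: float):
    """One raw forward-Euler update of ``(V, EF, EG, N)`` with step ``h``.

    Energies may go negative here; the caller is responsible for
    feasibility.  This is the primitive the sub-stepped simulator repeats.
    """
    if h <= 0:
        raise ValueError("step requires h > 0")
    V, EF, EG, N = (float(x) for x in state_k)
    if not all(map(math.isfinite, (V, EF, EG, N))):
        raise ValueError("non-finite state")
    if not (0.0 <= f_k <= params.f_max):
        raise ValueError("force outside [0, f_max]")
    if s_k < 0:
        raise ValueError("nutrition source must be nonnegative")
    wr = work_rate(f_k, V, params)
    g = float(glyc_profile(V / params.vvo2max))
    V1 = V + h * (f_k - V / params.tau)
    EG1 = EG + h * (params.c3 * params.c4 * N - wr * g)
    EF1 = EF + h * (-wr * (1.0 - g))
    N1 = N + h * (s_k - params.d * N - params.c4 * N)
    return (V1, EF1, EG1, N1)


def closed_form_velocity(f_const: float, tau: float, t):
    """Exact velocity ``f * tau * (1 - exp(-t/tau))`` under constant force.

    Analytic reference used to check the discrete integrator (agreement is
    first order in the sub-step).
    """
    if f_const < 0:
        raise ValueError("f_const must be nonnegative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = f_const * tau * (-np.expm1(-t / tau))
    return float(out) if out.ndim == 0 else out


def _simulate_core(
    params: RunnerParams,
    glyc_profile,
    f: np.ndarray,
    s: np.ndarray,
    grid: Grid,
    substeps: Optional[int] = None,
    with_sens: bool = False,
) -> dict:
    """Sub-stepped Euler integration of one mesh-resolution control pair.

    Per mesh interval ``k`` the controls are constant, so the interior
    velocity and nutrition recursions are affine with constant coefficients
    and have closed-form sub-step solutions:

        V_m = rho^m V_k + f_k tau (1 - rho^m),    rho = 1 - hs/tau
        N_m = phi^m N_k + s_k (1 - phi^m)/(d+c4), phi = 1 - hs (d+c4)

    which lets the whole integration (and, optionally, the exact jacobian
    of the discrete map with respect to ``f``) be evaluated with dense
    numpy array operations instead of a per-sub-step Python loop.

    Returns a dict with mesh states, per-interval energy flows, and — when
    ``with_sens`` — the ingredients of ``d(state)/d(f)``:

    * ``A``:  dV_mesh/df, lower-triangular ``(M, M-1)``;
    * ``wG, bG`` (and ``wF, bF``): per-interval partials of the glycogen
      (fat) drain with respect to the interval's entry velocity and force.
    """
    M = grid.M
    K = M - 1
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    if f.shape != (K,) or s.shape != (K,):
        raise ValueError(f"controls must have length M-1={K}, got {f.shape} and {s.shape}")
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(s))):
        bad = int(np.argmax(~(np.isfinite(f) & np.isfinite(s))))
        raise FloatingPointError(f"non-finite control at step {bad}")

    h = grid.h
    n = substeps if substeps is not None else substep_count(params, h)
    hs = h / n
    tau, vv = params.tau, params.vvo2max
    lam = params.d + params.c4

    rho = 1.0 - hs / tau
    phi = 1.0 - hs * lam
    if not (0.0 <= rho < 1.0) or not (0.0 < phi <= 1.0):
        raise ValueError("sub-step too large for a contracting Euler map")
    rho_pow = rho ** np.arange(n)          # (n,)
    phi_pow = phi ** np.arange(n)
    R = rho ** n
    Phi = phi ** n
    cV = tau * (1.0 - R)                   # dV_{k+1}/df_k

    # mesh-node velocity and nutrition via the exact interval maps
    V = np.empty(M)
    N = np.empty(M)
    V[0] = 0.0
    N[0] = 0.0
    for k in range(K):
        V[k + 1] = R * V[k] + cV * f[k]
        N[k + 1] = Phi * N[k] + s[k] * (1.0 - Phi) / lam
    if np.max(V) > 0 and not np.all(np.isfinite(V)):
        raise FloatingPointError("velocity overflow during simulation")

    # all sub-step values, (K, n)
    Vsub = V[:-1, None] * rho_pow[None, :] + (f * tau)[:, None] * (1.0 - rho_pow)[None, :]
    Nsub = N[:-1, None] * phi_pow[None, :] + (s / lam)[:, None] * (1.0 - phi_pow)[None, :]

    ratio = Vsub / vv
    g = glyc_profile(ratio)

    asm = params.a * params.sm
    work = hs * asm * f[:, None] * Vsub                      # (K, n) KJ/kg per sub-step
    glyc_drain = np.sum(work * g, axis=1)
    work_tot = np.sum(work, axis=1)
    fat_drain = work_tot - glyc_drain
    absorbed = hs * params.c3 * params.c4 * np.sum(Nsub, axis=1)

    EG = np.empty(M)
    EF = np.empty(M)
    EG[0] = params.EG0
    EF[0] = params.EF0
    EG[1:] = params.EG0 + np.cumsum(absorbed - glyc_drain)
    EF[1:] = params.EF0 - np.cumsum(fat_drain)

    out = {
        "V": V, "N": N, "EG": EG, "EF": EF,
        "work": work_tot, "absorbed": absorbed,
        "glyc_drain": glyc_drain, "fat_drain": fat_drain,
        "substeps": n,
    }

    if with_sens:
        gd = glyc_profile.derivative(ratio) / vv             # d g / d Vsub
        # dVsub/dV_k = rho^m ; dVsub/df_k = tau (1 - rho^m)
        dint_g = g + Vsub * gd                               # d(V g)/dV at sub-step
        dint_f = (1.0 - g) - Vsub * gd                       # d(V (1-g))/dV
        wG = hs * asm * f * np.sum(rho_pow[None, :] * dint_g, axis=1)
        wF = hs * asm * f * np.sum(rho_pow[None, :] * dint_f, axis=1)
        bG = hs * asm * (
            np.sum(Vsub * g, axis=1)
            + f * np.sum((tau * (1.0 - rho_pow))[None, :] * dint_g, axis=1)
        )
        bF = hs * asm * (
            np.sum(Vsub * (1.0 - g), axis=1)
            + f * np.sum((tau * (1.0 - rho_pow))[None, :] * dint_f, axis=1)
        )
        # A[k, j] = dV_k/df_j = cV * R^(k-1-j) for j <= k-1
        A = np.zeros((M, K))
        if R > 0:
            kk = np.arange(M)[:, None]
            jj = np.arange(K)[None, :]
            expo = kk - 1 - jj
            with np.errstate(over="ignore"):
                A = np.where(expo >= 0, cV * R ** np.maximum(expo, 0), 0.0)
        else:
            A[np.arange(1, M), np.arange(K)] = cV
        out.update({"A": A, "wG": wG, "bG": bG, "wF": wF, "bF": bF})
    return out


def simulate_forward(
    params: RunnerParams,
    glyc_profile,
    f,
    s,
    grid: Grid,
    substeps: Optional[int] = None,
) -> Trajectory:
    """Integrate the race forward under given force and nutrition schedules.

    ``f`` and ``s`` are per-interval (length ``M-1``) piecewise-constant
    controls.  Energies are not clipped; the first node where an energy
    store is negative is recorded in ``Trajectory.first_negative``.
    """
    core = _simulate_core(params, glyc_profile, f, s, grid, substeps=substeps)
    neg = np.flatnonzero((core["EG"] < 0) | (core["EF"] < 0))
    return Trajectory(
        t=grid.t,
        V=core["V"],
        EF=core["EF"],
        EG=core["EG"],
        N=core["N"],
        f=np.asarray(f, dtype=float).copy(),
        s=np.asarray(s, dtype=float).copy(),
        work=core["work"],
        absorbed=core["absorbed"],
        glyc_drain=core["glyc_drain"],
        fat_drain=core["fat_drain"],
        first_negative=int(neg[0]) if neg.size else None,
    )


@dataclass(frozen=True)
class LedgerReport:
    """Totals of the discrete energy balance over one trajectory (KJ/kg)."""

    work_done: float
    nutrition_absorbed: float
    fat_used: float
    glycogen_used: float
    residual: float          # |(ΔEF+ΔEG) - (work - absorbed)|, relative
    max_step_residual: float


def energy_ledger(
    traj: Trajectory,
    params: RunnerParams,
    glyc_profile,
    tol: float = 1e-9,
) -> LedgerReport:
    """Audit the discrete energy conservation identity of the Euler map.

    At every node the drop in total stored energy must equal accumulated
    work minus accumulated absorbed nutrition:

        (EF[0]-EF[k]) + (EG[0]-EG[k]) = sum_{i<k} work_i - absorbed_i

    which is an algebraic identity of the update; a violation beyond
    ``tol`` (relative) means the trajectory arrays are inconsistent.
    """
    if traj.work is None:
        # re-derive the per-interval flows by re-simulating the controls
        grid = Grid(T=float(traj.t[-1]), M=len(traj.t))
        traj = simulate_forward(params, glyc_profile, traj.f, traj.s, grid)
    lhs = (traj.EF[0] - traj.EF) + (traj.EG[0] - traj.EG)
    rhs = np.concatenate([[0.0], np.cumsum(traj.work - traj.absorbed)])
    scale = max(1.0, float(np.max(np.abs(rhs))))
    step_res = np.max(np.abs(lhs - rhs)) / scale
    report = LedgerReport(
        work_done=float(np.sum(traj.work)),
        nutrition_absorbed=float(np.sum(traj.absorbed)),
        fat_used=float(np.sum(traj.fat_drain)),
        glycogen_used=float(np.sum(traj.glyc_drain)),
        residual=float(abs(lhs[-1] - rhs[-1])) / scale,
        max_step_residual=float(step_res),
    )
    if report.max_step_residual > tol:
        raise ArithmeticError(
            f"energy ledger out of balance: relative residual {report.max_step_residual:.3e}"
        )
    return report
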