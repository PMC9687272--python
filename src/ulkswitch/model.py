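"""Mass-action ODE model of the mTORC1–ULK1–PP2A autophagy-induction triangle.

The model tracks the *active* form of three proteins — mTORC1 (master
growth kinase), ULK1 (autophagy-initiating kinase) and PP2A (the B55
phosphatase that dephosphorylates ULK1) — each of which interconverts with
an inactive (phosphorylated or otherwise silenced) form inside a conserved
total pool.  The wiring contains two double-negative loops
(mTORC1 ⊣ ULK1 ⊣ mTORC1 and mTORC1 ⊣ PP2A ⊣ mTORC1) and one positive loop
(ULK1 → PP2A → ULK1), which together act as a bistable switch between a
non-autophagy state (mTORC1 high) and an autophagy state (ULK1 high).

With ``m``, ``u``, ``p`` the active concentrations and ``MT``, ``UT``,
``PT`` the total pools, mass-action kinetics give

    dm/dt = ka_m·(MT − m) − (ki_m + k_b·u + k_e·p)·m
    du/dt = (ka_u + k_c·p)·(UT − u) − (ki_u + k_a·m)·u
    dp/dt = (ka_p + k_d·u)·(PT − p) − (ki_p + k_f·m)·p

Activation always acts on the inactive pool (``XT − x``) and inhibition on
the active pool, so each concentration is confined to ``[0, XT]``.  Time is
in minutes; totals are normalized to 1 under physiological conditions.
Drug treatments are modelled as step reductions of a total pool
(rapamycin → MT, okadaic acid → PT) and siRNA silencing as a reduced total
applied before equilibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "RATE_NAMES",
    "TOTAL_NAMES",
    "RateConstants",
    "TotalLevels",
    "SystemState",
    "Trajectory",
    "SimulationError",
    "ConvergenceError",
    "rhs",
    "jacobian",
    "simulate",
    "steady_state",
    "physiological_steady_state",
    "apply_treatment",
    "to_observables",
    "load_params",
    "save_params",
    "reference_rates",
    "default_rates",
]

#: Canonical ordering of the 12 free rate constants.
RATE_NAMES = (
    "ka_m", "ki_m", "ka_u", "ki_u", "ka_p", "ki_p",
    "k_a", "k_b", "k_c", "k_d", "k_e", "k_f",
)

TOTAL_NAMES = ("mTORT", "ULK1T", "PP2AT")

#: Observable column names: phosphorylated (inactive) ULK1 at Ser757,
#: phosphorylated (inactive) PP2A, and phospho-p70S6K as the mTORC1
#: activity proxy.
OBSERVABLE_NAMES = ("ulk1_757P", "pp2a_P", "p70S6K_P")


class SimulationError(RuntimeError):
    """Integrator failure; carries the last time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class ConvergenceError(RuntimeError):
    """Steady state not reached within the allotted horizon."""


@dataclass(frozen=True)
class RateConstants:
    """The 12 mass-action rate constants of the regulatory triangle.

    ``ka_*``/``ki_*`` are basal activation/inactivation rates (1/min);
    ``k_a``–``k_f`` are the six interaction constants (1/(conc·min)),
    lettered after the arrows of the wiring diagram:

    - ``k_a``: mTORC1 phosphorylates (inactivates) ULK1 at Ser757
    - ``k_b``: ULK1 inhibits mTORC1 (Raptor phosphorylation)
    - ``k_c``: PP2A dephosphorylates (activates) ULK1
    - ``k_d``: ULK1 activates PP2A
    - ``k_e``: PP2A inhibits mTORC1
    - ``k_f``: mTORC1 phosphorylates (inactivates) PP2A
    """

    ka_m: float
    ki_m: float
    ka_u: float
    ki_u: float
    ka_p: float
    ki_p: float
    k_a: float
    k_b: float
    k_c: float
    k_d: float
    k_e: float
    k_f: float

    def __post_init__(self) -> None:
        # Basal rates must be strictly positive (they guarantee that the
        # conservation box is forward-invariant with an interior attractor);
        # interaction constants may be exactly zero, representing an absent
        # coupling (the uncoupled limit used in closed-form checks).
        for name in RATE_NAMES[:6]:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(
                    f"basal rate {name}={value!r} must be finite and > 0"
                )
        for name in RATE_NAMES[6:]:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise ValueError(
                    f"interaction constant {name}={value!r} must be finite and >= 0"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RateConstants":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(RATE_NAMES),):
            raise ValueError(f"expected {len(RATE_NAMES)} rate constants")
        return cls(**dict(zip(RATE_NAMES, values.tolist())))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "RateConstants":
        unknown = set(mapping) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rate constant names: {sorted(unknown)}")
        missing = set(RATE_NAMES) - set(mapping)
        if missing:
            raise ValueError(f"missing rate constants: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in RATE_NAMES}

    def replace(self, **changes: float) -> "RateConstants":
        d = self.to_dict()
        d.update(changes)
        return RateConstants.from_mapping(d)


@dataclass(frozen=True)
class TotalLevels:
    """Total functional pools; the treatment levers.

    Physiological value is 1 for every pool.  Rapamycin lowers ``mTORT``,
    okadaic acid lowers ``PP2AT``, siRNA lowers the silenced protein's
    total before equilibration.
    """

    mTORT: float = 1.0
    ULK1T: float = 1.0
    PP2AT: float = 1.0

    def __post_init__(self) -> None:
        for name in TOTAL_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or not (0.0 < value <= 1.0):
                raise ValueError(
                    f"total {name}={value!r} must lie in (0, 1]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.mTORT, self.ULK1T, self.PP2AT], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in TOTAL_NAMES}

    def replace(self, **changes: float) -> "TotalLevels":
        d = self.to_dict()
        d.update(changes)
        return TotalLevels(**d)


@dataclass(frozen=True)
class SystemState:
    """Active-form concentrations (dimensionless, bounded by the totals)."""

    m_act: float
    u_act: float
    p_act: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m_act, self.u_act, self.p_act], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "SystemState":
        m, u, p = (float(v) for v in values)
        return cls(m, u, p)

    def within_bounds(self, totals: TotalLevels, tol: float = 1e-7) -> bool:
        t = totals.as_array()
        y = self.as_array()
        return bool(np.all(y >= -tol) and np.all(y <= t + tol))


@dataclass(frozen=True)
class Trajectory:
    """Time course of the three active concentrations on a minute grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 3), columns m_act, u_act, p_act

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if states.shape != (times.size, 3):
            raise ValueError("states must have shape (len(times), 3)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def m_act(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def u_act(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def p_act(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def to_frame(self, totals: TotalLevels):
        """Tabular form with the phospho-observable columns appended."""
        import pandas as pd

        obs = to_observables(self, totals)
        return pd.DataFrame(
            {
                "time_min": self.times,
                "m_act": self.m_act,
                "u_act": self.u_act,
                "p_act": self.p_act,
                **obs,
            }
        )


def _rhs(y: np.ndarray, k: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Vector field on raw arrays; the hot path shared by all callers."""
    m, u, p = y
    ka_m, ki_m, ka_u, ki_u, ka_p, ki_p, k_a, k_b, k_c, k_d, k_e, k_f = k
    MT, UT, PT = t
    return np.array(
        [
            ka_m * (MT - m) - (ki_m + k_b * u + k_e * p) * m,
            (ka_u + k_c * p) * (UT - u) - (ki_u + k_a * m) * u,
            (ka_p + k_d * u) * (PT - p) - (ki_p + k_f * m) * p,
        ]
    )


def _jac(y: np.ndarray, k: np.ndarray, t: np.ndarray) -> np.ndarray:
    m, u, p = y
    ka_m, ki_m, ka_u, ki_u, ka_p, ki_p, k_a, k_b, k_c, k_d, k_e, k_f = k
    MT, UT, PT = t
    return np.array(
        [
            [-ka_m - ki_m - k_b * u - k_e * p, -k_b * m, -k_e * m],
            [-k_a * u, -(ka_u + k_c * p) - ki_u - k_a * m, k_c * (UT - u)],
            [-k_f * p, k_d * (PT - p), -(ka_p + k_d * u) - ki_p - k_f * m],
        ]
    )


def rhs(
    state: SystemState, rates: RateConstants, totals: TotalLevels
) -> tuple[float, float, float]:
    """Time derivatives (dm/dt, du/dt, dp/dt) of the active forms."""
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    dm, du, dp = _rhs(y, rates.as_array(), totals.as_array())
    return float(dm), float(du), float(dp)


def jacobian(
    state: SystemState, rates: RateConstants, totals: TotalLevels
) -> np.ndarray:
    """Analytic 3×3 Jacobian of :func:`rhs` at ``state``."""
    return _jac(state.as_array(), rates.as_array(), totals.as_array())


def simulate(
    initial: SystemState,
    rates: RateConstants,
    totals: TotalLevels,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model on ``t_grid`` (minutes) with a stiff-capable solver.

    ``t_grid`` must start at 0 and be strictly increasing.  States are
    clipped to the conservation box only within solver tolerance; genuine
    escape raises :class:`SimulationError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    if not initial.within_bounds(totals):
        raise ValueError("initial state violates conservation bounds")
    k = rates.as_array()
    t = totals.as_array()
    sol = solve_ivp(
        lambda _t, y: _rhs(y, k, t),
        (t_grid[0], t_grid[-1]),
        initial.as_array(),
        method="LSODA",
        t_eval=t_grid,
        jac=lambda _t, y: _jac(y, k, t),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else float(t_grid[0])
        raise SimulationError(f"integration failed: {sol.message}", last)
    states = sol.y.T
    # Tolerate only round-off-scale excursions outside the box.
    slack = max(100 * atol, 1e-7)
    if np.any(states < -slack) or np.any(states > t[None, :] + slack):
        raise SimulationError("trajectory left the conservation box", float(sol.t[-1]))
    states = np.clip(states, 0.0, t[None, :])
    return Trajectory(times=t_grid, states=states)


def steady_state(
    rates: RateConstants,
    totals: TotalLevels,
    initial: SystemState,
    tol: float = 1e-8,
    t_max: float = 1e5,
) -> SystemState:
    """Relax from ``initial`` to the attracting steady state.

    Integrates in doubling time chunks until ``‖rhs‖ < tol`` and then
    polishes with a Newton step so the fixed-point residual is at
    round-off level.  Raises :class:`ConvergenceError` if the horizon
    ``t_max`` minutes is exhausted.
    """
    k = rates.as_array()
    t = totals.as_array()
    y = initial.as_array()
    elapsed, chunk = 0.0, 200.0
    while elapsed < t_max:
        sol = solve_ivp(
            lambda _t, yy: _rhs(yy, k, t),
            (0.0, chunk),
            y,
            method="LSODA",
            jac=lambda _t, yy: _jac(yy, k, t),
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise SimulationError(f"relaxation failed: {sol.message}", elapsed)
        y = sol.y[:, -1]
        elapsed += chunk
        chunk *= 2.0
        if np.linalg.norm(_rhs(y, k, t)) < tol:
            break
    else:  # pragma: no cover - defensive
        pass
    if np.linalg.norm(_rhs(y, k, t)) >= tol:
        raise ConvergenceError(
            f"no steady state within {t_max:g} min (‖rhs‖="
            f"{np.linalg.norm(_rhs(y, k, t)):.3g})"
        )
    res = root(lambda yy: _rhs(yy, k, t), y, jac=lambda yy: _jac(yy, k, t), tol=1e-13)
    if res.success and np.linalg.norm(_rhs(res.x, k, t)) < tol:
        y = np.clip(res.x, 0.0, t)
    return SystemState.from_array(y)


def physiological_steady_state(
    rates: RateConstants, tol: float = 1e-8
) -> SystemState:
    """Resting state of the untreated cell (all totals = 1).

    Obtained by relaxing from the mTORC1-dominant corner (m = MT, u = p = 0),
    mirroring the high initial mTORC1 activity that selects the
    non-autophagy branch of the bistable switch.
    """
    totals = TotalLevels()
    corner = SystemState(totals.mTORT, 0.0, 0.0)
    return steady_state(rates, totals, corner, tol=tol)


def apply_treatment(state: SystemState, totals_after: TotalLevels) -> SystemState:
    """Project a state onto the conservation box of a reduced total pool.

    A drug applied at t = 0 shrinks a total pool; any active amount above
    the new total is removed (clipped), the rest is untouched.
    """
    t = totals_after.as_array()
    return SystemState.from_array(np.minimum(state.as_array(), t))


def to_observables(
    traj: Trajectory, totals: TotalLevels, ratios: bool = False
) -> dict[str, np.ndarray]:
    """Map a trajectory to the immunoblot phospho-readouts.

    ``ulk1_757P`` and ``pp2a_P`` are the inactive (phosphorylated) pools
    ``UT − u`` and ``PT − p``; ``p70S6K_P`` proxies mTORC1 activity as
    ``m``.  With ``ratios=True`` the ULK1 and PP2A readouts are divided by
    their totals, giving the phospho/total ratios of densitometry; the
    p70S6K readout stays proportional to absolute mTORC1 kinase activity
    because total p70S6K is a downstream substrate, not a model pool.
    """
    ulk1_p = totals.ULK1T - traj.u_act
    pp2a_p = totals.PP2AT - traj.p_act
    s6k_p = traj.m_act.copy()
    if ratios:
        ulk1_p = ulk1_p / totals.ULK1T
        pp2a_p = pp2a_p / totals.PP2AT
    return {"ulk1_757P": ulk1_p, "pp2a_P": pp2a_p, "p70S6K_P": s6k_p}


# ---------------------------------------------------------------------------
# Parameter configuration files


def load_params(path: str | Path) -> tuple[RateConstants, TotalLevels]:
    """Read a flat YAML parameter config (12 rate constants + 3 totals).

    Totals are optional and default to the physiological value 1.
    Unknown keys are rejected.  A nested ``metadata`` block is permitted
    and ignored.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter config {path} is not a mapping")
    raw = dict(raw)
    raw.pop("metadata", None)
    unknown = set(raw) - set(RATE_NAMES) - set(TOTAL_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    rates = RateConstants.from_mapping({k: raw[k] for k in RATE_NAMES if k in raw})
    totals = TotalLevels(**{k: float(raw[k]) for k in TOTAL_NAMES if k in raw})
    return rates, totals


def save_params(
    path: str | Path,
    rates: RateConstants,
    totals: TotalLevels | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a parameter config in the same flat YAML dialect."""
    payload: dict[str, object] = dict(rates.to_dict())
    if totals is not None:
        payload.update(totals.to_dict())
    if metadata:
        payload["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def reference_rates() -> RateConstants:
    """The generator-truth rate constants shipped with the package."""
    rates, _ = load_params(_data_path("reference_params.yaml"))
    return rates


def default_rates() -> RateConstants:
    """The default rate constants used by all catalog experiments."""
    rates, _ = load_params(_data_path("default_params.yaml"))
    return rates
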