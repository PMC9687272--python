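"""Phase-plane analysis of the autophagy switch.

The 3-D system is projected onto the (m_act, u_act) plane by putting PP2A
at quasi-steady state — legitimate because active PP2A enters its own
balance linearly, so its nullcline solves in closed form.  On that plane
the ULK1 and mTORC1 balance curves (nullclines) are traced, their
intersections enumerated as equilibria of the full system, and each
equilibrium classified by the eigenvalues of the full 3×3 Jacobian.
Scanning a treatment lever (a total pool) over a range of values maps out
where the bistable region begins and ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .model import (
    RateConstants,
    SystemState,
    TotalLevels,
    _jac,
    _rhs,
    jacobian,
)

__all__ = [
    "BalanceCurve",
    "Equilibrium",
    "pp2a_qss",
    "balance_curve",
    "find_equilibria",
    "classify_stability",
    "label_state",
    "bifurcation_scan",
    "equilibria_frame",
]

#: Residual below which a refined root is accepted as an equilibrium.
ROOT_TOL = 1e-9
#: Euclidean distance below which two roots are merged as duplicates.
MERGE_TOL = 1e-6
#: Margin on eigenvalue real parts for the stable/unstable call.
STABILITY_TOL = 1e-8


@dataclass(frozen=True)
class BalanceCurve:
    """Zero set of one variable's derivative with PP2A at quasi-steady state."""

    which: Literal["ULK1", "mTORC1"]
    points: np.ndarray  # shape (n, 2): columns m_act, u_act

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["m_act", "u_act"])


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the full system with its stability and identity."""

    state: SystemState
    stability: Literal["stable", "unstable"]
    label: Literal["non-autophagy", "autophagy"]
    eigenvalues: tuple[complex, complex, complex]
    marginal: bool = False


def pp2a_qss(
    u_act: float, m_act: float, rates: RateConstants, totals: TotalLevels
) -> float:
    """Quasi-steady active PP2A at clamped (u_act, m_act), in closed form.

    Setting dp/dt = 0 gives
    ``p = (ka_p + k_d·u)·PT / (ka_p + k_d·u + ki_p + k_f·m)``,
    always inside [0, PT] for positive rates.
    """
    num = rates.ka_p + rates.k_d * u_act
    return num * totals.PP2AT / (num + rates.ki_p + rates.k_f * m_act)


def _reduced_rhs(
    m: float, u: float, rates: RateConstants, totals: TotalLevels
) -> tuple[float, float]:
    """(dm/dt, du/dt) on the plane, PP2A eliminated."""
    p = pp2a_qss(u, m, rates, totals)
    dm = rates.ka_m * (totals.mTORT - m) - (
        rates.ki_m + rates.k_b * u + rates.k_e * p
    ) * m
    du = (rates.ka_u + rates.k_c * p) * (totals.ULK1T - u) - (
        rates.ki_u + rates.k_a * m
    ) * u
    return dm, du


def _reduced_grid(
    rates: RateConstants, totals: TotalLevels, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized reduced derivatives on an n×n grid over the state box."""
    m = np.linspace(0.0, totals.mTORT, n)
    u = np.linspace(0.0, totals.ULK1T, n)
    M, U = np.meshgrid(m, u, indexing="ij")
    num = rates.ka_p + rates.k_d * U
    P = num * totals.PP2AT / (num + rates.ki_p + rates.k_f * M)
    dM = rates.ka_m * (totals.mTORT - M) - (
        rates.ki_m + rates.k_b * U + rates.k_e * P
    ) * M
    dU = (rates.ka_u + rates.k_c * P) * (totals.ULK1T - U) - (
        rates.ki_u + rates.k_a * M
    ) * U
    return m, u, dM, dU


def balance_curve(
    which: Literal["ULK1", "mTORC1"],
    rates: RateConstants,
    totals: TotalLevels,
    resolution: int = 200,
) -> BalanceCurve:
    """Trace one nullcline over the (m_act, u_act) rectangle.

    For each grid value of the transverse coordinate the sign changes of
    the reduced derivative are bracketed and polished with Brent's method,
    so every returned point satisfies the balance condition to solver
    precision.  Points are ordered along the sweep axis; an empty curve
    (possible when a pool is nearly depleted) is returned with a warning.
    """
    if which not in ("ULK1", "mTORC1"):
        raise ValueError("which must be 'ULK1' or 'mTORC1'")
    if resolution < 100:
        raise ValueError("resolution must be at least 100")

    pts: list[tuple[float, float]] = []
    if which == "ULK1":
        # du/dt = 0: sweep m, solve for u (possibly multivalued).
        sweep = np.linspace(0.0, totals.mTORT, resolution)
        axis = np.linspace(0.0, totals.ULK1T, resolution)
        f = lambda u, m: _reduced_rhs(m, u, rates, totals)[1]
    else:
        # dm/dt = 0: sweep u, solve for m.
        sweep = np.linspace(0.0, totals.ULK1T, resolution)
        axis = np.linspace(0.0, totals.mTORT, resolution)
        f = lambda m, u: _reduced_rhs(m, u, rates, totals)[0]

    for s in sweep:
        vals = np.array([f(a, s) for a in axis])
        for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
            try:
                a_root = brentq(f, axis[i], axis[i + 1], args=(s,), xtol=1e-12)
            except ValueError:  # pragma: no cover - bracket lost to round-off
                continue
            pts.append((s, a_root) if which == "ULK1" else (a_root, s))
        for i in np.flatnonzero(vals == 0.0):
            pts.append((s, axis[i]) if which == "ULK1" else (axis[i], s))

    if not pts:
        warnings.warn(f"{which} balance curve is empty inside the state box")
        return BalanceCurve(which, np.empty((0, 2)))
    order = 0 if which == "ULK1" else 1
    arr = np.array(sorted(pts, key=lambda q: (q[order], q[1 - order])))
    return BalanceCurve(which, arr)


def classify_stability(
    eq: SystemState, rates: RateConstants, totals: TotalLevels
) -> tuple[str, tuple[complex, ...], bool]:
    """Stable/unstable call from the full 3×3 Jacobian eigenvalues.

    Returns ``(stability, eigenvalues, marginal)``; ``marginal`` flags a
    leading real part inside ±STABILITY_TOL of zero, where the linear
    analysis is inconclusive.
    """
    eigs = np.linalg.eigvals(jacobian(eq, rates, totals))
    max_re = float(np.max(eigs.real))
    marginal = abs(max_re) <= STABILITY_TOL
    stability = "stable" if max_re < -STABILITY_TOL else "unstable"
    return stability, tuple(eigs), marginal


def label_state(eq: SystemState, totals: TotalLevels) -> str:
    """Autophagy iff the ULK1 active fraction exceeds the mTORC1 one."""
    if eq.u_act / totals.ULK1T > eq.m_act / totals.mTORT:
        return "autophagy"
    return "non-autophagy"


def find_equilibria(
    rates: RateConstants,
    totals: TotalLevels,
    seed_resolution: int = 30,
) -> list[Equilibrium]:
    """Enumerate all steady states inside the conservation box.

    Multi-start Newton refinement on the PP2A-eliminated 2-D system,
    seeded from a regular grid; duplicates merged within MERGE_TOL; each
    root lifted back to 3-D, verified against the full vector field and
    classified.  At least one equilibrium always exists for positive
    rates (the box is forward-invariant), so an empty result is an error.
    """
    k = rates.as_array()
    t = totals.as_array()

    def g(x: np.ndarray) -> np.ndarray:
        m, u = x
        return np.array(_reduced_rhs(m, u, rates, totals))

    roots: list[np.ndarray] = []
    box = np.array([totals.mTORT, totals.ULK1T])
    for m0 in np.linspace(0.0, totals.mTORT, seed_resolution):
        for u0 in np.linspace(0.0, totals.ULK1T, seed_resolution):
            res = root(g, np.array([m0, u0]), method="hybr", tol=1e-13)
            if not res.success:
                continue
            x = res.x
            if np.any(x < -1e-9) or np.any(x > box + 1e-9):
                continue
            x = np.clip(x, 0.0, box)
            if all(np.linalg.norm(x - r) >= MERGE_TOL for r in roots):
                roots.append(x)

    out: list[Equilibrium] = []
    for m, u in sorted(map(tuple, roots), key=lambda q: q[1]):
        p = pp2a_qss(u, m, rates, totals)
        y = np.array([m, u, p])
        res = root(
            lambda yy: _rhs(yy, k, t), y, jac=lambda yy: _jac(yy, k, t), tol=1e-14
        )
        if res.success:
            y = res.x
        if np.linalg.norm(_rhs(y, k, t)) >= ROOT_TOL:
            continue
        if np.any(y < -1e-9) or np.any(y > t + 1e-9):
            continue
        state = SystemState.from_array(np.clip(y, 0.0, t))
        if any(
            np.linalg.norm(state.as_array() - e.state.as_array()) < MERGE_TOL
            for e in out
        ):
            continue
        stability, eigs, marginal = classify_stability(state, rates, totals)
        out.append(
            Equilibrium(
                state=state,
                stability=stability,
                label=label_state(state, totals),
                eigenvalues=eigs,
                marginal=marginal,
            )
        )
    if not out:
        raise RuntimeError(
            "no equilibrium found; impossible for positive rates — "
            "increase seed_resolution"
        )
    return out


def bifurcation_scan(
    lever: Literal["mTORT", "ULK1T", "PP2AT"],
    values: Iterable[float],
    rates: RateConstants,
    base_totals: TotalLevels | None = None,
) -> pd.DataFrame:
    """Equilibrium bookkeeping along a treatment-lever scan.

    One row per lever value: equilibrium count, stable count, sorted
    labels, and the largest eigenvalue real part over all equilibria
    (useful to rule out oscillatory instabilities).
    """
    if lever not in ("mTORT", "ULK1T", "PP2AT"):
        raise ValueError(f"unknown lever {lever!r}")
    base = base_totals or TotalLevels()
    rows = []
    for v in values:
        totals = base.replace(**{lever: float(v)})
        eqs = find_equilibria(rates, totals)
        max_im_at_margin = max(
            (
                abs(e.imag)
                for eq in eqs
                for e in eq.eigenvalues
                if abs(e.real) <= 10 * STABILITY_TOL
            ),
            default=0.0,
        )
        rows.append(
            {
                "lever_name": lever,
                "lever_value": float(v),
                "n_equilibria": len(eqs),
                "n_stable": sum(e.stability == "stable" for e in eqs),
                "labels": "|".join(sorted(e.label for e in eqs)),
                "max_re_eigenvalue": max(
                    max(ev.real for ev in eq.eigenvalues) for eq in eqs
                ),
                "imag_at_marginal": max_im_at_margin,
            }
        )
    return pd.DataFrame(rows)


def equilibria_frame(
    eqs: Sequence[Equilibrium],
    lever_name: str = "",
    lever_value: float = float("nan"),
) -> pd.DataFrame:
    """Flatten equilibria into the delimited report schema."""
    rows = []
    for eq in eqs:
        rows.append(
            {
                "lever_name": lever_name,
                "lever_value": lever_value,
                "m_act": eq.state.m_act,
                "u_act": eq.state.u_act,
                "p_act": eq.state.p_act,
                "stability": eq.stability,
                "label": eq.label,
                "max_re_eigenvalue": max(e.real for e in eq.eigenvalues),
            }
        )
    return pd.DataFrame(rows)
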