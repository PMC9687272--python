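"""Synthetic densitometry generator emulating the immunoblot experiments.

Each treatment protocol mirrors one wet-lab condition: an optional siRNA
pre-silencing step (the cell is equilibrated at the reduced total before
anything else happens), a drug step applied at t = 0 as a drop in a total
pool, a sampling schedule in minutes, and a replicate count.  The model is
simulated under the protocol, mapped to the three phospho-readouts,
corrupted with multiplicative Gaussian noise per replicate, and normalized
per protein to the replicate mean of its own t = 0 control — the same
normalization chain applied to the real blots.

The defaults encode the study conditions: sampling every 10 min for 60 min
(acute rapamycin / okadaic-acid series), every 30 min for 180 min
(prolonged okadaic acid), and three replicates per point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densitometry import PROTEINS, DensitometrySeries
from .model import (
    RateConstants,
    SystemState,
    TotalLevels,
    apply_treatment,
    physiological_steady_state,
    simulate,
    steady_state,
)

__all__ = [
    "TreatmentProtocol",
    "NoiseModel",
    "builtin_protocols",
    "noiseless_observables",
    "generate",
]

#: Acute drug series: samples every 10 min for 60 min.
SCHEDULE_60 = tuple(float(t) for t in range(0, 61, 10))
#: Prolonged series: samples every 30 min for 180 min.
SCHEDULE_180 = tuple(float(t) for t in range(0, 181, 30))
#: Endpoint-style combined-treatment series (2 h of rapamycin).
SCHEDULE_120 = tuple(float(t) for t in range(0, 121, 30))


@dataclass(frozen=True)
class TreatmentProtocol:
    """One named experimental condition.

    ``pre_silenced`` models siRNA transfection: the system is equilibrated
    at those totals before t = 0.  ``totals_after`` are the pools from
    t = 0 on (drug steps).  The t = 0 sample is the untreated (but
    possibly pre-silenced) control.
    """

    name: str
    totals_after: TotalLevels
    schedule: tuple[float, ...] = SCHEDULE_60
    pre_silenced: TotalLevels | None = None
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if len(self.schedule) == 0 or self.schedule[0] != 0.0:
            raise ValueError("schedule must start at 0 (the control point)")
        if np.any(np.diff(self.schedule) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def control_totals(self) -> TotalLevels:
        return self.pre_silenced if self.pre_silenced is not None else TotalLevels()


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, truncated positive.

    ``cv`` is the coefficient of variation of a band intensity; the
    default 0.10 is a typical replicate scatter for quantified
    immunoblots.  The paper reports mean ± SD over three measurements but
    prints no noise magnitude, so this is a modelling choice.
    """

    cv: float = 0.10
    seed: int = 0
    type: str = "multiplicative-gaussian"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.type != "multiplicative-gaussian":
            raise ValueError(f"unsupported noise type {self.type!r}")


def builtin_protocols() -> dict[str, TreatmentProtocol]:
    """Catalog of the named treatment conditions.

    Drug levers: 100 nM rapamycin ↦ mTORT = 0.1; 100 nM okadaic acid ↦
    PP2AT = 0.1.  siRNA levers: ULK1T ∈ {0.01, 0.3}; PP2AT = 0.01 for
    full silencing, 0.25 for the measured residual after transfection.
    """
    P = TreatmentProtocol
    protocols = [
        P("control", TotalLevels()),
        P("rapamycin_60min", TotalLevels(mTORT=0.1)),
        P("oa_60min", TotalLevels(PP2AT=0.1)),
        P("oa_180min", TotalLevels(PP2AT=0.1), schedule=SCHEDULE_180),
        P(
            "ulk1_siRNA_rap_low",
            TotalLevels(ULK1T=0.01, mTORT=0.1),
            schedule=SCHEDULE_120,
            pre_silenced=TotalLevels(ULK1T=0.01),
        ),
        P(
            "ulk1_siRNA_rap_mid",
            TotalLevels(ULK1T=0.3, mTORT=0.1),
            schedule=SCHEDULE_120,
            pre_silenced=TotalLevels(ULK1T=0.3),
        ),
        P(
            "pp2a_siRNA_rap",
            TotalLevels(PP2AT=0.01, mTORT=0.1),
            schedule=SCHEDULE_120,
            pre_silenced=TotalLevels(PP2AT=0.01),
        ),
        P(
            "pp2a_siRNA_25",
            TotalLevels(PP2AT=0.25),
            schedule=SCHEDULE_120,
            pre_silenced=TotalLevels(PP2AT=0.25),
        ),
        P(
            "oa_plus_rap",
            TotalLevels(PP2AT=0.1, mTORT=0.1),
            schedule=SCHEDULE_120,
        ),
    ]
    return {p.name: p for p in protocols}


def _signals(state_m, state_u, state_p, totals: TotalLevels) -> dict[str, np.ndarray]:
    """Raw (pre-normalization) densitometry signals for given active levels.

    ULK1 and PP2A phospho bands are expressed per total protein; the
    phospho-p70S6K band tracks absolute mTORC1 kinase activity.
    """
    return {
        "ULK1_757P": (totals.ULK1T - np.asarray(state_u)) / totals.ULK1T,
        "PP2A_P": (totals.PP2AT - np.asarray(state_p)) / totals.PP2AT,
        "p70S6K_P": np.asarray(state_m, dtype=float),
    }


def _control_state(protocol: TreatmentProtocol, rates: RateConstants) -> SystemState:
    phys = physiological_steady_state(rates)
    if protocol.pre_silenced is None:
        return phys
    # 24 h of silencing before treatment: fully re-equilibrated.
    sil = protocol.pre_silenced
    return steady_state(rates, sil, apply_treatment(phys, sil))


def noiseless_observables(
    protocol: TreatmentProtocol,
    rates: RateConstants,
    control: SystemState | None = None,
) -> dict[str, np.ndarray]:
    """Control-normalized noiseless signals on the protocol's schedule.

    The t = 0 entry is the control sample itself, so every series starts
    at exactly 1.  ``control`` may be passed to avoid recomputing the
    pre-treatment steady state.
    """
    if control is None:
        control = _control_state(protocol, rates)
    ctrl = _signals(
        control.m_act, control.u_act, control.p_act, protocol.control_totals
    )
    initial = apply_treatment(control, protocol.totals_after)
    traj = simulate(initial, rates, protocol.totals_after, protocol.schedule)
    sig = _signals(traj.m_act, traj.u_act, traj.p_act, protocol.totals_after)
    out = {}
    for name in PROTEINS:
        series = sig[name].astype(float).copy()
        series[0] = ctrl[name]  # the t=0 sample is taken untreated
        out[name] = series / ctrl[name]
    return out


def generate(
    protocol: TreatmentProtocol,
    rates: RateConstants,
    noise: NoiseModel = NoiseModel(),
    include_totals: bool = False,
) -> list[DensitometrySeries]:
    """Simulate one protocol into replicated densitometry series.

    Noise is applied multiplicatively per replicate to the raw signals and
    the result renormalized to the replicate mean of the t = 0 control,
    exactly as blot intensities are processed.  Deterministic for a fixed
    ``noise.seed``.  With ``include_totals=True`` three additional series
    report the total-protein bands relative to the physiological totals
    (the silencing-efficiency readout).
    """
    rng = np.random.default_rng(noise.seed)
    clean = noiseless_observables(protocol, rates)
    n_rep, n_t = protocol.n_replicates, len(protocol.schedule)
    out = []
    for name in PROTEINS:
        factors = 1.0 + noise.cv * rng.standard_normal((n_rep, n_t))
        noisy = clean[name][None, :] * np.clip(factors, 0.05, None)
        ctrl_mean = noisy[:, 0].mean()
        out.append(
            DensitometrySeries(
                protein=name,
                condition=protocol.name,
                times=np.asarray(protocol.schedule),
                values=noisy / ctrl_mean,
            )
        )
    if include_totals:
        totals_now = protocol.totals_after.as_array()
        for readout, level in zip(
            ("p70S6K_total", "ULK1_total", "PP2A_total"), totals_now
        ):
            factors = 1.0 + noise.cv * rng.standard_normal((n_rep, n_t))
            noisy = level * np.clip(factors, 0.05, None)
            out.append(
                DensitometrySeries(
                    protein=readout,
                    condition=protocol.name,
                    times=np.asarray(protocol.schedule),
                    values=noisy,  # relative to physiological total = 1
                )
            )
    return out


def generate_catalog(
    names: tuple[str, ...],
    rates: RateConstants,
    noise: NoiseModel = NoiseModel(),
) -> list[DensitometrySeries]:
    """Generate several named protocols; the seed is offset per protocol so
    conditions carry independent noise while staying reproducible."""
    catalog = builtin_protocols()
    out = []
    for i, name in enumerate(names):
        if name not in catalog:
            raise KeyError(f"unknown protocol {name!r}")
        n = NoiseModel(cv=noise.cv, seed=(noise.seed + 7919 * i) % (2**31))
        out.extend(generate(catalog[name], rates, n))
    return out
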