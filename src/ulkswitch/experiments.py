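"""Named reproductions of the model's figure-level computations.

Each catalog experiment fixes the treatment levers of one simulated
condition — e.g. rapamycin as mTORT = 0.1, okadaic acid as PP2AT = 0.1 or
0.3, siRNA as a pre-equilibrated reduced total — runs the requested
analyses (trajectory, equilibria, balance curves) and evaluates the
condition's qualitative claim as a machine-checkable assertion on the
final state, with half-activation of the relevant pool as the threshold.

``run_pipeline`` chains the whole workflow: synthetic densitometry
generation → rate-constant fitting → all catalog experiments →
consolidated report, deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import model
from .densitometry import write_densitometry
from .fitting import fit
from .model import (
    RateConstants,
    SystemState,
    TotalLevels,
    apply_treatment,
    physiological_steady_state,
    simulate,
    steady_state,
)
from .phaseplane import balance_curve, equilibria_frame, find_equilibria
from .synth import NoiseModel, generate_catalog

__all__ = ["ExperimentSpec", "experiment_catalog", "run_experiment", "run_pipeline"]

log = logging.getLogger("ulkswitch")


@dataclass(frozen=True)
class ExperimentSpec:
    """One named condition with its levers and requested analyses."""

    name: str
    totals: TotalLevels
    pre_silenced: TotalLevels | None = None
    analyses: tuple[str, ...] = ("trajectory", "equilibria")
    t_end: float = 360.0
    dt: float = 5.0

    def __post_init__(self) -> None:
        bad = set(self.analyses) - {"trajectory", "equilibria", "phase_plane"}
        if bad:
            raise ValueError(f"unknown analyses {sorted(bad)}")


def experiment_catalog() -> dict[str, ExperimentSpec]:
    """The named figure-level conditions.

    Drug levers follow the simulation annotations: rapamycin mTORT = 0.1;
    okadaic acid PP2AT = 0.1 acutely and 0.3 in the phase-plane panel;
    siRNA as pre-equilibrated ULK1T ∈ {0.01, 0.3} or PP2AT = 0.01.
    """
    E, T = ExperimentSpec, TotalLevels
    specs = [
        E("physiological", T(), analyses=("trajectory", "equilibria", "phase_plane")),
        E("fig2c", T(mTORT=0.1), t_end=60.0, dt=1.0),
        E("fig3c", T(PP2AT=0.1), t_end=60.0, dt=1.0),
        E("fig4a", T(), analyses=("equilibria", "phase_plane")),
        E("fig4b", T(mTORT=0.1), analyses=("equilibria", "phase_plane")),
        E("fig4c", T(PP2AT=0.3), analyses=("trajectory", "equilibria", "phase_plane")),
        E("fig5c", T(ULK1T=0.01, mTORT=0.1), pre_silenced=T(ULK1T=0.01), t_end=120.0),
        E("fig5d", T(ULK1T=0.3, mTORT=0.1), pre_silenced=T(ULK1T=0.3), t_end=120.0),
        E("fig6c", T(PP2AT=0.1, mTORT=0.1), t_end=180.0),
        E("fig6d", T(PP2AT=0.01, mTORT=0.1), pre_silenced=T(PP2AT=0.01), t_end=120.0),
    ]
    return {s.name: s for s in specs}


#: Figure-level qualitative claims, encoded on final active fractions with
#: half-activation thresholds.
def _assertions(name: str, final: SystemState, totals: TotalLevels, label: str):
    m = final.m_act / totals.mTORT
    u = final.u_act / totals.ULK1T
    p = final.p_act / totals.PP2AT
    checks: dict[str, bool] = {}
    if name == "fig2c":
        checks["ulk1_activated"] = u > 0.5
        checks["mtorc1_inactivated"] = m < 0.5
        checks["final_autophagy"] = label == "autophagy"
    elif name == "fig3c":
        checks["ulk1_stays_inactive"] = u < 0.5
        checks["mtorc1_stays_active"] = m > 0.5
    elif name == "fig4c":
        checks["remains_non_autophagy"] = label == "non-autophagy"
    elif name in ("fig5c", "fig5d"):
        checks["no_pp2a_activation"] = p < 0.5
    elif name == "fig6c":
        checks["ulk1_activated"] = u > 0.5
        checks["final_autophagy"] = label == "autophagy"
    elif name == "fig6d":
        checks["ulk1_stays_inactive"] = u < 0.5
    return checks


def run_experiment(
    spec: ExperimentSpec,
    rates: RateConstants,
    outdir: str | Path | None = None,
    rates_provenance: str = "shipped default",
) -> dict:
    """Run one condition end to end and return its summary.

    Simulates from the (optionally pre-silenced) physiological steady
    state with the treatment levers applied at t = 0, relaxes to the
    final steady state, runs the requested analyses, writes all tabular
    outputs to ``outdir`` (if given), and evaluates the condition's
    encoded assertions.
    """
    log.info("experiment %s: parameters from %s", spec.name, rates_provenance)
    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)

    phys = physiological_steady_state(rates)
    if spec.pre_silenced is not None:
        start = steady_state(
            rates, spec.pre_silenced, apply_treatment(phys, spec.pre_silenced)
        )
    else:
        start = phys
    initial = apply_treatment(start, spec.totals)

    summary: dict = {"name": spec.name, "totals": spec.totals.to_dict()}

    if "trajectory" in spec.analyses:
        t_grid = np.arange(0.0, spec.t_end + spec.dt / 2, spec.dt)
        traj = simulate(initial, rates, spec.totals, t_grid)
        if outdir_path is not None:
            traj.to_frame(spec.totals).to_csv(
                outdir_path / f"{spec.name}_trajectory.csv", index=False
            )

    final = steady_state(rates, spec.totals, initial)
    from .phaseplane import label_state

    label = label_state(final, spec.totals)
    summary["final_state"] = {
        "m_act": final.m_act,
        "u_act": final.u_act,
        "p_act": final.p_act,
    }
    summary["final_label"] = label
    summary["assertions"] = _assertions(spec.name, final, spec.totals, label)

    if "equilibria" in spec.analyses:
        eqs = find_equilibria(rates, spec.totals)
        summary["n_equilibria"] = len(eqs)
        summary["n_stable"] = sum(e.stability == "stable" for e in eqs)
        summary["equilibrium_labels"] = sorted(e.label for e in eqs)
        if outdir_path is not None:
            equilibria_frame(eqs, lever_name=spec.name).to_csv(
                outdir_path / f"{spec.name}_equilibria.csv", index=False
            )

    if "phase_plane" in spec.analyses:
        for which in ("ULK1", "mTORC1"):
            curve = balance_curve(which, rates, spec.totals)
            if outdir_path is not None:
                curve.to_frame().to_csv(
                    outdir_path / f"{spec.name}_balance_{which}.csv", index=False
                )

    summary["ok"] = all(summary["assertions"].values())
    log.info(
        "experiment %s: final label %s; assertions %s",
        spec.name,
        label,
        summary["assertions"],
    )
    return summary


DEFAULT_PIPELINE_CONFIG: dict = {
    "seed": 0,
    "cv": 0.10,
    "fit_conditions": ("rapamycin_60min", "oa_60min"),
    "fit_budget": 5000,
    "do_fit": True,
    "use_fitted_for_experiments": False,
    "experiments": None,  # None -> whole catalog
}


def run_pipeline(
    config: Mapping[str, object] | None = None,
    outdir: str | Path = "pipeline_out",
) -> dict:
    """generate → fit → catalog experiments → consolidated report.

    Deterministic for a fixed ``seed``.  Experiments use the shipped
    default parameter set unless ``use_fitted_for_experiments`` is set;
    the fitted configuration is written alongside either way (when
    ``do_fit`` is on) so the two can be compared.
    """
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg.update(config)
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = model.reference_rates()
    report: dict = {"seed": seed, "stages": {}}

    # Stage 1: synthetic densitometry.
    try:
        data = generate_catalog(
            tuple(cfg["fit_conditions"]), truth, NoiseModel(cv=float(cfg["cv"]), seed=seed)
        )
        write_densitometry(data, outdir / "densitometry.csv")
        report["stages"]["generate"] = {
            "n_series": len(data),
            "conditions": sorted({s.condition for s in data}),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'generate' failed: {exc}") from exc

    # Stage 2: fit.
    rates = model.default_rates()
    provenance = "shipped default"
    if cfg["do_fit"]:
        try:
            result = fit(data, seed=seed, budget=int(cfg["fit_budget"]))
            model.save_params(
                outdir / "fitted_params.yaml",
                result.rates,
                metadata={
                    "cost": result.cost,
                    "n_evaluations": result.n_evaluations,
                    "seed": result.seed,
                    "converged": bool(result.converged),
                },
            )
            report["stages"]["fit"] = {
                "cost": result.cost,
                "n_evaluations": result.n_evaluations,
                "converged": bool(result.converged),
            }
            if cfg["use_fitted_for_experiments"]:
                rates, provenance = result.rates, "fitted"
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    # Stage 3: catalog experiments.
    catalog = experiment_catalog()
    names = cfg["experiments"] or tuple(catalog)
    summaries = {}
    for name in names:
        if name not in catalog:
            raise ValueError(f"unknown experiment {name!r}")
        try:
            summaries[name] = run_experiment(
                catalog[name], rates, outdir / "experiments", rates_provenance=provenance
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'experiment:{name}' failed: {exc}"
            ) from exc
    report["stages"]["experiments"] = summaries
    report["parameter_provenance"] = provenance

    # Consolidated numeric table (byte-stable for a fixed seed).
    rows = []
    for name, s in summaries.items():
        rows.append(
            {
                "experiment": name,
                "final_label": s["final_label"],
                "n_equilibria": s.get("n_equilibria", ""),
                "n_stable": s.get("n_stable", ""),
                "m_act": f"{s['final_state']['m_act']:.10f}",
                "u_act": f"{s['final_state']['u_act']:.10f}",
                "p_act": f"{s['final_state']['p_act']:.10f}",
                "all_assertions_pass": s["ok"],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "report.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
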