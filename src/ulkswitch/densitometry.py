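"""Densitometry time-series container and its delimited-text dialect.

A densitometry series is what an immunoblot quantification yields: for one
phospho-protein readout under one treatment, a set of replicate band
intensities per sampling time, normalized first to the matching total
protein and then to the untreated control, so the control time point has
mean 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROTEINS",
    "DensitometrySeries",
    "write_densitometry",
    "read_densitometry",
]

#: Phospho-readouts of the three model proteins: Ser757-phosphorylated
#: (inactive) ULK1, phosphorylated (inactive) PP2A, and phospho-p70S6K as
#: the mTORC1 activity proxy.  Total-protein readouts (suffix ``_total``)
#: are also admitted, for silencing-efficiency bookkeeping.
PROTEINS = ("ULK1_757P", "PP2A_P", "p70S6K_P")
TOTAL_READOUTS = ("ULK1_total", "PP2A_total", "p70S6K_total")

_COLUMNS = ["protein", "condition", "time_min", "replicate", "value"]


@dataclass(frozen=True)
class DensitometrySeries:
    """Replicated, control-normalized time course of one readout.

    ``values`` has shape (n_replicates, n_times); entry [r, i] is the
    normalized intensity of replicate ``r`` at ``times[i]`` minutes.
    """

    protein: str
    condition: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if times.ndim != 1 or times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("times must start at 0 (control) and increase")
        if values.shape[1] != times.size:
            raise ValueError("values must have one column per time point")
        if values.shape[0] < 1:
            raise ValueError("at least one replicate is required")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("densitometry values must be finite and positive")
        if self.protein not in PROTEINS + TOTAL_READOUTS:
            raise ValueError(f"unknown protein readout {self.protein!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def replicate_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def replicate_sd(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1) if self.n_replicates > 1 else np.zeros(
            self.times.size
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_replicates):
            for i, t in enumerate(self.times):
                rows.append(
                    (self.protein, self.condition, t, r + 1, self.values[r, i])
                )
        return pd.DataFrame(rows, columns=_COLUMNS)


def write_densitometry(
    series: Sequence[DensitometrySeries], path: str | Path
) -> None:
    """Write series to CSV with columns protein, condition, time_min, replicate, value."""
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    # %.17g guarantees binary64 round-trip through the text dialect
    frame.to_csv(path, index=False, float_format="%.17g")


def read_densitometry(path: str | Path) -> list[DensitometrySeries]:
    """Read the CSV dialect back into series (one per protein × condition)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"densitometry file {path} lacks columns {sorted(missing)}")
    out = []
    for (protein, condition), grp in frame.groupby(
        ["protein", "condition"], sort=False
    ):
        pivot = grp.pivot_table(
            index="replicate", columns="time_min", values="value", sort=True
        )
        out.append(
            DensitometrySeries(
                protein=str(protein),
                condition=str(condition),
                times=pivot.columns.to_numpy(dtype=float),
                values=pivot.to_numpy(dtype=float),
            )
        )
    return out
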