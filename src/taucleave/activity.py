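"""Chromogenic pNA protease activity: initial rates, specific activity, folds.

A pNA (para-nitroaniline) assay monitors absorbance at 405 nm while the
protease consumes a chromogenic peptide substrate.  Specific enzyme
activity is

    specific activity = dA405 * V / (m * eps * t)

with dA405 the absorbance change at 405 nm, V the reaction volume (ml),
m the protease amount (mg), eps the molar extinction coefficient of free
pNA (M^-1 cm^-1; path length folded in, 1 cm assumed) and t the time (min).
When dA405 is already a per-minute rate (the slope of the trace), t = 1 by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Molar extinction coefficient of free pNA at 405 nm (M^-1 cm^-1).
DEFAULT_EPSILON = 8800.0

#: Default initial-rate window: the first 20 min of a 2 h trace.
DEFAULT_WINDOW = (0.0, 20.0)


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A405 time series from one well; times in minutes, strictly increasing."""

    minutes: tuple[float, ...]
    a405: tuple[float, ...]
    ligand: str = ""
    ligand_concentration: float = 0.0

    def __post_init__(self) -> None:
        if len(self.minutes) != len(self.a405):
            raise ValueError("times and absorbances differ in length")
        t = tuple(float(x) for x in self.minutes)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "minutes", t)
        object.__setattr__(self, "a405", tuple(float(x) for x in self.a405))


@dataclass(frozen=True)
class ActivityMeasurement:
    """Inputs of the specific-activity formula (see module docstring)."""

    delta_a405: float  # absorbance change (per min when time_min == 1)
    volume_ml: float
    protease_mg: float
    epsilon: float = DEFAULT_EPSILON
    time_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("volume_ml", "protease_mg", "epsilon", "time_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_a405 < 0:
            raise ValueError("dA405 must be >= 0 for a substrate-consuming assay")


def initial_rate(
    trace: AbsorbanceTrace, window: tuple[float, float] = DEFAULT_WINDOW
) -> float:
    """Least-squares slope of A405 vs time (per minute) over the window."""
    t0, t1 = window
    times = np.asarray(trace.minutes)
    values = np.asarray(trace.a405)
    mask = (times >= t0) & (times <= t1)
    if mask.sum() < 3:
        raise ValueError(
            f"initial-rate window [{t0}, {t1}] covers {int(mask.sum())} points; "
            "need at least 3"
        )
    return float(stats.linregress(times[mask], values[mask]).slope)


def specific_activity(measurement: ActivityMeasurement) -> float:
    """Specific enzyme activity, dA405 * V / (m * eps * t)."""
    return (
        measurement.delta_a405
        * measurement.volume_ml
        / (measurement.protease_mg * measurement.epsilon * measurement.time_min)
    )


def fold_activation(
    activity_ligand: float | Sequence[float], activity_basal: float
) -> float | np.ndarray:
    """Activity ratio ligand / basal; accepts a batch over concentrations."""
    if activity_basal <= 0:
        raise ValueError("basal activity must be positive")
    ligand = np.asarray(activity_ligand, dtype=float)
    folds = ligand / activity_basal
    return float(folds) if folds.ndim == 0 else folds


def read_plate_csv(source) -> dict[str, AbsorbanceTrace]:
    """Read a long-format plate-reader export (columns well, minute, A405;
    optional ligand, ligand_concentration) into per-well traces."""
    frame = pd.read_csv(source)
    for column in ("well", "minute", "A405"):
        if column not in frame.columns:
            raise ValueError(f"plate export lacks mandatory column {column!r}")
    traces: dict[str, AbsorbanceTrace] = {}
    for well, group in frame.groupby("well", sort=True):
        group = group.sort_values("minute")
        ligand = str(group["ligand"].iloc[0]) if "ligand" in group else ""
        conc = (
            float(group["ligand_concentration"].iloc[0])
            if "ligand_concentration" in group
            else 0.0
        )
        traces[str(well)] = AbsorbanceTrace(
            minutes=tuple(group["minute"].astype(float)),
            a405=tuple(group["A405"].astype(float)),
            ligand=ligand,
            ligand_concentration=conc,
        )
    return traces


def activity_table(
    traces: dict[str, AbsorbanceTrace],
    volume_ml: float,
    protease_mg: float,
    epsilon: float = DEFAULT_EPSILON,
    window: tuple[float, float] = DEFAULT_WINDOW,
    basal_well: str | None = None,
) -> pd.DataFrame:
    """Specific activity per well, with fold activation over a basal well."""
    rows = []
    for well, trace in traces.items():
        rate = initial_rate(trace, window)
        act = specific_activity(
            ActivityMeasurement(
                delta_a405=max(rate, 0.0),
                volume_ml=volume_ml,
                protease_mg=protease_mg,
                epsilon=epsilon,
            )
        )
        rows.append(
            {
                "well": well,
                "ligand": trace.ligand,
                "ligand_concentration": trace.ligand_concentration,
                "rate_per_min": rate,
                "specific_activity": act,
            }
        )
    table = pd.DataFrame(rows)
    if basal_well is not None:
        basal = float(
            table.loc[table["well"] == basal_well, "specific_activity"].iloc[0]
        )
        table["fold_activation"] = fold_activation(
            table["specific_activity"].to_numpy(), basal
        )
    return table
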