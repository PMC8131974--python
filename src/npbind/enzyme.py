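"""Enzyme-activity rates and purification-table arithmetic.

Activity is followed as product fluorescence versus time; the initial
rate is the OLS slope over the linear phase divided by a
fluorescence-to-product calibration factor (fluorescence units per
umol ml^-1 of product).  Relative activity expresses a condition's rate
as a percentage of an uninhibited control.

A purification table tracks, per step: total protein
(volume x concentration), specific activity (total activity / total
protein), purification fold (specific activity relative to the crude
extract) and percent yield (total activity relative to crude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeCourse",
    "PurificationStep",
    "initial_rate",
    "relative_activity",
    "summarize_replicates",
    "purification_table",
    "purification_frame",
    "load_timecourses",
    "load_purification",
]


@dataclass(frozen=True)
class TimeCourse:
    """Product-formation time course for one assay condition.

    ``calibration`` converts fluorescence units to product
    concentration: fluorescence units per (umol ml^-1).
    """

    time: np.ndarray            # minutes, strictly increasing
    fluorescence: np.ndarray    # arbitrary units
    condition: str = ""
    calibration: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.shape != f.shape or t.ndim != 1 or len(t) < 3:
            raise ValueError("time course needs >=3 (time, fluorescence) pairs")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")


def initial_rate(tc: TimeCourse, window_minutes: tuple[float, float] | None = None) -> float:
    """Initial product-formation rate in umol ml^-1 min^-1.

    OLS slope of fluorescence on time over the window (default: the full
    trace), divided by the calibration factor.
    """
    if window_minutes is None:
        mask = np.ones_like(tc.time, dtype=bool)
    else:
        lo, hi = window_minutes
        mask = (tc.time >= lo) & (tc.time <= hi)
    t, f = tc.time[mask], tc.fluorescence[mask]
    if len(t) < 3:
        raise ValueError(f"window contains {len(t)} point(s); need >=3")
    if np.ptp(f) == 0.0:
        return 0.0
    res = stats.linregress(t, f)
    return float(res.slope) / tc.calibration


def relative_activity(rate: float, control_rate: float) -> float:
    """Activity as a percentage of the control rate."""
    if control_rate <= 0:
        raise ValueError("control rate must be > 0")
    return 100.0 * rate / control_rate


def summarize_replicates(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, sample standard deviation, n) of replicate measurements."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >=2 replicates for a standard deviation")
    return float(v.mean()), float(v.std(ddof=1)), int(v.size)


@dataclass(frozen=True)
class PurificationStep:
    """One row of a purification table with its derived quantities.

    Raw derived values are kept at full precision; ``rounded()`` applies
    the conventional 2-decimal display rounding.
    """

    name: str
    volume_ml: float
    protein_conc_mg_per_ml: float
    total_activity_U: float
    total_protein_mg: float
    specific_activity_U_per_mg: float
    fold: float
    yield_percent: float

    def rounded(self) -> dict:
        return {
            "name": self.name,
            "volume_ml": round(self.volume_ml, 2),
            "protein_conc_mg_per_ml": round(self.protein_conc_mg_per_ml, 2),
            "total_protein_mg": round(self.total_protein_mg, 2),
            "total_activity_U": round(self.total_activity_U, 2),
            "specific_activity_U_per_mg": round(self.specific_activity_U_per_mg, 2),
            "fold": round(self.fold, 2),
            "yield_percent": round(self.yield_percent, 2),
        }


def purification_table(
    steps: Sequence[tuple[str, float, float, float]]
) -> list[PurificationStep]:
    """Derive specific activity, fold and yield for a purification series.

    ``steps`` are (name, volume_ml, protein_conc_mg_per_ml,
    total_activity_U) with the first entry the crude reference, whose
    fold is 1 and yield 100 by definition.
    """
    if not steps:
        raise ValueError("empty purification table")
    out: list[PurificationStep] = []
    crude_specific = crude_activity = None
    for name, vol, conc, act in steps:
        if vol <= 0 or conc <= 0 or act <= 0:
            raise ValueError(f"step {name!r}: volume, concentration and activity must be > 0")
        protein = vol * conc
        specific = act / protein
        if crude_specific is None:
            crude_specific, crude_activity = specific, act
        out.append(
            PurificationStep(
                name=name,
                volume_ml=vol,
                protein_conc_mg_per_ml=conc,
                total_activity_U=act,
                total_protein_mg=protein,
                specific_activity_U_per_mg=specific,
                fold=specific / crude_specific,
                yield_percent=100.0 * act / crude_activity,
            )
        )
    return out


def purification_frame(steps: Sequence[PurificationStep], rounded: bool = True) -> pd.DataFrame:
    """Purification table as a DataFrame (display-rounded by default)."""
    if rounded:
        return pd.DataFrame([s.rounded() for s in steps])
    return pd.DataFrame([vars(s) for s in steps])


def load_timecourses(path, calibration: float = 1.0) -> list[TimeCourse]:
    """Read time courses from delimited text with columns time_min,
    fluorescence and optional condition."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"time_min", "fluorescence"} - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    if "condition" not in df.columns:
        df = df.assign(condition="")
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            TimeCourse(
                time=grp["time_min"].to_numpy(float),
                fluorescence=grp["fluorescence"].to_numpy(float),
                condition=str(cond),
                calibration=calibration,
            )
        )
    return out


def load_purification(path) -> list[PurificationStep]:
    """Read and derive a purification table from delimited text with
    columns name, volume_ml, conc_mg_per_ml, total_activity_U."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"name", "volume_ml", "conc_mg_per_ml", "total_activity_U"} - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    steps = [
        (str(r["name"]), float(r["volume_ml"]), float(r["conc_mg_per_ml"]),
         float(r["total_activity_U"]))
        for _, r in df.iterrows()
    ]
    return purification_table(steps)
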