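"""First-order plasma elimination and biodistribution summaries.

First-order elimination means concentration decays exponentially, so the
base-10 log of concentration is linear in time:

    log10 C(t) = a - b t,   half_life = log10(2) / b

with the slope reported positive for decay.  The fit is ordinary least
squares on the log-transformed concentrations; with destructive sampling
(separate animals per time point) it is applied to per-time group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "PKSeries", "EliminationFit", "PeakSummary", "fit_first_order",
    "half_life", "peak_summary", "group_mean_series", "read_pk", "write_pk",
]

LOG10_2 = math.log10(2.0)


@dataclass
class PKSeries:
    """Concentration-time course for one subject or group (time in hours)."""

    time: np.ndarray
    concentration: np.ndarray
    subject: str = ""
    group: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.time.shape != self.concentration.shape:
            raise DataError("time and concentration must be equal length")
        if (self.concentration <= 0).any():
            raise DataError("concentrations must be positive "
                            "(log-transform undefined otherwise)")


@dataclass
class EliminationFit:
    """Log-linear elimination fit y = a - b x with b > 0 for decay."""

    intercept: float
    slope: float
    r_squared: float
    half_life_h: float
    eliminating: bool
    group: str = ""


def half_life(b: float) -> float:
    """Elimination half-life log10(2)/b (hours) for a log10-slope b > 0."""
    if b <= 0:
        raise DataError("slope must be positive for a decaying profile")
    return LOG10_2 / b


def fit_first_order(series: PKSeries) -> EliminationFit:
    """OLS of log10(concentration) on time.

    A non-positive decay slope is flagged (``eliminating=False``) with the
    half-life undefined, never silently reported.
    """
    if len(series.time) < 3:
        raise DataError("need at least 3 time points to fit elimination")
    y = np.log10(series.concentration)
    res = stats.linregress(series.time, y)
    b = -float(res.slope)
    r2 = float(res.rvalue ** 2)
    if b <= 0:
        return EliminationFit(intercept=float(res.intercept), slope=b,
                              r_squared=r2, half_life_h=float("nan"),
                              eliminating=False, group=series.group)
    return EliminationFit(intercept=float(res.intercept), slope=b,
                          r_squared=r2, half_life_h=half_life(b),
                          eliminating=True, group=series.group)


def group_mean_series(series_list: list[PKSeries],
                      group: str = "") -> PKSeries:
    """Per-time mean across subjects sharing one measurement grid."""
    if not series_list:
        raise DataError("empty series list")
    t0 = series_list[0].time
    for s in series_list[1:]:
        if not np.array_equal(s.time, t0):
            raise DataError("mismatched measurement grids")
    conc = np.mean([s.concentration for s in series_list], axis=0)
    return PKSeries(t0.copy(), conc, group=group or series_list[0].group)


@dataclass
class PeakSummary:
    time_of_peak_h: float
    fold_change_vs_control: float
    group: str = ""


def peak_summary(group_series: list[PKSeries],
                 control: PKSeries) -> PeakSummary:
    """Time of maximum group mean and its fold-change vs the control mean.

    Ties in the maximum break toward the earliest time.
    """
    mean = group_mean_series(group_series)
    if not np.array_equal(mean.time, control.time):
        raise DataError("group and control must share the measurement grid")
    i = int(np.argmax(mean.concentration))  # argmax returns earliest maximum
    c = float(control.concentration[i])
    if c == 0:
        raise DataError("control mean is zero at the peak time")
    return PeakSummary(time_of_peak_h=float(mean.time[i]),
                       fold_change_vs_control=float(
                           mean.concentration[i] / c),
                       group=mean.group)


# -- I/O --------------------------------------------------------------------


def read_pk(path) -> list[PKSeries]:
    """Long format: columns time_h, concentration, subject, group."""
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"time_h", "concentration", "subject", "group"}
    if not need.issubset(df.columns):
        raise DataError(f"PK table must have columns {sorted(need)}")
    out = []
    for (group, subject), g in df.groupby(["group", "subject"], sort=True):
        g = g.sort_values("time_h")
        out.append(PKSeries(g["time_h"].to_numpy(),
                            g["concentration"].to_numpy(),
                            subject=str(subject), group=str(group)))
    return out


def write_pk(series_list: list[PKSeries], path) -> None:
    frames = [pd.DataFrame(dict(time_h=s.time, concentration=s.concentration,
                                subject=s.subject, group=s.group))
              for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
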