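"""Sigmoidal fibrillation-kinetics fitting for ThT fluorescence assays.

Amyloid fibrillation monitored by Thioflavin T fluorescence follows a
nucleation-growth time course: a lag phase, a rapid elongation phase and a
plateau.  The standard descriptive model is the Boltzmann sigmoid

    F(t) = F0 + A / (1 + exp(-k (t - t_half)))

with baseline ``F0``, amplitude ``A`` (plateau minus baseline), apparent
aggregation constant ``k`` (1/h) and midpoint ``t_half`` (h).  The lag time
uses the tangent-at-midpoint convention common in the amyloid-kinetics
literature:

    lag = t_half - 2/k

Inhibition of fibrillation shows up as a longer lag, a smaller ``k`` and a
reduced amplitude; ``max_intensity_decrease`` quantifies the last as a
percentage relative to a control fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConvergenceError, DataError, NoTransitionError

__all__ = [
    "ThTCurve", "SigmoidFit", "sigmoid_model", "fit_sigmoid",
    "max_intensity_decrease", "compare_fits", "read_tht", "write_tht",
]


@dataclass
class ThTCurve:
    """One fluorescence time series (time in hours, arbitrary units)."""

    time: np.ndarray
    fluorescence: np.ndarray
    replicate: int = 0
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.fluorescence.shape:
            raise DataError("time and fluorescence must be equal-length 1-D")
        if len(self.time) < 6:
            raise DataError("need at least 6 time points")
        if (np.diff(self.time) <= 0).any():
            raise DataError("time points must be strictly increasing")
        if (self.time < 0).any():
            raise DataError("time points must be non-negative")
        if not np.isfinite(self.fluorescence).all():
            raise DataError("fluorescence values must be finite")


@dataclass
class SigmoidFit:
    """Fitted sigmoid parameters; ``lag_time = t_half - 2/rate`` always."""

    f0: float
    amplitude: float
    rate: float
    t_half: float
    lag_time: float
    rss: float
    converged: bool
    label: str = ""
    replicate: int = 0
    message: str = ""
    pcov: np.ndarray | None = field(default=None, repr=False)


def sigmoid_model(t, f0, amplitude, rate, t_half):
    """Boltzmann sigmoid F0 + A / (1 + exp(-k (t - t_half)))."""
    t = np.asarray(t, dtype=float)
    # clip the exponent to avoid overflow far from the transition
    z = np.clip(-rate * (t - t_half), -700.0, 700.0)
    return f0 + amplitude / (1.0 + np.exp(z))


def _initial_guess(t, f):
    f0 = float(f.min())
    amp = float(f.max() - f.min())
    half = f0 + amp / 2.0
    above = np.nonzero(f >= half)[0]
    i = above[0] if len(above) else len(f) // 2
    if i == 0:
        t_half = float(t[0])
    else:
        # linear interpolation of the half-range crossing
        f1, f2 = f[i - 1], f[i]
        t_half = float(t[i - 1] + (half - f1) / max(f2 - f1, 1e-12)
                       * (t[i] - t[i - 1]))
    df = np.gradient(f, t)
    slope = float(df.max())
    k = 4.0 * slope / max(amp, 1e-12)
    k = min(max(k, 1e-3), 1e3)
    return f0, amp, k, t_half


def fit_sigmoid(curve: ThTCurve) -> SigmoidFit:
    """Nonlinear least squares with data-driven starting values.

    Raises :class:`NoTransitionError` for flat curves; a fit that fails to
    converge is returned flagged (``converged=False``) rather than raising,
    so batch pipelines can report it.
    """
    t = curve.time
    f = curve.fluorescence
    rng_f = float(f.max() - f.min())
    scale = max(abs(f).max(), 1.0)
    if rng_f <= 1e-9 * scale:
        raise NoTransitionError(
            f"no transition: curve '{curve.label}' is flat "
            f"(range {rng_f:.3g})")
    p0 = _initial_guess(t, f)
    try:
        popt, pcov = curve_fit(
            sigmoid_model, t, f, p0=p0, maxfev=20_000,
            bounds=([-np.inf, 0.0, 1e-9, -np.inf],
                    [np.inf, np.inf, np.inf, np.inf]))
    except (RuntimeError, ValueError) as exc:
        f0, amp, k, t_half = p0
        return SigmoidFit(f0=f0, amplitude=amp, rate=k, t_half=t_half,
                          lag_time=t_half - 2.0 / k, rss=float("nan"),
                          converged=False, label=curve.label,
                          replicate=curve.replicate,
                          message=f"did not converge: {exc}")
    f0, amp, k, t_half = (float(x) for x in popt)
    resid = f - sigmoid_model(t, *popt)
    return SigmoidFit(f0=f0, amplitude=amp, rate=k, t_half=t_half,
                      lag_time=t_half - 2.0 / k,
                      rss=float((resid ** 2).sum()), converged=True,
                      label=curve.label, replicate=curve.replicate,
                      pcov=pcov)


def max_intensity_decrease(control: SigmoidFit, treated: SigmoidFit) -> float:
    """Percent decrease of the fitted amplitude relative to the control.

    100 * (1 - A_treated / A_control); 60 means the treated plateau rises
    only 40% as far above baseline as the control's.
    """
    if not (control.converged and treated.converged):
        raise ConvergenceError("both fits must have converged")
    if control.amplitude <= 0:
        raise DataError("control amplitude must be positive")
    return 100.0 * (1.0 - treated.amplitude / control.amplitude)


def compare_fits(fits: list[SigmoidFit], control_label: str) -> pd.DataFrame:
    """Per-fit kinetic parameters and inhibition flags vs a control group.

    The inhibition direction is: lag up, rate down, amplitude down.  Group
    rows carry the percent amplitude decrease relative to the mean control
    amplitude.
    """
    conv = [f for f in fits if f.converged]
    if len(conv) < 2:
        raise DataError("need at least two converged fits")
    controls = [f for f in conv if f.label == control_label]
    if not controls:
        raise DataError(f"missing control label '{control_label}'")
    a_c = float(np.mean([f.amplitude for f in controls]))
    lag_c = float(np.mean([f.lag_time for f in controls]))
    k_c = float(np.mean([f.rate for f in controls]))
    rows = []
    for f in conv:
        rows.append(dict(
            label=f.label, replicate=f.replicate, lag_time=f.lag_time,
            t_half=f.t_half, rate=f.rate, amplitude=f.amplitude,
            pct_decrease=100.0 * (1.0 - f.amplitude / a_c),
            lag_increased=f.lag_time > lag_c,
            rate_decreased=f.rate < k_c,
            amplitude_decreased=f.amplitude < a_c,
        ))
    out = pd.DataFrame(rows)
    ctrl = out["label"] == control_label
    out.loc[ctrl, ["lag_increased", "rate_decreased",
                   "amplitude_decreased"]] = False
    return out


# -- I/O --------------------------------------------------------------------


def read_tht(path) -> list[ThTCurve]:
    """Long-format delimited text: columns time, value, replicate, label."""
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"time", "value", "replicate", "label"}
    if not need.issubset(df.columns):
        raise DataError(f"ThT table must have columns {sorted(need)}")
    curves = []
    for (label, rep), g in df.groupby(["label", "replicate"], sort=True):
        g = g.sort_values("time")
        curves.append(ThTCurve(g["time"].to_numpy(), g["value"].to_numpy(),
                               replicate=int(rep), label=str(label)))
    return curves


def write_tht(curves: list[ThTCurve], path) -> None:
    frames = [pd.DataFrame(dict(time=c.time, value=c.fluorescence,
                                replicate=c.replicate, label=c.label))
              for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
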