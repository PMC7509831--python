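"""One-site binding model for isothermal titration calorimetry.

A titrant (peptide, syringe) is injected stepwise into a cell containing the
binding species (nanoparticle).  With ``n0`` identical independent sites per
nanoparticle, site binding constant ``K`` (1/M) and molar enthalpy ``dH``
(kcal/mol), mass action gives the bound titrant concentration in closed form:

    b = X_t / (n0 M_t)      (molar-ratio of titrant to sites)
    X_b = (n0 M_t / 2) * (q - sqrt(q^2 - 4 b)),   q = 1 + b + 1/(n0 K M_t)

Injection bookkeeping follows the perfusion (overfill) convention of
standard titration calorimeters: each injection of ``dV`` into cell volume
``V0`` displaces an equal volume of mixed solution, so effective
concentrations are diluted by (1 - dV/2V0)/(1 + dV/2V0) per injection and
the measured heat of injection i is the change in cell heat content
corrected for the displaced material:

    q_i = Q_i - Q_{i-1} + (dV_i/V0) (Q_i + Q_{i-1})/2,
    Q_i = dH * V0 * X_b,i

Thermodynamic identities: dG = -R T ln K and dG = dH - T dS, with
R = 1.987e-3 kcal/(mol K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError

R_KCAL = 1.987e-3  # kcal / (mol K)
UCAL_PER_KCAL = 1e9

__all__ = [
    "ITCThermogram", "OneSiteFit", "one_site_heats", "fit_one_site",
    "derive_thermo", "read_itc", "write_itc", "R_KCAL",
]


@dataclass
class ITCThermogram:
    """Integrated per-injection heats plus the titration geometry.

    Volumes in microliters, concentrations in micromolar, heats in
    microcalories, temperature in kelvin.
    """

    injection_volumes_uL: np.ndarray
    heats_ucal: np.ndarray
    cell_volume_uL: float = 200.0
    cell_conc_uM: float = 1.5
    syringe_conc_uM: float = 138.0
    temperature_K: float = 298.15

    def __post_init__(self):
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL,
                                               dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.injection_volumes_uL.shape != self.heats_ucal.shape:
            raise DataError("volumes and heats must be equal length")
        if (self.injection_volumes_uL <= 0).any():
            raise DataError("injection volumes must be positive")
        if min(self.cell_volume_uL, self.cell_conc_uM,
               self.syringe_conc_uM, self.temperature_K) <= 0:
            raise DataError("geometry values must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_uL)

    def molar_ratios(self) -> np.ndarray:
        """Titrant-to-cell-species molar ratio after each injection."""
        _, x_t, m_t = _concentration_schedule(self)
        return x_t / m_t


@dataclass
class OneSiteFit:
    """One-site fit with derived Gibbs energy and entropy.

    ``dG = -R T ln K`` and ``dG = dH - T dS`` hold exactly for the returned
    fields.  ``dS`` is in cal/(mol K), everything else in kcal/mol.
    """

    n0: float
    K: float
    dH: float
    dG: float
    dS: float
    T: float
    offset: float = 0.0
    rss: float = float("nan")
    c_value: float = float("nan")
    converged: bool = True
    message: str = ""
    pcov: np.ndarray | None = field(default=None, repr=False)


def _concentration_schedule(tg: ITCThermogram):
    """Per-injection dilution factors and running concentrations (M)."""
    v0 = tg.cell_volume_uL
    dv = tg.injection_volumes_uL
    xs = tg.syringe_conc_uM * 1e-6
    m = tg.cell_conc_uM * 1e-6
    x = 0.0
    m_t = np.empty(tg.n_injections)
    x_t = np.empty(tg.n_injections)
    for i, dvi in enumerate(dv):
        f = (1.0 - dvi / (2 * v0)) / (1.0 + dvi / (2 * v0))
        m *= f
        x = x * f + xs * (dvi / v0) / (1.0 + dvi / (2 * v0))
        m_t[i] = m
        x_t[i] = x
    return dv / v0, x_t, m_t


def bound_titrant(x_t, m_t, n0: float, K: float):
    """Closed-form one-site bound-titrant concentration (M)."""
    x_t = np.asarray(x_t, dtype=float)
    m_t = np.asarray(m_t, dtype=float)
    sites = n0 * m_t
    q = 1.0 + x_t / sites + 1.0 / (K * sites)
    disc = q * q - 4.0 * x_t / sites
    disc = np.maximum(disc, 0.0)
    return 0.5 * sites * (q - np.sqrt(disc))


def one_site_heats(n0: float, K: float, dH: float,
                   thermogram: ITCThermogram, offset: float = 0.0):
    """Predicted per-injection heats (microcal) of the one-site model."""
    if n0 <= 0 or K <= 0:
        raise DataError("n0 and K must be positive")
    dvf, x_t, m_t = _concentration_schedule(thermogram)
    x_b = bound_titrant(x_t, m_t, n0, K)
    v0_L = thermogram.cell_volume_uL * 1e-6
    q_content = dH * v0_L * x_b * UCAL_PER_KCAL
    heats = np.empty_like(q_content)
    prev = 0.0
    for i in range(len(heats)):
        heats[i] = (q_content[i] - prev
                    + dvf[i] * (q_content[i] + prev) / 2.0)
        prev = q_content[i]
    return heats + offset


def derive_thermo(K: float, dH: float, T: float) -> tuple[float, float]:
    """(dG, dS) from the binding constant and enthalpy at temperature T.

    dG = -R T ln K in kcal/mol; dS = (dH - dG)/T reported in cal/(mol K).
    """
    if K <= 0 or T <= 0:
        raise DataError("K and T must be positive")
    dG = -R_KCAL * T * np.log(K)
    dS = (dH - dG) / T * 1e3
    return float(dG), float(dS)


def fit_one_site(thermogram: ITCThermogram,
                 fit_offset: bool = True) -> OneSiteFit:
    """Nonlinear least squares for (n0, K, dH) and an optional constant
    per-injection dilution-heat offset.

    Starting values come from total-heat and inflection heuristics plus a
    coarse log-spaced scan over K.  A Wiseman c-value (n0 K M_cell) outside
    [1, 1e4] triggers a reliability warning, not a failure.
    """
    if thermogram.n_injections < 10:
        raise DataError("need at least 10 injections to fit")
    heats = thermogram.heats_ucal
    T = thermogram.temperature_K
    scale = float(np.abs(heats).max())
    if scale <= 0:
        return OneSiteFit(n0=np.nan, K=np.nan, dH=np.nan, dG=np.nan,
                          dS=np.nan, T=T, converged=False,
                          message="all heats are zero; nothing to fit")

    dvf, x_t, m_t = _concentration_schedule(thermogram)
    v0_L = thermogram.cell_volume_uL * 1e-6
    # enthalpy guess: early injections are nearly stoichiometric
    mol_inj = (thermogram.syringe_conc_uM * 1e-6
               * thermogram.injection_volumes_uL[0] * 1e-6)
    dh0 = heats[0] / (mol_inj * UCAL_PER_KCAL)
    # stoichiometry guess: molar ratio where cumulative heat reaches half
    cum = np.cumsum(heats)
    half = cum[-1] / 2.0
    i_half = int(np.searchsorted(np.abs(cum), abs(half)))
    i_half = min(max(i_half, 0), len(heats) - 1)
    n0_guess = max(x_t[i_half] / m_t[i_half], 1e-3)

    def model(idx, n0, logK, dH, offset=0.0):
        return one_site_heats(n0, 10.0 ** logK, dH, thermogram, offset)

    best = None
    idx = np.arange(len(heats), dtype=float)
    for logK0 in (4.0, 5.0, 6.0, 7.0, 8.0):
        p0 = [n0_guess, logK0, dh0] + ([0.0] if fit_offset else [])
        lo = [1e-6, 0.0, -np.inf] + ([-np.inf] if fit_offset else [])
        hi = [np.inf, 12.0, np.inf] + ([np.inf] if fit_offset else [])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(model, idx, heats, p0=p0,
                                       bounds=(lo, hi), maxfev=20_000)
            rss = float(((heats - model(idx, *popt)) ** 2).sum())
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        except (RuntimeError, ValueError):
            continue

    if best is None:
        return OneSiteFit(n0=np.nan, K=np.nan, dH=np.nan, dG=np.nan,
                          dS=np.nan, T=T, converged=False,
                          message="nonlinear fit did not converge")
    popt, pcov, rss = best
    n0 = float(popt[0])
    K = float(10.0 ** popt[1])
    dH = float(popt[2])
    offset = float(popt[3]) if fit_offset else 0.0
    dG, dS = derive_thermo(K, dH, T)
    c = n0 * K * thermogram.cell_conc_uM * 1e-6
    if not (1.0 <= c <= 1e4):
        warnings.warn(
            f"Wiseman c-value {c:.3g} outside [1, 1e4]; fitted K is "
            "poorly constrained", stacklevel=2)
    return OneSiteFit(n0=n0, K=K, dH=dH, dG=dG, dS=dS, T=T, offset=offset,
                      rss=rss, c_value=float(c), converged=True, pcov=pcov)


# -- I/O --------------------------------------------------------------------

_META_FIELDS = ("cell_volume_uL", "cell_conc_uM", "syringe_conc_uM",
                "temperature_K")


def write_itc(tg: ITCThermogram, path) -> None:
    """Tab-separated heats with a '# key: value' metadata header block."""
    with open(path, "w") as fh:
        for k in _META_FIELDS:
            fh.write(f"# {k}: {getattr(tg, k)!r}\n")
        fh.write("injection\tvolume_uL\theat_ucal\n")
        for i, (v, q) in enumerate(zip(tg.injection_volumes_uL,
                                       tg.heats_ucal), start=1):
            fh.write(f"{i}\t{v:.6g}\t{q:.10g}\n")


def read_itc(path) -> ITCThermogram:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val)
            body_start = i + 1
        else:
            break
    missing = set(_META_FIELDS) - set(meta)
    if missing:
        raise DataError(f"ITC file missing metadata: {sorted(missing)}")
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    if not {"volume_uL", "heat_ucal"}.issubset(df.columns):
        raise DataError("ITC table needs volume_uL and heat_ucal columns")
    return ITCThermogram(df["volume_uL"].to_numpy(),
                         df["heat_ucal"].to_numpy(), **meta)
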