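"""Synthetic data generators for every fitting stage.

Each generator is a pure function of its parameters and a seed, and its
noise-free output satisfies the corresponding stage model identically, so
generator/fitter round trips probe the fitters alone.  Default parameters
emulate the study designs the pipeline targets (plate-reader ThT assays of
amyloid fibrillation with and without nanoparticles, peptide-into-NP ITC
titrations, intravenous-dose plasma decay in mice); they are emulation
presets, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .itc import ITCThermogram, one_site_heats
from .pk import PKSeries
from .tht import SigmoidFit, ThTCurve, sigmoid_model

__all__ = [
    "ThTGroupParams", "gen_tht", "gen_itc", "gen_pk",
    "DEFAULT_THT_GROUPS", "ITC_PRESETS", "itc_preset_params",
]


# ---------------------------------------------------------------------------
# ThT curves
# ---------------------------------------------------------------------------


@dataclass
class ThTGroupParams:
    """True sigmoid parameters of a treatment group, expressed relative to a
    control: percent amplitude decrease, lag extension (h) and a
    multiplicative factor on the apparent rate."""

    amplitude_decrease_pct: float = 0.0
    lag_extension_h: float = 0.0
    rate_factor: float = 1.0


#: Emulates the study design: two chiral 3.3 nm NP groups with strong
#: amplitude suppression (60%/63%), one achiral control NP with weak (11%).
DEFAULT_THT_GROUPS = {
    "L3.3": ThTGroupParams(60.0, 6.0, 0.6),
    "D3.3": ThTGroupParams(63.0, 8.0, 0.5),
    "C3.5": ThTGroupParams(11.0, 1.0, 0.9),
}


def gen_tht(seed: int,
            grid: np.ndarray | None = None,
            control=(5.0, 95.0, 0.4, 18.0),
            groups: dict[str, ThTGroupParams] | None = None,
            noise_sd: float = 2.0,
            n_replicates: int = 3) -> list[ThTCurve]:
    """Control + treated ThT curve families with Gaussian plate-reader noise.

    ``control`` is (F0, A, k, t_half); treated groups are derived from it via
    :class:`ThTGroupParams`.  Labels: "control" plus the group names.
    """
    if noise_sd < 0:
        raise DataError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.arange(0.0, 48.0 + 1e-9, 0.5)
    if groups is None:
        groups = DEFAULT_THT_GROUPS
    f0, a_c, k_c, th_c = control
    lag_c = th_c - 2.0 / k_c
    params = {"control": (f0, a_c, k_c, th_c)}
    for name, g in groups.items():
        a = a_c * (1.0 - g.amplitude_decrease_pct / 100.0)
        k = k_c * g.rate_factor
        lag = lag_c + g.lag_extension_h
        params[name] = (f0, a, k, lag + 2.0 / k)
    curves = []
    for label, p in params.items():
        for rep in range(n_replicates):
            clean = sigmoid_model(grid, *p)
            noisy = clean + rng.normal(0.0, noise_sd, size=grid.shape) \
                if noise_sd > 0 else clean
            curves.append(ThTCurve(grid.copy(), noisy, replicate=rep,
                                   label=label))
    return curves


def true_tht_fit(control=(5.0, 95.0, 0.4, 18.0),
                 group: ThTGroupParams | None = None,
                 label: str = "") -> SigmoidFit:
    """The SigmoidFit a perfect fitter would return for a generated group."""
    f0, a_c, k_c, th_c = control
    if group is None:
        a, k, th = a_c, k_c, th_c
    else:
        a = a_c * (1.0 - group.amplitude_decrease_pct / 100.0)
        k = k_c * group.rate_factor
        th = (th_c - 2.0 / k_c) + group.lag_extension_h + 2.0 / k
    return SigmoidFit(f0=f0, amplitude=a, rate=k, t_half=th,
                      lag_time=th - 2.0 / k, rss=0.0, converged=True,
                      label=label)


# ---------------------------------------------------------------------------
# ITC thermograms
# ---------------------------------------------------------------------------

#: Well-conditioned default: c = n0 K M_cell ~ 50 with the standard
#: geometry (20 x 2 uL of 138 uM titrant into 200 uL of 1.5 uM cell).
DEFAULT_ITC_PARAMS = dict(n0=8.0, K=4.2e6, dH=-12.0)

#: Illustrative enantiomer presets: K chosen so that dG at 298.15 K equals
#: the published free-energy gap between the two chiral surfaces
#: (-6.7 vs -7.3 kcal/mol); dH set negative (bonding-dominated complexation).
ITC_PRESETS = {
    "L3.3-like": dict(dG=-6.7, dH=-9.0, n0=8.0),
    "D3.3-like": dict(dG=-7.3, dH=-9.5, n0=8.0),
}


def itc_preset_params(name: str, temperature_K: float = 298.15) -> dict:
    """(n0, K, dH) for a named preset, with K back-computed from dG."""
    from .itc import R_KCAL
    p = ITC_PRESETS[name]
    K = float(np.exp(-p["dG"] / (R_KCAL * temperature_K)))
    return dict(n0=p["n0"], K=K, dH=p["dH"])


def gen_itc(seed: int,
            n0: float = DEFAULT_ITC_PARAMS["n0"],
            K: float = DEFAULT_ITC_PARAMS["K"],
            dH: float = DEFAULT_ITC_PARAMS["dH"],
            n_injections: int = 20,
            injection_volume_uL: float = 2.0,
            cell_volume_uL: float = 200.0,
            cell_conc_uM: float = 1.5,
            syringe_conc_uM: float = 138.0,
            temperature_K: float = 298.15,
            noise_frac: float = 0.02) -> ITCThermogram:
    """One-site thermogram with proportional Gaussian noise.

    The default geometry delivers 40 uL of titrant in 2 uL steps into a
    200 uL cell.  ``noise_frac`` scales the per-injection Gaussian sd by the
    largest clean heat.
    """
    if noise_frac < 0:
        raise DataError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    vols = np.full(n_injections, injection_volume_uL)
    clean_tg = ITCThermogram(vols, np.zeros(n_injections),
                             cell_volume_uL=cell_volume_uL,
                             cell_conc_uM=cell_conc_uM,
                             syringe_conc_uM=syringe_conc_uM,
                             temperature_K=temperature_K)
    heats = one_site_heats(n0, K, dH, clean_tg)
    if noise_frac > 0:
        sd = noise_frac * np.abs(heats).max()
        heats = heats + rng.normal(0.0, sd, size=heats.shape)
    return ITCThermogram(vols, heats, cell_volume_uL=cell_volume_uL,
                         cell_conc_uM=cell_conc_uM,
                         syringe_conc_uM=syringe_conc_uM,
                         temperature_K=temperature_K)


# ---------------------------------------------------------------------------
# Plasma decay
# ---------------------------------------------------------------------------


def gen_pk(seed: int,
           intercept: float = 1.396,
           slope: float = 0.0211,
           grid=(6.0, 12.0, 24.0, 48.0),
           n_subjects: int = 4,
           noise_sd: float = 0.1,
           group: str = "") -> list[PKSeries]:
    """Plasma time courses C = 10^(a - b t) * exp(eps), eps ~ N(0, sd^2).

    Multiplicative lognormal noise keeps concentrations positive.  The
    default grid matches 6/12/24/48 h post-injection sampling with four
    animals per time point.
    """
    if noise_sd < 0:
        raise DataError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(grid, dtype=float)
    out = []
    for s in range(n_subjects):
        clean = 10.0 ** (intercept - slope * t)
        conc = clean * np.exp(rng.normal(0.0, noise_sd, size=t.shape)) \
            if noise_sd > 0 else clean
        out.append(PKSeries(t.copy(), conc, subject=f"s{s}", group=group))
    return out
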