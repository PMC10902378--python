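"""Apparent Michaelis–Menten kinetics from initial-rate data.

Rates follow v = kcat * [E] * S / (KM + S) with kcat in 1/min, enzyme
and substrate concentrations in uM, rates in uM/min.  The parameters
are "apparent" in the assay sense: measured under a fixed coupled
cofactor-recycling regime, not true single-substrate conditions.
Catalytic efficiency is reported as kcat/KM in 1/min/mM, the unit
kinetic tables in this field print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: NADPH molar absorptivity at 340 nm, L/mol/cm.
DEFAULT_MOLAR_ABSORPTIVITY = 6220.0
#: Optical path length of a 200 uL well in a standard microplate, cm.
DEFAULT_PATH_LENGTH = 0.56

# multiplicative perturbations of (kcat0, km0) tried in order on
# non-convergence
_RESTART_LADDER = ((1.0, 1.0), (0.3, 3.0), (3.0, 0.3), (10.0, 10.0), (0.1, 0.1))


def mm_rate(kcat: float, km: float, enzyme_conc: float, substrate) -> float | np.ndarray:
    """Michaelis–Menten initial rate (uM/min)."""
    if kcat <= 0 or km <= 0 or enzyme_conc <= 0:
        raise ValueError("kcat, km and enzyme_conc must be > 0")
    s = np.asarray(substrate, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate must be >= 0")
    v = kcat * enzyme_conc * s / (km + s)
    return float(v) if np.isscalar(substrate) else v


@dataclass(frozen=True)
class MMFit:
    """Fitted apparent Michaelis–Menten parameters and diagnostics."""

    kcat_app: float            # 1/min
    km_app: float              # uM
    kcat_se: float
    km_se: float
    efficiency: float          # kcat/KM, 1/min/mM
    enzyme_conc: float         # uM
    converged: bool
    saturated: bool            # False when max substrate < 2 * km_app
    n_points: int

    def __post_init__(self) -> None:
        if self.converged and (self.kcat_app <= 0 or self.km_app <= 0):
            raise ValueError("converged fit must have positive parameters")


def _initial_guess(s: np.ndarray, v: np.ndarray, enzyme_conc: float) -> tuple[float, float]:
    vmax0 = float(v.max())
    kcat0 = max(vmax0 / enzyme_conc, 1e-9)
    half = vmax0 / 2.0
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    km0 = float(s_sorted[len(s_sorted) // 2])
    above = np.nonzero(v_sorted >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        s0, s1 = s_sorted[i - 1], s_sorted[i]
        v0, v1 = v_sorted[i - 1], v_sorted[i]
        if v1 > v0:
            km0 = float(s0 + (half - v0) * (s1 - s0) / (v1 - v0))
    return kcat0, max(km0, 1e-9)


def fit_mm(rate_table, enzyme_conc: float, weighting: str = "none") -> MMFit:
    """Nonlinear least-squares fit of the Michaelis–Menten curve.

    ``rate_table`` is a DataFrame with columns ``substrate_uM`` and
    ``rate_uM_per_min`` (or a ``(substrate, rate)`` array pair).
    Initialization uses kcat0 = max rate / [E] and km0 at the
    interpolated half-maximal substrate; on non-convergence a ladder of
    perturbed starts is tried, and persistent failure yields a flagged
    (not raised) result.  Standard errors come from the curvature of
    the objective at the optimum; the saturation flag marks datasets
    whose largest substrate concentration stays below 2 * KM.
    """
    if isinstance(rate_table, pd.DataFrame):
        s = rate_table["substrate_uM"].to_numpy(dtype=float)
        v = rate_table["rate_uM_per_min"].to_numpy(dtype=float)
    else:
        s, v = (np.asarray(a, dtype=float) for a in rate_table)
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")
    if np.unique(s).size < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    if np.any(v < 0):
        raise ValueError("rates must be non-negative")
    if weighting not in ("none", "relative"):
        raise ValueError(f"unknown weighting scheme {weighting!r}")
    # relative-error weighting: sigma proportional to the observed rate
    sigma = np.maximum(v, v[v > 0].min() if np.any(v > 0) else 1.0) if weighting == "relative" else None

    def model(s_, kcat, km):
        return kcat * enzyme_conc * s_ / (km + s_)

    kcat0, km0 = _initial_guess(s, v, enzyme_conc)
    for f_kcat, f_km in _RESTART_LADDER:
        try:
            popt, pcov = curve_fit(
                model,
                s,
                v,
                p0=(kcat0 * f_kcat, km0 * f_km),
                sigma=sigma,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        kcat, km = (float(x) for x in popt)
        ses = np.sqrt(np.diag(pcov))
        if np.all(np.isfinite(popt)):
            return MMFit(
                kcat_app=kcat,
                km_app=km,
                kcat_se=float(ses[0]),
                km_se=float(ses[1]),
                efficiency=kcat / (km / 1000.0),
                enzyme_conc=float(enzyme_conc),
                converged=True,
                saturated=bool(s.max() >= 2.0 * km),
                n_points=int(s.size),
            )
    return MMFit(
        kcat_app=float("nan"), km_app=float("nan"), kcat_se=float("nan"),
        km_se=float("nan"), efficiency=float("nan"), enzyme_conc=float(enzyme_conc),
        converged=False, saturated=False, n_points=int(s.size),
    )


class RelativeKcat(NamedTuple):
    """Fold-improvement in turnover over a reference enzyme."""

    fold: float
    rounded: int


def relative_kcat(fit: MMFit | float, reference: MMFit | float) -> RelativeKcat:
    """kcat ratio versus a reference fit, with the integer-rounded fold."""
    kcat = fit.kcat_app if isinstance(fit, MMFit) else float(fit)
    ref = reference.kcat_app if isinstance(reference, MMFit) else float(reference)
    for value, label in ((kcat, "fit"), (ref, "reference")):
        if not math.isfinite(value):
            raise ValueError(f"{label} kcat is not finite (unconverged fit?)")
    if ref == 0:
        raise ValueError("reference kcat must be nonzero")
    fold = kcat / ref
    return RelativeKcat(fold=fold, rounded=int(round(fold)))


def slope_to_conc_rate(
    slope: float,
    molar_absorptivity: float = DEFAULT_MOLAR_ABSORPTIVITY,
    path_length: float = DEFAULT_PATH_LENGTH,
) -> float:
    """Beer–Lambert conversion of a dA/min slope to uM/min."""
    if molar_absorptivity <= 0 or path_length <= 0:
        raise ValueError("molar absorptivity and path length must be > 0")
    return slope / (molar_absorptivity * path_length) * 1e6


def slope_to_rate(
    slope: float,
    molar_absorptivity: float = DEFAULT_MOLAR_ABSORPTIVITY,
    path_length: float = DEFAULT_PATH_LENGTH,
    enzyme_conc: float = 1.0,
) -> float:
    """Per-enzyme turnover rate (1/min) from an absorbance slope."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")
    return slope_to_conc_rate(slope, molar_absorptivity, path_length) / enzyme_conc
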