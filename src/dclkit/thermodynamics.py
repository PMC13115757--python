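"""Van't Hoff analysis of association constants measured across temperature.

A linear van't Hoff plot, ln K vs 1/T, decomposes the complexation free
energy into enthalpic and entropic parts:

    ln K = -dH/(R T) + dS/R

so the slope gives dH = -slope * R and the intercept dS = intercept * R.
Conventions follow the formulation literature: dH in kJ mol^-1, dS in
J K^-1 mol^-1, dG(T) = dH - T dS / 1000 in kJ mol^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = ["R_GAS", "ThermoResult", "vant_hoff_fit", "predict_K"]

R_GAS = 8.314  # J K^-1 mol^-1


@dataclass
class ThermoResult:
    """Enthalpy/entropy decomposition from a linear van't Hoff fit."""

    dH: float  # kJ mol^-1
    dS: float  # J K^-1 mol^-1
    std_errors: dict = field(default_factory=dict)
    n_temperatures: int = 0
    residual_ss: float = math.nan
    r_squared: float | None = None

    def __post_init__(self):
        if self.n_temperatures < 2:
            raise ValidationError("van't Hoff analysis needs >= 2 temperatures")

    def dG_at(self, T: float) -> float:
        """Gibbs energy of complexation at T (kelvin), kJ mol^-1."""
        return self.dH - T * self.dS / 1000.0


def vant_hoff_fit(K_by_T, K_se=None) -> ThermoResult:
    """Least squares of ln K on 1/T, optionally weighted by K uncertainties.

    Parameters
    ----------
    K_by_T : mapping or pair of sequences
        Temperature (K) -> association constant.  Duplicate temperatures are
        collapsed by averaging ln K with a warning.  All K must be positive.
    K_se : mapping or sequence, optional
        Standard errors of the constants (same temperature keys/order).
        When given, the regression is weighted by 1/sigma_lnK^2 with
        sigma_lnK = SE_K / K — appropriate when the constants come from
        isotherm fits of very different precision (low-saturation
        temperatures produce much noisier K estimates).

    Returns
    -------
    ThermoResult
        dH (kJ mol^-1), dS (J K^-1 mol^-1) with regression standard errors
        propagated through the same unit conversions.
    """
    if hasattr(K_by_T, "items"):
        temps = np.array(sorted(K_by_T), dtype=float)
        Ks = np.array([K_by_T[t] for t in sorted(K_by_T)], dtype=float)
        if K_se is not None and hasattr(K_se, "items"):
            K_se = np.array([K_se[t] for t in sorted(K_by_T)], dtype=float)
    else:
        temps, Ks = (np.asarray(a, dtype=float) for a in K_by_T)
        order = np.argsort(temps)
        temps, Ks = temps[order], Ks[order]
        if K_se is not None:
            K_se = np.asarray(K_se, dtype=float)[order]
    if temps.size != Ks.size or temps.size < 2:
        raise ValidationError("need >= 2 (temperature, K) pairs")
    if np.any(temps <= 0):
        raise DomainError("temperatures must be positive kelvin")
    if np.any(Ks <= 0):
        raise DomainError("association constants must be positive")

    lnK = np.log(Ks)
    sig = None
    if K_se is not None:
        sig = np.asarray(K_se, dtype=float) / Ks
        if np.any(~np.isfinite(sig)) or np.any(sig <= 0):
            raise DomainError("K_se must be finite and positive")
    uniq, inv = np.unique(temps, return_inverse=True)
    if uniq.size != temps.size:
        warnings.warn("duplicate temperatures collapsed by averaging ln K")
        lnK = np.array([lnK[inv == i].mean() for i in range(uniq.size)])
        if sig is not None:
            sig = np.array([np.sqrt(np.mean(sig[inv == i] ** 2))
                            for i in range(uniq.size)])
        temps = uniq
    if temps.size < 2:
        raise ValidationError("fewer than 2 distinct temperatures after collapsing")

    x = 1.0 / temps
    if sig is None:
        res = stats.linregress(x, lnK)
        slope, intercept = res.slope, res.intercept
        se_slope = res.stderr or 0.0
        se_inter = res.intercept_stderr or 0.0
        r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else None
        pred = intercept + slope * x
        ss = float(np.sum((lnK - pred) ** 2))
    else:
        w = 1.0 / sig ** 2
        W = np.sum(w)
        xm = np.sum(w * x) / W
        ym = np.sum(w * lnK) / W
        sxx = np.sum(w * (x - xm) ** 2)
        slope = float(np.sum(w * (x - xm) * (lnK - ym)) / sxx)
        intercept = float(ym - slope * xm)
        pred = intercept + slope * x
        ss = float(np.sum(w * (lnK - pred) ** 2))
        # errors from the supplied measurement variances
        se_slope = math.sqrt(1.0 / sxx)
        se_inter = math.sqrt(1.0 / W + xm ** 2 / sxx)
        tot = float(np.sum(w * (lnK - ym) ** 2))
        r2 = 1.0 - ss / tot if tot > 0 else None

    dH = -slope * R_GAS / 1000.0  # kJ mol^-1
    dS = intercept * R_GAS        # J K^-1 mol^-1
    se = {"dH": se_slope * R_GAS / 1000.0, "dS": se_inter * R_GAS}
    return ThermoResult(dH=dH, dS=dS, std_errors=se,
                        n_temperatures=int(temps.size),
                        residual_ss=ss, r_squared=r2)


def predict_K(thermo: ThermoResult, T: float) -> float:
    """Association constant implied by (dH, dS) at temperature T (kelvin).

    Inverse of the van't Hoff relation: K = exp(-dG(T) / (R T)) with dG
    converted to J mol^-1.
    """
    if not T > 0:
        raise DomainError("temperature must be positive kelvin")
    dG_J = thermo.dG_at(T) * 1000.0
    return math.exp(-dG_J / (R_GAS * T))
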