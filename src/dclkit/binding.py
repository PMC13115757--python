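"""Host-guest binding equilibria probed by fluorescence anisotropy.

Inclusion of a fluorescent guest (here camptothecin, CPT) in a cyclodextrin
cavity slows its rotational diffusion, so the steady-state anisotropy r rises
from the free-guest value ``r_free`` toward ``r_inf`` (all guest complexed) as
host is titrated in.  Because the guest's lifetime and intensity are
essentially insensitive to complexation, the observed anisotropy is the
population-fraction-weighted average

    r([H]) = r_free + (r_inf - r_free) * f_bound([H])

with ``f_bound`` given by mass action.  Two stoichiometries are supported:

* 1:1 (guest:host), association constant K in dm^3 mol^-1; f = K[H]/(1+K[H])
  in the host-excess limit, or the exact root of the mass balance quadratic.
* 1:2 overall (guest sandwiched between two hosts), a single overall constant
  K in dm^6 mol^-2; f = K[H]^2/(1+K[H]^2), sigmoidal on a log-[H] axis.

The module provides species-fraction solvers, forward anisotropy prediction,
nonlinear and double-reciprocal (linearized) fitting, and information-
criterion stoichiometry selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .errors import DomainError, FitError, ValidationError

__all__ = [
    "MEDIA",
    "Titration",
    "BindingFit",
    "StoichiometryReport",
    "complex_fraction_1to1",
    "complex_fraction_1to2",
    "predict_anisotropy",
    "fit_binding_isotherm",
    "linearized_fit_1to1",
    "select_stoichiometry",
]

#: Recognized solution media (buffer, pH) labels.
MEDIA = ("citrate_pH3.5", "PBS_pH7.4", "water_pH7.4")

GAS_CONSTANT = 8.314  # J K^-1 mol^-1


@dataclass(frozen=True)
class Titration:
    """One anisotropy-vs-host-concentration series at fixed temperature.

    Parameters
    ----------
    host_conc : array-like
        Total host (cyclodextrin) concentrations, mol dm^-3.  Must be
        non-negative, strictly increasing and include 0.
    r_obs : array-like
        Observed steady-state anisotropies (dimensionless, L-format).
    temperature : float
        Sample temperature in kelvin.
    medium : str
        One of :data:`MEDIA`.
    guest_total : float
        Total guest (drug) concentration, mol dm^-3 (> 0).
    sigma_r : array-like, optional
        Per-point anisotropy standard deviations used as fit weights.
    """

    host_conc: np.ndarray
    r_obs: np.ndarray
    temperature: float
    medium: str
    guest_total: float
    sigma_r: np.ndarray | None = None

    def __post_init__(self):
        h = np.asarray(self.host_conc, dtype=float)
        r = np.asarray(self.r_obs, dtype=float)
        object.__setattr__(self, "host_conc", h)
        object.__setattr__(self, "r_obs", r)
        if h.ndim != 1 or h.shape != r.shape:
            raise ValidationError("host_conc and r_obs must be 1-D of equal length")
        if np.any(h < 0):
            raise ValidationError("host concentrations must be non-negative")
        if np.any(np.diff(h) <= 0):
            raise ValidationError("host concentrations must be strictly increasing")
        if h[0] != 0.0:
            raise ValidationError("titration must include a zero-host point")
        if np.any(r <= -0.2) or np.any(r > 0.4):
            raise ValidationError("anisotropy values outside (-0.2, 0.4]")
        if self.medium not in MEDIA:
            raise ValidationError(f"unknown medium {self.medium!r}; expected one of {MEDIA}")
        if not self.guest_total > 0:
            raise ValidationError("guest_total must be positive")
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive (kelvin)")
        if self.sigma_r is not None:
            s = np.asarray(self.sigma_r, dtype=float)
            object.__setattr__(self, "sigma_r", s)
            if s.shape != h.shape or np.any(s <= 0):
                raise ValidationError("sigma_r must match series length and be positive")

    def __len__(self):
        return self.host_conc.size


@dataclass
class BindingFit:
    """Fitted binding model for an anisotropy titration.

    ``K`` is in dm^3 mol^-1 for 1:1 stoichiometry and is the overall constant
    in dm^6 mol^-2 for 1:2; ``K_sqrt`` (dm^3 mol^-1) is defined only for 1:2.
    """

    stoichiometry: str  # "1:1" or "1:2"
    K: float
    r_free: float
    r_inf: float
    std_errors: dict = field(default_factory=dict)
    residual_ss: float = math.nan
    r_squared: float | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.stoichiometry not in ("1:1", "1:2"):
            raise DomainError("stoichiometry must be '1:1' or '1:2'")
        if not self.K > 0:
            raise DomainError("association constant must be positive")
        if self.r_inf <= self.r_free and "r_inf<=r_free" not in self.warnings:
            self.warnings.append("r_inf<=r_free")

    @property
    def K_sqrt(self) -> float:
        """Square root of the overall 1:2 constant, dm^3 mol^-1."""
        if self.stoichiometry != "1:2":
            raise DomainError("K_sqrt is defined only for 1:2 stoichiometry")
        return math.sqrt(self.K)


def complex_fraction_1to1(K, guest_total, host_total, mode="exact"):
    """Bound-guest fraction for a 1:1 host-guest equilibrium.

    ``exact`` solves the mass-balance quadratic
    ``K c^2 - (K G + K H + 1) c + K G H = 0`` for the complex concentration c
    and returns c/G; ``host_excess`` neglects host depletion and returns
    ``K H / (1 + K H)``.

    Parameters are the association constant K (dm^3 mol^-1) and total guest
    and host concentrations (mol dm^-3).  ``host_total`` may be an array.
    """
    K = float(K)
    guest_total = float(guest_total)
    host = np.asarray(host_total, dtype=float)
    scalar = host.ndim == 0
    host = np.atleast_1d(host)
    if K < 0 or guest_total < 0 or np.any(host < 0):
        raise DomainError("K and concentrations must be non-negative")
    if mode not in ("exact", "host_excess"):
        raise DomainError(f"unknown mode {mode!r}")

    if K == 0.0:
        frac = np.zeros_like(host)
    elif mode == "host_excess" or guest_total == 0.0:
        # guest at infinite dilution: depletion-free limit
        frac = K * host / (1.0 + K * host)
    else:
        G, H = guest_total, host
        b = K * (G + H) + 1.0
        disc = b * b - 4.0 * K * K * G * H
        if np.any(disc < 0):
            raise FitError("mass-balance discriminant negative: no physical root "
                           f"(K={K}, G={G}, H min/max={H.min()}/{H.max()})")
        # smaller root is the physical one (c <= min(G, H)); the
        # product form avoids cancellation when b^2 >> 4 K^2 G H
        c = 2.0 * K * G * H / (b + np.sqrt(disc))
        frac = c / G
        if np.any(frac < -1e-12) or np.any(frac > 1.0 + 1e-12):
            raise FitError("mass-balance root outside [0, guest_total]")
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac[0]) if scalar else frac


def complex_fraction_1to2(K_overall, host_total):
    """Bound fraction ``K H^2 / (1 + K H^2)`` for an overall 1:2 complex.

    Assumes host in large excess over guest.  ``K_overall`` is in
    dm^6 mol^-2; the curve is sigmoidal in [H] on a log axis with
    half-saturation at H = K_overall^(-1/2).
    """
    K = float(K_overall)
    host = np.asarray(host_total, dtype=float)
    scalar = host.ndim == 0
    host = np.atleast_1d(host)
    if K < 0 or np.any(host < 0):
        raise DomainError("K_overall and host_total must be non-negative")
    x = K * host * host
    frac = x / (1.0 + x)
    return float(frac[0]) if scalar else frac


def predict_anisotropy(fit: BindingFit, host_conc, guest_total=None):
    """Anisotropy predicted by a binding fit at the given host concentration.

    Uses population-fraction weighting ``r = r_free + (r_inf-r_free)*f_bound``
    (valid because guest lifetime/intensity are complexation-invariant).
    When ``guest_total`` is given the 1:1 fraction is solved exactly,
    otherwise the host-excess limit is used.
    """
    if fit.stoichiometry == "1:1":
        if guest_total is None:
            f = complex_fraction_1to1(fit.K, 0.0, host_conc, mode="host_excess")
        else:
            f = complex_fraction_1to1(fit.K, guest_total, host_conc, mode="exact")
    else:
        f = complex_fraction_1to2(fit.K, host_conc)
    return fit.r_free + (fit.r_inf - fit.r_free) * f


def _isotherm_r(host, K, r_free, r_inf, stoichiometry):
    if stoichiometry == "1:1":
        f = K * host / (1.0 + K * host)
    else:
        f = K * host * host / (1.0 + K * host * host)
    return r_free + (r_inf - r_free) * f


def _start_values(t: Titration, stoichiometry: str):
    """Deterministic data-driven starts: r_free from the zero-host point,
    r_inf 20% above the observed maximum, K from the linearized fit (1:1)
    or the half-rise concentration (1:2)."""
    r_free0 = float(t.r_obs[0])
    r_inf0 = float(np.max(t.r_obs)) * 1.2
    if r_inf0 <= r_free0:
        r_inf0 = r_free0 + 1e-3
    r_inf0 = min(r_inf0, 0.39)
    if stoichiometry == "1:1":
        try:
            lin = linearized_fit_1to1(t)
            K0 = lin.K
        except (DomainError, FitError, ValidationError):
            K0 = 1.0 / float(np.median(t.host_conc[1:]))
    else:
        # host conc at half the observed rise; K_overall = 1/H_half^2
        rise = t.r_obs - r_free0
        target = 0.5 * float(np.max(rise))
        idx = int(np.argmin(np.abs(rise - target)))
        h_half = float(t.host_conc[max(idx, 1)])
        K0 = 1.0 / (h_half * h_half)
    return max(K0, 1e-6), r_free0, r_inf0


def fit_binding_isotherm(titration: Titration, stoichiometry: str = "1:1") -> BindingFit:
    """Weighted nonlinear least-squares fit of (K, r_free, r_inf).

    Host depletion is neglected during fitting (host is in mM excess over a
    uM-scale guest in the emulated experiments); the exact solver remains
    available through :func:`complex_fraction_1to1` for checks.

    Raises :class:`FitError` (carrying the best iterate) on non-convergence;
    a fit whose optimum has ``r_inf <= r_free`` is returned with a warning
    flag rather than rejected.
    """
    if stoichiometry not in ("1:1", "1:2"):
        raise DomainError("stoichiometry must be '1:1' or '1:2'")
    if len(titration) < 5:
        raise ValidationError("need at least 5 host concentrations (including 0)")

    K0, r_free0, r_inf0 = _start_values(titration, stoichiometry)
    params = lmfit.Parameters()
    params.add("K", value=K0, min=1e-12)
    params.add("r_free", value=r_free0, min=-0.2, max=0.4)
    # 0.4 is the one-photon limit for steady-state anisotropy
    params.add("r_inf", value=r_inf0, min=-0.2, max=0.4)

    h, r = titration.host_conc, titration.r_obs
    w = 1.0 / titration.sigma_r if titration.sigma_r is not None else None

    def resid(p):
        d = _isotherm_r(h, p["K"].value, p["r_free"].value, p["r_inf"].value,
                        stoichiometry) - r
        return d * w if w is not None else d

    out = lmfit.minimize(resid, params, method="leastsq",
                         ftol=1e-10, xtol=1e-10, max_nfev=2000)
    ss = float(np.sum(np.asarray(out.residual) ** 2))
    stderr = {name: (out.params[name].stderr if out.params[name].stderr is not None
                     else math.nan)
              for name in ("K", "r_free", "r_inf")}
    flags = []
    if not out.success:
        raise FitError(f"isotherm fit did not converge: {out.message}",
                       best_fit=out)
    popt = out.params
    if popt["r_inf"].value <= popt["r_free"].value:
        flags.append("r_inf<=r_free")
    # near-flat series: amplitude indistinguishable from zero -> K unidentifiable
    amp = popt["r_inf"].value - popt["r_free"].value
    spread = float(np.ptp(r))
    if spread < 1e-12 or abs(amp) < 1e-6:
        flags.append("K_unidentifiable")
    tss = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss / tss if tss > 0 else None
    fit = BindingFit(
        stoichiometry=stoichiometry,
        K=max(popt["K"].value, 1e-12),
        r_free=popt["r_free"].value,
        r_inf=popt["r_inf"].value,
        std_errors=stderr,
        residual_ss=ss,
        r_squared=r2,
        warnings=flags,
    )
    return fit


def linearized_fit_1to1(titration: Titration) -> BindingFit:
    """Double-reciprocal (Benesi-Hildebrand style) 1:1 fit.

    Regresses ``1/(r - r_free)`` on ``1/[H]`` over nonzero-host points;
    ``K = intercept/slope`` and ``r_inf = r_free + 1/intercept``.  Points
    with ``r_obs <= r_free`` are excluded (recorded in the result warnings).
    The returned ``r_squared`` is that of the linear regression.
    """
    r_free = float(titration.r_obs[0])
    h = titration.host_conc[1:]
    r = titration.r_obs[1:]
    keep = r > r_free
    flags = []
    if not np.all(keep):
        flags.append(f"excluded {int((~keep).sum())} points with r_obs<=r_free")
    h, r = h[keep], r[keep]
    if h.size < 2:
        raise FitError("fewer than 2 usable points for the double-reciprocal fit")
    x = 1.0 / h
    y = 1.0 / (r - r_free)
    res = stats.linregress(x, y)
    if res.slope <= 0 or res.intercept <= 0:
        raise FitError("double-reciprocal regression gave non-physical "
                       f"slope={res.slope:.3g}, intercept={res.intercept:.3g}")
    K = res.intercept / res.slope
    r_inf = r_free + 1.0 / res.intercept
    pred = res.intercept + res.slope * x
    ss = float(np.sum((y - pred) ** 2))
    return BindingFit(
        stoichiometry="1:1",
        K=K,
        r_free=r_free,
        r_inf=r_inf,
        std_errors={"slope": res.stderr, "intercept": res.intercept_stderr},
        residual_ss=ss,
        r_squared=res.rvalue ** 2,
        warnings=flags,
    )


def _aicc(n: int, ss: float, k: int) -> float:
    """Small-sample-corrected Akaike criterion for a least-squares fit."""
    if ss <= 0:
        ss = 1e-300  # noiseless exact fit; keeps ordering meaningful
    aic = n * math.log(ss / n) + 2 * k
    corr = 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else math.inf
    return aic + corr


@dataclass
class StoichiometryReport:
    """Both candidate fits plus the AICc-based selection."""

    fit_1to1: BindingFit
    fit_1to2: BindingFit
    aicc_1to1: float
    aicc_1to2: float
    selected: str

    @property
    def delta_aicc(self) -> float:
        """AICc(rejected) - AICc(selected); the evidence gap."""
        return abs(self.aicc_1to1 - self.aicc_1to2)


def select_stoichiometry(titration: Titration) -> StoichiometryReport:
    """Fit both 1:1 and 1:2 models and pick by corrected AIC.

    Ties (and anything short of an advantage for 1:2) resolve to 1:1 on
    parsimony grounds.  Raises :class:`FitError` only if both fits fail.
    """
    errors = []
    fits = {}
    for stoich in ("1:1", "1:2"):
        try:
            fits[stoich] = fit_binding_isotherm(titration, stoich)
        except (FitError, DomainError) as exc:
            errors.append(f"{stoich}: {exc}")
    if not fits:
        raise FitError("both stoichiometry fits failed: " + "; ".join(errors))
    if len(fits) == 1:
        only = next(iter(fits))
        warnings.warn(f"only the {only} fit converged; selecting it by default")
        f = fits[only]
        a = _aicc(len(titration), f.residual_ss, 3)
        return StoichiometryReport(
            fit_1to1=fits.get("1:1", f), fit_1to2=fits.get("1:2", f),
            aicc_1to1=a if only == "1:1" else math.inf,
            aicc_1to2=a if only == "1:2" else math.inf,
            selected=only)
    n = len(titration)
    a11 = _aicc(n, fits["1:1"].residual_ss, 3)
    a12 = _aicc(n, fits["1:2"].residual_ss, 3)
    selected = "1:2" if a12 < a11 else "1:1"
    return StoichiometryReport(fit_1to1=fits["1:1"], fit_1to2=fits["1:2"],
                               aicc_1to1=a11, aicc_1to2=a12, selected=selected)
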