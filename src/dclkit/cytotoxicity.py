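"""MTT cytotoxicity analysis: survival normalization, four-parameter
logistic (4PL) dose-response fitting and replicate-level IC50 comparison.

Survival is the treated/control absorbance ratio in percent.  The
dose-response model on log-dose is

    S(d) = bottom + (top - bottom) / (1 + (d / IC50)^hill)

with the top fixed at 100% (controls define 100% by construction) and the
bottom floored at 0.  IC50 is the dose at the curve midpoint.  Because IC50s
are approximately log-normal across biological replicates, group comparison
uses Student's two-sample t-test on log IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .errors import DomainError, FitError, ValidationError

__all__ = [
    "DoseResponse",
    "IC50Fit",
    "TTestResult",
    "survival_percent",
    "fit_ic50",
    "compare_ic50",
]


@dataclass(frozen=True)
class DoseResponse:
    """Survival (%) replicate matrix across drug doses for one treatment."""

    dose: np.ndarray       # mol dm^-3, includes 0 (control)
    survival: np.ndarray   # shape (n_doses, n_replicates), percent
    cell_line: str = ""
    treatment: str = ""
    exposure_h: float = 48.0

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if s.ndim == 1:
            s = s[:, None]
        if d.ndim != 1 or s.shape[0] != d.size:
            raise ValidationError("survival must have one row per dose")
        if np.any(d < 0) or d[0] != 0.0 or np.any(np.diff(d) <= 0):
            raise ValidationError("dose must start at 0 and increase strictly")
        if np.any(s < 0):
            raise ValidationError("survival percentages must be non-negative")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "survival", s)

    @property
    def n_replicates(self) -> int:
        return self.survival.shape[1]

    def mean_survival(self) -> np.ndarray:
        return self.survival.mean(axis=1)


@dataclass
class IC50Fit:
    """4PL dose-response fit result."""

    ic50: float            # mol dm^-3
    hill: float
    bottom: float          # percent
    top: float             # percent (fixed at 100 by default)
    std_errors: dict = field(default_factory=dict)
    r_squared: float | None = None
    warnings: list = field(default_factory=list)


def survival_percent(abs_treated, abs_control):
    """Percent survival from blank-subtracted absorbances at 550 nm."""
    abs_treated = np.asarray(abs_treated, dtype=float)
    if not abs_control > 0:
        raise DomainError("control absorbance must be positive")
    if np.any(abs_treated < 0):
        raise DomainError("treated absorbance must be non-negative")
    out = 100.0 * abs_treated / abs_control
    return out if out.ndim else float(out)


def _fit_4pl_single(dose, survival, top=100.0):
    """4PL fit on one survival series; dose-0 control anchors the top."""
    pos = dose > 0
    d = dose[pos]
    s = survival[pos]
    mean_lo, mean_hi = float(np.min(s)), float(np.max(s))
    if not (mean_lo < 50.0 < max(mean_hi, top)):
        raise FitError("survival never crosses 50%: IC50 would be extrapolation")
    params = lmfit.Parameters()
    # log10 parameterization keeps IC50 positive and well-scaled
    i_half = int(np.argmin(np.abs(s - 50.0)))
    params.add("log_ic50", value=math.log10(d[i_half]),
               min=math.log10(d[0]) - 3, max=math.log10(d[-1]) + 3)
    params.add("hill", value=1.0, min=0.05, max=20.0)
    params.add("bottom", value=max(mean_lo, 0.0), min=0.0, max=top - 1e-6)

    logd = np.log10(d)

    def model(p):
        return (p["bottom"].value
                + (top - p["bottom"].value)
                / (1.0 + 10.0 ** (p["hill"].value * (logd - p["log_ic50"].value))))

    def resid(p):
        return model(p) - s

    out = lmfit.minimize(resid, params, method="leastsq",
                         ftol=1e-12, xtol=1e-12, max_nfev=5000)
    if not out.success:
        raise FitError(f"4PL fit did not converge: {out.message}", best_fit=out)
    p = out.params
    ic50 = 10.0 ** p["log_ic50"].value
    se = {}
    if p["log_ic50"].stderr is not None:
        se["ic50"] = ic50 * math.log(10) * p["log_ic50"].stderr
    se["hill"] = p["hill"].stderr if p["hill"].stderr is not None else math.nan
    se["bottom"] = (p["bottom"].stderr
                    if p["bottom"].stderr is not None else math.nan)
    ss = float(np.sum(np.asarray(out.residual) ** 2))
    tss = float(np.sum((s - s.mean()) ** 2))
    flags = []
    if np.any(np.diff(s) > 15.0):
        flags.append("non-monotone survival series")
    return IC50Fit(ic50=ic50, hill=p["hill"].value, bottom=p["bottom"].value,
                   top=top, std_errors=se,
                   r_squared=1.0 - ss / tss if tss > 0 else None,
                   warnings=flags)


def fit_ic50(dr: DoseResponse, per_replicate: bool = False, top: float = 100.0):
    """Fit the 4PL model and return the IC50.

    With ``per_replicate=False`` the replicate-mean survival is fitted and a
    single :class:`IC50Fit` returned.  With ``per_replicate=True`` each
    replicate column is fitted separately and a list of fits returned —
    the input for replicate-level t-tests.
    """
    if np.count_nonzero(dr.dose > 0) < 5:
        raise ValidationError("need at least 5 nonzero dose levels")
    if per_replicate:
        return [_fit_4pl_single(dr.dose, dr.survival[:, j], top=top)
                for j in range(dr.n_replicates)]
    return _fit_4pl_single(dr.dose, dr.mean_survival(), top=top)


@dataclass
class TTestResult:
    """Two-sample two-tailed Student's t-test on log IC50."""

    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_ic50(group_a, group_b, alpha: float = 0.05) -> TTestResult:
    """Student's (equal-variance) two-tailed t-test on log-transformed IC50s.

    Accepts sequences of IC50 values or of :class:`IC50Fit`.  Significance
    is declared at p < ``alpha`` (0.05 by default).  Two identical
    zero-variance groups give t = 0, p = 1.
    """
    def _values(g):
        vals = np.array([f.ic50 if isinstance(f, IC50Fit) else float(f)
                         for f in g], dtype=float)
        if vals.size < 2:
            raise ValidationError("need >= 2 IC50 replicates per group")
        if np.any(vals <= 0):
            raise DomainError("IC50 values must be positive")
        return np.log(vals)

    a, b = _values(group_a), _values(group_b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TTestResult(0.0, 1.0, False, alpha)
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()),
                           0.0, True, alpha)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), bool(p < alpha), alpha)
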