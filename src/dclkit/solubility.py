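"""Higuchi-Connors phase-solubility analysis for cyclodextrin complexation.

A phase-solubility diagram plots total dissolved drug against cyclodextrin
concentration.  A linear rise (A_L type) is diagnostic of 1:1 complexation
and yields the stability constant

    K = slope / (S0 * (1 - slope))

with S0 the intrinsic drug solubility (the diagram intercept).  Positive or
negative curvature (A_P / A_N) points to higher-order complexes or
nonideality; B-type diagrams (plateau then decline) indicate complexes of
limited solubility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "SolubilityDiagram",
    "DiagramClassification",
    "classify_diagram",
    "stability_constant",
    "solubility_enhancement",
]


@dataclass(frozen=True)
class SolubilityDiagram:
    """Total dissolved drug vs cyclodextrin concentration at fixed T, pH."""

    cd_conc: np.ndarray     # mol dm^-3, includes 0
    drug_total: np.ndarray  # mol dm^-3
    temperature: float = 298.15
    pH: float = 7.4

    def __post_init__(self):
        cd = np.asarray(self.cd_conc, dtype=float)
        s = np.asarray(self.drug_total, dtype=float)
        if cd.ndim != 1 or cd.shape != s.shape:
            raise ValidationError("cd_conc and drug_total must be 1-D, equal length")
        if cd[0] != 0.0 or np.any(np.diff(cd) <= 0):
            raise ValidationError("cd_conc must start at 0 and be strictly increasing")
        if np.any(s <= 0):
            raise ValidationError("drug_total must be positive")
        object.__setattr__(self, "cd_conc", cd)
        object.__setattr__(self, "drug_total", s)

    @property
    def S0(self) -> float:
        """Intrinsic solubility read off the zero-CD point, mol dm^-3."""
        return float(self.drug_total[0])

    def __len__(self):
        return self.cd_conc.size


@dataclass
class DiagramClassification:
    """Diagram type call plus the underlying linear fit."""

    diagram_type: str  # "A_L" | "A_P" | "A_N" | "B"
    slope: float
    intercept: float
    r_squared: float
    details: dict = field(default_factory=dict)


def classify_diagram(diagram: SolubilityDiagram,
                     r2_linear: float = 0.98,
                     curvature_alpha: float = 0.05) -> DiagramClassification:
    """Classify a phase-solubility diagram and return its linear fit.

    A post-peak decline (B-type, limited-solubility complex) is checked
    first; then a quadratic term is tested at ``curvature_alpha`` (A_P if
    significantly positive, A_N if negative) — curvature must be ruled out
    before the linear call, because a straight line fits a gentle parabola
    with R^2 well above any practical cutoff; finally A_L requires the
    linear fit to reach R^2 >= ``r2_linear`` with positive slope.
    """
    if len(diagram) < 4:
        raise ValidationError("need at least 4 points to classify a diagram")
    x, y = diagram.cd_conc, diagram.drug_total
    lin = stats.linregress(x, y)
    r2 = lin.rvalue ** 2

    # B-type: maximum reached before the end and a clear decline afterwards
    imax = int(np.argmax(y))
    if imax < len(y) - 2 and y[-1] < 0.95 * y[imax]:
        return DiagramClassification("B", lin.slope, lin.intercept, r2,
                                     {"plateau_index": imax})

    # quadratic curvature test: y = a + b x + c x^2, t-test on c
    X = np.column_stack([np.ones_like(x), x, x * x])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = len(y) - 3
    if dof > 0 and rank == 3:
        resid = y - X @ coef
        s2 = float(resid @ resid) / dof
        cov_cc = s2 * np.linalg.inv(X.T @ X)[2, 2]
        if cov_cc > 0:
            t_c = coef[2] / math.sqrt(cov_cc)
            p_c = 2 * stats.t.sf(abs(t_c), dof)
        else:
            # numerically exact fit: treat any real curvature as present
            p_c = 0.0 if abs(coef[2]) * x[-1] ** 2 > 1e-9 * float(np.max(y)) \
                else 1.0
    else:
        p_c = 1.0
    details = {"quad_coef": float(coef[2]), "quad_p": float(p_c)}
    if p_c < curvature_alpha and coef[2] > 0:
        return DiagramClassification("A_P", lin.slope, lin.intercept, r2, details)
    if p_c < curvature_alpha and coef[2] < 0:
        return DiagramClassification("A_N", lin.slope, lin.intercept, r2, details)

    if r2 >= r2_linear and lin.slope > 0:
        return DiagramClassification("A_L", lin.slope, lin.intercept, r2,
                                     details)
    # fall back to the best linear description
    label = "A_L" if lin.slope > 0 else "B"
    return DiagramClassification(label, lin.slope, lin.intercept, r2, details)


def stability_constant(slope: float, S0: float) -> float:
    """1:1 stability constant from an A_L diagram: K = slope/(S0(1-slope)).

    Valid only for 0 < slope < 1 (a slope >= 1 breaks the 1:1 assumption).
    Returns K in dm^3 mol^-1.
    """
    if not S0 > 0:
        raise DomainError("intrinsic solubility S0 must be positive")
    if slope <= 0:
        raise DomainError("A_L slope must be positive")
    if slope >= 1:
        raise DomainError("slope >= 1: the 1:1 phase-solubility formula is invalid")
    return slope / (S0 * (1.0 - slope))


def solubility_enhancement(S_with_cd: float, S_without: float,
                           rounding: str = "none") -> float:
    """Fold increase in drug solubility due to the cyclodextrin.

    ``rounding='nearest_int'`` mirrors how fold factors are quoted in
    formulation reports.
    """
    if not (S_with_cd > 0 and S_without > 0):
        raise DomainError("solubilities must be positive")
    ratio = S_with_cd / S_without
    if rounding == "nearest_int":
        return float(round(ratio))
    if rounding != "none":
        raise DomainError("rounding must be 'none' or 'nearest_int'")
    return ratio
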