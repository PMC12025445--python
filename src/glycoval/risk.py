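"""Misinterpretation-risk model for HbA1c results.

A measured HbA1c value is modelled as Normal(R + B, sigma), where R is the
patient's true value, B the analytical bias of the method, and sigma pools
the relevant dispersion terms as percent CVs of R:

* diagnosis:  sigma = (R/100) * sqrt(CVwl^2 + BVw^2 + BVb^2) — analytical
  imprecision plus within- and between-subject biological variation, because
  a diagnostic cut-off is interpreted against a population reference;
* monitoring: sigma = (R/100) * sqrt(2*(CVwl^2 + BVw^2)) — the difference of
  two serial results in the same subject, hence the factor 2 and no
  between-subject term.

Z-values against the decision limits L (rule-out) and U (rule-in), or
against the minimum therapy-changing difference Delta, convert to error
probabilities through the standard normal distribution.  Setting B = 0 and
CVwl = 0 gives the "ideal test" whose residual error is purely biological.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import UnitSystem

__all__ = [
    "RiskParams",
    "RiskCurve",
    "sigma_diagnosis",
    "sigma_monitoring",
    "prob_misdiagnosis_low",
    "prob_misdiagnosis_high",
    "prob_monitoring",
    "risk_curves",
    "individuality_index",
    "MisinterpretationRisk",
]


@dataclass(frozen=True)
class RiskParams:
    """Parameter set of the misinterpretation-risk model.

    B : analytical bias, absolute dataset units.
    cv_wl : within-laboratory CV, percent of R.
    bv_w, bv_b : within-/between-subject biological variation, percent.
    L, U : lower (rule-out) and upper (rule-in) decision limits.
    delta : minimum therapy-changing difference between serial results.
    """

    B: float
    cv_wl: float
    bv_w: float
    bv_b: float
    L: float
    U: float
    delta: float
    unit: UnitSystem

    def __post_init__(self):
        if not self.L < self.U:
            raise ValueError("L must be below U")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if min(self.cv_wl, self.bv_w, self.bv_b) < 0:
            raise ValueError("CV terms must be non-negative")

    @classmethod
    def ifcc_defaults(cls, B: float = -1.0, cv_wl: float = 2.1) -> "RiskParams":
        """IFCC defaults: BVw 1.6 %, BVb 7.1 %, L 39, U 47, Delta 5 mmol/mol.

        The default cv_wl is the within-laboratory CV of the concentration
        level nearest the decision region; the default B is the bias found
        at the decision limits.
        """
        return cls(B=B, cv_wl=cv_wl, bv_w=1.6, bv_b=7.1,
                   L=39.0, U=47.0, delta=5.0,
                   unit=UnitSystem.IFCC_MMOL_PER_MOL)

    @classmethod
    def ngsp_defaults(cls, B: float = -0.10, cv_wl: float = 1.26) -> "RiskParams":
        """NGSP defaults: BVw 1.2 %, BVb 5.4 %, L 5.7, U 6.4, Delta 0.46 %."""
        return cls(B=B, cv_wl=cv_wl, bv_w=1.2, bv_b=5.4,
                   L=5.7, U=6.4, delta=0.46,
                   unit=UnitSystem.NGSP_PERCENT)

    def ideal(self) -> "RiskParams":
        """The ideal test: zero analytical bias and imprecision."""
        return replace(self, B=0.0, cv_wl=0.0)


def sigma_diagnosis(R: float, params: RiskParams) -> float:
    """Pooled SD for diagnostic interpretation at true value R."""
    if not R > 0:
        raise ValueError("R must be positive")
    return (R / 100.0) * float(
        np.sqrt(params.cv_wl ** 2 + params.bv_w ** 2 + params.bv_b ** 2))


def sigma_monitoring(R: float, params: RiskParams) -> float:
    """Pooled SD of the difference of two serial results at true value R."""
    if not R > 0:
        raise ValueError("R must be positive")
    return (R / 100.0) * float(
        np.sqrt(2.0 * (params.cv_wl ** 2 + params.bv_w ** 2)))


def _upper_tail(z_num: float, sigma: float) -> float:
    # sigma = 0 collapses the Normal to a point mass: exact indicator
    if sigma == 0:
        return 0.0 if z_num > 0 else (1.0 if z_num < 0 else 0.5)
    return float(stats.norm.sf(z_num / sigma))


def prob_misdiagnosis_low(R: float, params: RiskParams) -> float:
    """P(measured value falls below L) for a patient with true value R.

    z = ((R + B) - L) / sigma_diagnosis; returns 1 - Phi(z).
    """
    return _upper_tail((R + params.B) - params.L, sigma_diagnosis(R, params))


def prob_misdiagnosis_high(R: float, params: RiskParams) -> float:
    """P(measured value exceeds U) for a patient with true value R.

    z = (U - (R + B)) / sigma_diagnosis; returns 1 - Phi(z).
    """
    return _upper_tail(params.U - (R + params.B), sigma_diagnosis(R, params))


def prob_monitoring(R: float, params: RiskParams) -> tuple[float, float]:
    """(P(undertreatment), P(overtreatment)) for serial monitoring at R.

    Undertreatment: a true change of Delta is masked, z = (Delta - B)/sigma.
    Overtreatment: no true change but the difference reads as one,
    z = (Delta + B)/sigma.  Both use the serial-difference SD.
    """
    sig = sigma_monitoring(R, params)
    return (_upper_tail(params.delta - params.B, sig),
            _upper_tail(params.delta + params.B, sig))


@dataclass(frozen=True)
class RiskCurve:
    """Probability curves over a grid of true values, test vs ideal test."""

    grid: np.ndarray
    p_underdx: np.ndarray
    p_overdx: np.ndarray
    p_undertx: np.ndarray
    p_overtx: np.ndarray
    p_underdx_ideal: np.ndarray
    p_overdx_ideal: np.ndarray
    p_undertx_ideal: np.ndarray
    p_overtx_ideal: np.ndarray
    params: RiskParams

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "R": self.grid,
            "p_underdx": self.p_underdx,
            "p_overdx": self.p_overdx,
            "p_undertx": self.p_undertx,
            "p_overtx": self.p_overtx,
            "p_underdx_ideal": self.p_underdx_ideal,
            "p_overdx_ideal": self.p_overdx_ideal,
            "p_undertx_ideal": self.p_undertx_ideal,
            "p_overtx_ideal": self.p_overtx_ideal,
        })


def default_grid(unit: UnitSystem) -> np.ndarray:
    if unit is UnitSystem.IFCC_MMOL_PER_MOL:
        return np.arange(30.0, 90.0 + 1e-9, 1.0)
    return np.round(np.arange(4.9, 10.4 + 1e-9, 0.1), 10)


def risk_curves(params: RiskParams,
                grid: Optional[Sequence[float]] = None) -> RiskCurve:
    """Evaluate all four misinterpretation probabilities over a grid of R.

    Curves are produced both for the supplied parameter set and for the
    ideal test (B = 0, cv_wl = 0), whose curves are by construction
    independent of the analytical terms.
    """
    g = np.asarray(grid, dtype=float) if grid is not None \
        else default_grid(params.unit)
    if np.any(g <= 0):
        raise ValueError("grid values must be positive")
    ideal = params.ideal()

    def curve(p):
        under = np.array([prob_misdiagnosis_low(r, p) for r in g])
        over = np.array([prob_misdiagnosis_high(r, p) for r in g])
        mon = np.array([prob_monitoring(r, p) for r in g])
        return under, over, mon[:, 0], mon[:, 1]

    u, o, ut, ot = curve(params)
    ui, oi, uti, oti = curve(ideal)
    return RiskCurve(grid=g, p_underdx=u, p_overdx=o, p_undertx=ut,
                     p_overtx=ot, p_underdx_ideal=ui, p_overdx_ideal=oi,
                     p_undertx_ideal=uti, p_overtx_ideal=oti, params=params)


def individuality_index(bv_w: float, bv_b: float) -> tuple[float, str]:
    """Harris individuality index BVw/BVb and its classification.

    A ratio at or below 0.6 marks a highly individual analyte, for which
    population reference intervals are insensitive and serial monitoring of
    the same subject is preferred.
    """
    if not bv_b > 0:
        raise ValueError("between-subject variation must be positive")
    idx = bv_w / bv_b
    return float(idx), ("highly_individual" if idx <= 0.6 else "not_individual")


class MisinterpretationRisk:
    """Risk model bound to a parameter set; statsmodels-flavoured facade."""

    def __init__(self, params: RiskParams):
        self.params = params

    def curves(self, grid: Optional[Sequence[float]] = None) -> RiskCurve:
        return risk_curves(self.params, grid)

    def at(self, R: float) -> dict:
        """All probabilities (test and ideal) at one true value, as fractions."""
        p, ideal = self.params, self.params.ideal()
        under_m, over_m = prob_monitoring(R, p)
        under_mi, over_mi = prob_monitoring(R, ideal)
        return {
            "R": R,
            "p_below_L": prob_misdiagnosis_low(R, p),
            "p_above_U": prob_misdiagnosis_high(R, p),
            "p_undertx": under_m,
            "p_overtx": over_m,
            "p_below_L_ideal": prob_misdiagnosis_low(R, ideal),
            "p_above_U_ideal": prob_misdiagnosis_high(R, ideal),
            "p_undertx_ideal": under_mi,
            "p_overtx_ideal": over_mi,
        }

    def summary(self) -> str:
        p = self.params
        at_u = self.at(p.U)
        at_l = self.at(p.L)
        idx, cls = individuality_index(p.bv_w, p.bv_b)
        sym = p.unit.symbol
        return "\n".join([
            "Misinterpretation-risk model",
            "=" * 60,
            f"unit {sym}; B {p.B}; CVwl {p.cv_wl}%; BVw {p.bv_w}%; "
            f"BVb {p.bv_b}%; L {p.L}; U {p.U}; Delta {p.delta}",
            f"P(read < L | R = U={p.U}):  {100*at_u['p_below_L']:.1f}%  "
            f"(ideal {100*at_u['p_below_L_ideal']:.1f}%)",
            f"P(read > U | R = L={p.L}):  {100*at_l['p_above_U']:.1f}%  "
            f"(ideal {100*at_l['p_above_U_ideal']:.1f}%)",
            f"individuality index      {idx:.2f} ({cls})",
        ])
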