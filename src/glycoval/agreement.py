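"""Agreement statistics: Bland-Altman with nonparametric limits and ATE
adjudication, Lin's concordance correlation coefficient, mountain plot.

The Bland-Altman analysis here uses empirical 2.5th/97.5th percentiles of
the candidate-minus-comparative differences as limits of agreement (rather
than mean +/- 1.96 SD), with exact binomial order-statistic confidence
intervals, and compares each limit against a symmetric allowable-total-error
band.  The verdict uses the percentile point estimates; CI-based verdicts
are reported alongside as informational.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .core import ATELimits, PairedDataset, UnitSystem

__all__ = [
    "percentile_with_ci",
    "BlandAltman",
    "BlandAltmanResults",
    "bland_altman",
    "CCCResult",
    "lin_ccc",
    "mountain_plot_points",
]


def hazen_percentile(values: np.ndarray, p: float) -> float:
    """Hazen order-statistic percentile: 1-based rank h = (p/100)*n + 0.5."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    h = p / 100.0 * n + 0.5
    if h <= 1:
        return float(v[0])
    if h >= n:
        return float(v[-1])
    lo = int(np.floor(h))
    frac = h - lo
    return float(v[lo - 1] + frac * (v[lo] - v[lo - 1]))


def percentile_with_ci(values, p: float, confidence: float = 0.95
                       ) -> tuple[float, float, float]:
    """Percentile estimate (Hazen rule) with an exact binomial order-statistic CI.

    The CI endpoints are the order statistics whose cumulative binomial
    coverage first reaches the requested confidence: the largest rank l with
    P(B < l) <= alpha/2 and the smallest rank u with P(B >= u) <= alpha/2,
    B ~ Binomial(n, p/100).  Ranks are clipped to the sample extremes when
    the tail mass cannot be achieved (small n, extreme p).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2:
        raise ValueError("percentile CI needs n >= 2")
    if not 0 < p < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    est = hazen_percentile(v, p)
    q = p / 100.0
    alpha = 1 - confidence
    # largest l in [1, n] with cdf(l-1) <= alpha/2
    l = int(stats.binom.ppf(alpha / 2, n, q))
    while l >= 1 and stats.binom.cdf(l - 1, n, q) > alpha / 2:
        l -= 1
    while l + 1 <= n and stats.binom.cdf(l, n, q) <= alpha / 2:
        l += 1
    l = max(l, 1)
    # smallest u in [1, n] with sf(u-1) <= alpha/2
    u = int(stats.binom.ppf(1 - alpha / 2, n, q)) + 1
    while u > 1 and stats.binom.sf(u - 2, n, q) <= alpha / 2:
        u -= 1
    while u <= n and stats.binom.sf(u - 1, n, q) > alpha / 2:
        u += 1
    u = min(u, n)
    if l > u:
        l, u = u, l
    return est, float(v[l - 1]), float(v[u - 1])


@dataclass
class BlandAltmanResults:
    """Bland-Altman difference analysis against an allowable-error band."""

    n: int
    unit: UnitSystem
    bias: float
    bias_ci: tuple[float, float]
    p2_5: float
    p2_5_ci: Optional[tuple[float, float]]
    p97_5: float
    p97_5_ci: Optional[tuple[float, float]]
    ate: Optional[ATELimits]
    lower_verdict: Optional[str]
    upper_verdict: Optional[str]
    lower_verdict_ci: Optional[str]
    upper_verdict_ci: Optional[str]
    prop_bias_slope: float
    prop_bias_slope_ci: tuple[float, float]
    differences: np.ndarray = field(repr=False, default=None)

    @property
    def passed(self) -> Optional[bool]:
        if self.lower_verdict is None:
            return None
        return self.lower_verdict == "passed" and self.upper_verdict == "passed"

    def mountain_points(self) -> np.ndarray:
        return mountain_plot_points(self.differences)

    def to_record(self) -> dict:
        return {
            "n": self.n,
            "unit": self.unit.value,
            "bias": self.bias,
            "bias_ci": list(self.bias_ci),
            "lower_p2_5": self.p2_5,
            "lower_p2_5_ci": list(self.p2_5_ci) if self.p2_5_ci else None,
            "upper_p97_5": self.p97_5,
            "upper_p97_5_ci": list(self.p97_5_ci) if self.p97_5_ci else None,
            "ate_half_width": self.ate.half_width if self.ate else None,
            "lower_verdict": self.lower_verdict,
            "upper_verdict": self.upper_verdict,
            "lower_verdict_ci": self.lower_verdict_ci,
            "upper_verdict_ci": self.upper_verdict_ci,
            "proportional_bias_slope": self.prop_bias_slope,
            "proportional_bias_slope_ci": list(self.prop_bias_slope_ci),
        }

    def summary(self) -> str:
        sym = self.unit.symbol
        out = [
            "Bland-Altman difference analysis (candidate - comparative)",
            "=" * 62,
            f"n                    {self.n}",
            f"bias                 {self.bias:.3f} {sym}  "
            f"(95% CI {self.bias_ci[0]:.3f} to {self.bias_ci[1]:.3f})",
            f"lower P2.5           {self.p2_5:.3f} {sym}",
            f"upper P97.5          {self.p97_5:.3f} {sym}",
        ]
        if self.ate is not None:
            out.append(f"ATE band             +/-{self.ate.half_width} {sym}  "
                       f"lower {self.lower_verdict}, upper {self.upper_verdict}")
        out.append(f"diff-vs-x OLS slope  {self.prop_bias_slope:.4f}  "
                   f"(95% CI {self.prop_bias_slope_ci[0]:.4f} to "
                   f"{self.prop_bias_slope_ci[1]:.4f})")
        return "\n".join(out)


class BlandAltman:
    """Bland-Altman model for a paired dataset, fitted against ATE limits."""

    def __init__(self, data: PairedDataset, ate: Optional[ATELimits] = None):
        if ate is not None and ate.unit is not data.unit:
            raise ValueError("ATE limits and dataset must share a unit system")
        self.data = data
        self.ate = ate

    def fit(self, confidence: float = 0.95) -> BlandAltmanResults:
        d = self.data.differences()
        n = len(d)
        bias = float(d.mean())
        se = d.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
        bias_ci = (bias - tcrit * se, bias + tcrit * se)

        if n >= 20:
            p2_5, lo2, hi2 = percentile_with_ci(d, 2.5, confidence)
            p97_5, lo97, hi97 = percentile_with_ci(d, 97.5, confidence)
            ci2: Optional[tuple[float, float]] = (lo2, hi2)
            ci97: Optional[tuple[float, float]] = (lo97, hi97)
        else:
            p2_5 = hazen_percentile(d, 2.5)
            p97_5 = hazen_percentile(d, 97.5)
            ci2 = ci97 = None

        lower_verdict = upper_verdict = None
        lower_verdict_ci = upper_verdict_ci = None
        if self.ate is not None:
            w = self.ate.half_width
            lower_verdict = "passed" if p2_5 >= -w else "failed"
            upper_verdict = "passed" if p97_5 <= w else "failed"
            if ci2 is not None:
                lower_verdict_ci = "passed" if ci2[0] >= -w else "failed"
                upper_verdict_ci = "passed" if ci97[1] <= w else "failed"

        # OLS of differences on comparative values flags proportional bias
        if np.all(self.data.x == self.data.x[0]):
            slope = 0.0
            slope_ci = (float("nan"), float("nan"))
        else:
            reg = stats.linregress(self.data.x, d)
            tslope = stats.t.ppf(0.5 + confidence / 2, n - 2)
            slope = float(reg.slope)
            slope_ci = (reg.slope - tslope * reg.stderr,
                        reg.slope + tslope * reg.stderr)

        return BlandAltmanResults(
            n=n, unit=self.data.unit, bias=bias, bias_ci=bias_ci,
            p2_5=p2_5, p2_5_ci=ci2, p97_5=p97_5, p97_5_ci=ci97,
            ate=self.ate,
            lower_verdict=lower_verdict, upper_verdict=upper_verdict,
            lower_verdict_ci=lower_verdict_ci, upper_verdict_ci=upper_verdict_ci,
            prop_bias_slope=slope,
            prop_bias_slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
            differences=d,
        )


def bland_altman(data: PairedDataset, ate: Optional[ATELimits] = None,
                 confidence: float = 0.95) -> BlandAltmanResults:
    """Functional wrapper around :class:`BlandAltman`."""
    return BlandAltman(data, ate).fit(confidence=confidence)


@dataclass(frozen=True)
class CCCResult:
    """Lin's concordance correlation coefficient decomposition."""

    pearson_rho: float
    c_b: float
    rho_c: float
    rho_c_ci: tuple[float, float]
    n: int
    strength: str

    def to_record(self) -> dict:
        return {
            "pearson_rho": self.pearson_rho,
            "c_b": self.c_b,
            "rho_c": self.rho_c,
            "rho_c_ci": list(self.rho_c_ci),
            "n": self.n,
            "strength": self.strength,
        }


def _ccc_strength(rho_c: float) -> str:
    if rho_c < 0.90:
        return "poor"
    if rho_c < 0.95:
        return "moderate"
    if rho_c <= 0.99:
        return "substantial"
    return "nearly_perfect"


def lin_ccc(data: PairedDataset, confidence: float = 0.95) -> CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) using population
    (1/n) moment estimators; the accuracy factor C_b = rho_c / rho measures
    how far the best-fit line deviates from the identity line, and the
    precision factor rho is the Pearson correlation.  The CI applies Lin's
    asymptotic variance to the z-transformed coefficient.
    """
    x, y = data.x, data.y
    n = data.n
    if n < 3:
        raise ValueError("CCC requires n >= 3")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    if sx2 == 0 or sy2 == 0:
        raise ValueError("constant series: CCC undefined")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    dmean = float(x.mean() - y.mean())
    rho_c = 2 * sxy / (sx2 + sy2 + dmean * dmean)
    rho = sxy / np.sqrt(sx2 * sy2)
    c_b = rho_c / rho

    if abs(rho_c) >= 1.0:
        ci = (rho_c, rho_c)
    else:
        u2 = dmean * dmean / np.sqrt(sx2 * sy2)  # squared scaled location shift
        z = np.arctanh(rho_c)
        one = 1 - rho_c ** 2
        var_z = (
            (1 - rho ** 2) * rho_c ** 2 / (one * rho ** 2)
            + 2 * rho_c ** 3 * (1 - rho_c) * u2 / (rho * one ** 2)
            - rho_c ** 4 * u2 ** 2 / (2 * rho ** 2 * one ** 2)
        ) / (n - 2)
        half = stats.norm.ppf(0.5 + confidence / 2) * np.sqrt(max(var_z, 0.0))
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))

    return CCCResult(pearson_rho=float(rho), c_b=float(c_b),
                     rho_c=float(rho_c), rho_c_ci=ci, n=n,
                     strength=_ccc_strength(rho_c))


def mountain_plot_points(differences) -> np.ndarray:
    """Folded empirical-percentile ("mountain") plot point set.

    Each sorted difference at empirical percentile p_i = 100*(i - 0.5)/n is
    mapped to min(p_i, 100 - p_i); the fold places the peak at the median
    and makes bias visible as a horizontal shift of the peak.  Returns an
    (n, 2) array of (difference, folded percentile) sorted by difference.
    """
    d = np.sort(np.asarray(differences, dtype=float))
    n = len(d)
    if n < 2:
        raise ValueError("mountain plot needs n >= 2")
    p = 100.0 * (np.arange(1, n + 1) - 0.5) / n
    folded = np.minimum(p, 100.0 - p)
    return np.column_stack([d, folded])
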