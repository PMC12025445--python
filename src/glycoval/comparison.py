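"""Passing-Bablok method-comparison regression and pre-screening tests.

Passing-Bablok regression estimates the line relating two measurement
procedures from the shifted median of all pairwise slopes, making no
assumption about the error distribution and tolerating measurement error in
both variables.  The companion Cusum test checks the linearity assumption,
Spearman's rho quantifies monotone association, and Tukey / Grubbs /
generalised-ESD screens flag candidate outliers (which are reported, never
silently removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from .core import PairedDataset, UnitSystem

__all__ = [
    "PassingBablok",
    "PassingBablokResults",
    "passing_bablok",
    "cusum_linearity",
    "spearman_with_ci",
    "OutlierReport",
    "tukey_outliers",
    "grubbs_two_sided",
    "generalized_esd",
    "normality_test",
]


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """All pairwise slopes S_ij (i<j) under the Passing-Bablok conventions.

    Identical points contribute nothing; vertical segments (x_i == x_j,
    y_i != y_j) contribute signed infinities that sort above/below all
    finite slopes; slopes exactly equal to -1 are excluded.  Returns the
    retained slopes (unsorted) and K, the count of slopes below -1.
    """
    n = len(x)
    iu, ju = np.triu_indices(n, k=1)
    dx = x[ju] - x[iu]
    dy = y[ju] - y[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dy / dx
    vertical = dx == 0
    s[vertical & (dy > 0)] = np.inf
    s[vertical & (dy < 0)] = -np.inf
    keep = ~(vertical & (dy == 0))  # drop identical points
    s = s[keep]
    s = s[s != -1.0]
    return s, int(np.sum(s < -1.0))


def _shifted_median(sorted_slopes: np.ndarray, k_offset: int) -> float:
    """Median of the slope set shifted by the count of slopes below -1."""
    n_s = len(sorted_slopes)
    if n_s == 0:
        raise ValueError("no valid pairwise slopes (degenerate data)")
    if n_s % 2 == 1:
        idx = (n_s - 1) // 2 + k_offset
        return float(sorted_slopes[min(idx, n_s - 1)])
    lo = min(n_s // 2 - 1 + k_offset, n_s - 1)
    hi = min(n_s // 2 + k_offset, n_s - 1)
    return float(0.5 * (sorted_slopes[lo] + sorted_slopes[hi]))


def _slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fast Passing-Bablok point estimate (no confidence intervals).

    Used inside bootstrap loops; must agree exactly with the full fit.
    """
    s, k = _pairwise_slopes(x, y)
    s.sort()
    b = _shifted_median(s, k)
    a = float(np.median(y - b * x))
    return b, a


@dataclass
class PassingBablokResults:
    """Fitted Passing-Bablok line with rank-based confidence intervals."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n_pairs: int
    confidence: float
    cusum_statistic: float
    cusum_p: float
    spearman_rho: float
    spearman_ci: tuple[float, float]
    unit: UnitSystem
    model: "PassingBablok" = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        """Candidate-method value the fitted line predicts at x."""
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_record(self) -> dict:
        rec = {
            "n": self.n_pairs,
            "unit": self.unit.value,
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "confidence": self.confidence,
            "cusum_p": self.cusum_p,
            "spearman_rho": self.spearman_rho,
            "spearman_ci": list(self.spearman_ci),
        }
        if self.model is not None:
            rec.update(self.model.data.summary_row())
        return rec

    def summary(self) -> str:
        lo, hi = self.slope_ci
        ilo, ihi = self.intercept_ci
        rlo, rhi = self.spearman_ci
        pct = 100 * self.confidence
        lines = [
            "Passing-Bablok regression",
            "=" * 60,
            f"n pairs            {self.n_pairs}",
            f"unit               {self.unit.symbol}",
            f"slope              {self.slope:.4f}  ({pct:.0f}% CI {lo:.4f} to {hi:.4f})",
            f"intercept          {self.intercept:.4f}  ({pct:.0f}% CI {ilo:.4f} to {ihi:.4f})",
            f"Cusum linearity p  {self.cusum_p:.4f}",
            f"Spearman rho       {self.spearman_rho:.4f}  (95% CI {rlo:.4f} to {rhi:.4f})",
        ]
        return "\n".join(lines)


class PassingBablok:
    """Passing-Bablok regression model for a paired-method dataset.

    Parameters
    ----------
    data : PairedDataset
        Comparative (x) vs candidate (y) measurements.

    Examples
    --------
    >>> import numpy as np
    >>> from glycoval import PairedDataset, UnitSystem, PassingBablok
    >>> d = PairedDataset(np.array([1., 2., 3.]), np.array([3., 5., 7.]),
    ...                   UnitSystem.IFCC_MMOL_PER_MOL)
    >>> res = PassingBablok(d).fit()
    >>> round(res.slope, 10), round(res.intercept, 10)
    (2.0, 1.0)
    """

    def __init__(self, data: PairedDataset):
        if data.n < 3:
            raise ValueError("Passing-Bablok regression requires n >= 3")
        if np.all(data.x == data.x[0]):
            raise ValueError("degenerate input: all comparative values equal")
        self.data = data

    @classmethod
    def from_dataframe(cls, frame, x_col="comparative", y_col="candidate",
                       unit=UnitSystem.IFCC_MMOL_PER_MOL) -> "PassingBablok":
        ds = PairedDataset(frame[x_col].to_numpy(dtype=float),
                           frame[y_col].to_numpy(dtype=float), unit)
        return cls(ds)

    def fit(self, confidence: float = 0.95) -> PassingBablokResults:
        x, y = self.data.x, self.data.y
        n = len(x)
        s, k = _pairwise_slopes(x, y)
        s.sort()
        n_s = len(s)
        b = _shifted_median(s, k)

        # rank-based CI from the null distribution of Kendall's statistic
        z = stats.norm.ppf(0.5 + confidence / 2)
        w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
        m1 = max(1, int(round((n_s - w) / 2.0)))
        m2 = n_s - m1 + 1
        lo_idx = min(max(m1 + k, 1), n_s) - 1
        hi_idx = min(max(m2 + k, 1), n_s) - 1
        b_lo, b_hi = float(s[lo_idx]), float(s[hi_idx])

        a = float(np.median(y - b * x))
        # intercept bounds pair with the opposite slope bounds
        a_lo = float(np.median(y - b_hi * x))
        a_hi = float(np.median(y - b_lo * x))

        stat, p = cusum_linearity(self.data, slope=b, intercept=a)
        try:
            rho, r_lo, r_hi = spearman_with_ci(self.data)
        except ValueError:
            # n < 4 or constant series: regression stands, correlation doesn't
            rho = r_lo = r_hi = float("nan")
        return PassingBablokResults(
            slope=b, slope_ci=(b_lo, b_hi),
            intercept=a, intercept_ci=(a_lo, a_hi),
            n_pairs=n, confidence=confidence,
            cusum_statistic=stat, cusum_p=p,
            spearman_rho=rho, spearman_ci=(r_lo, r_hi),
            unit=self.data.unit, model=self,
        )


def passing_bablok(data: PairedDataset,
                   confidence: float = 0.95) -> PassingBablokResults:
    """Functional wrapper around :class:`PassingBablok`."""
    return PassingBablok(data).fit(confidence=confidence)


def cusum_linearity(data: PairedDataset, slope: float,
                    intercept: float) -> tuple[float, float]:
    """Cusum test of the linearity assumption of Passing-Bablok regression.

    Each point is scored by its side of the fitted line
    (+sqrt(n_below/n_above) above, -sqrt(n_above/n_below) below, 0 on the
    line); scores are accumulated in order of ascending projection onto the
    line and the maximum |cusum|, scaled by sqrt(n_above + n_below), is
    referred to the asymptotic Kolmogorov-Smirnov distribution.

    Returns
    -------
    (statistic, p_value)
    """
    x, y = data.x, data.y
    resid = y - (intercept + slope * x)
    above = resid > 0
    below = resid < 0
    n_above = int(above.sum())
    n_below = int(below.sum())
    if n_above == 0 or n_below == 0:
        # all points on (or on one side of) the line: no linearity signal
        return 0.0, 1.0
    scores = np.zeros(len(x))
    scores[above] = np.sqrt(n_below / n_above)
    scores[below] = -np.sqrt(n_above / n_below)
    # order by projection onto the fitted line; ties broken by x then index
    if slope != 0:
        key = x + y / slope
    else:
        key = x
    order = np.lexsort((np.arange(len(x)), x, key))
    cusum = np.cumsum(scores[order])
    stat = float(np.max(np.abs(cusum)) / np.sqrt(n_above + n_below))
    p = float(special.kolmogorov(stat))  # 2*sum (-1)^(k-1) exp(-2 k^2 stat^2)
    return stat, min(max(p, 0.0), 1.0)


def spearman_with_ci(data: PairedDataset,
                     confidence: float = 0.95) -> tuple[float, float, float]:
    """Spearman rank correlation with a Fisher-z confidence interval.

    The CI uses the large-sample standard error 1/sqrt(n-3) on the
    z-transformed coefficient.
    """
    x, y = data.x, data.y
    if len(x) < 4:
        raise ValueError("Spearman CI requires n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant series: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return rho, rho, rho
    z = np.arctanh(rho)
    half = stats.norm.ppf(0.5 + confidence / 2) / np.sqrt(len(x) - 3)
    return rho, float(np.tanh(z - half)), float(np.tanh(z + half))


@dataclass(frozen=True)
class OutlierReport:
    """Result of one outlier screen; indices refer to the input order."""

    method: str
    flagged_indices: tuple[int, ...]
    statistics: dict

    @property
    def any_flagged(self) -> bool:
        return len(self.flagged_indices) > 0


def tukey_outliers(values, k: float = 1.5) -> OutlierReport:
    """Flag values outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR]."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("Tukey fences need n >= 4")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flagged = tuple(int(i) for i in np.nonzero((v < lo) | (v > hi))[0])
    return OutlierReport("tukey", flagged,
                         {"q1": float(q1), "q3": float(q3),
                          "fence_low": float(lo), "fence_high": float(hi)})


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_two_sided(values, alpha: float = 0.05) -> OutlierReport:
    """Two-sided Grubbs test flagging at most the single most extreme value."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        return OutlierReport("grubbs", (), {"G": 0.0, "critical": float("nan")})
    dev = np.abs(v - v.mean())
    g = float(dev.max() / sd)
    crit = float(_grubbs_critical(n, alpha))
    flagged = (int(np.argmax(dev)),) if g > crit else ()
    return OutlierReport("grubbs", flagged, {"G": g, "critical": crit})


def generalized_esd(values, max_k: int = 5,
                    alpha: float = 0.05) -> OutlierReport:
    """Generalised extreme studentised deviate test for up to max_k outliers.

    Iterates the Grubbs statistic on successively reduced samples; the
    declared outlier count is the largest step i whose statistic R_i exceeds
    its critical value lambda_i.  With max_k = 1 this reduces to Grubbs.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("gESD needs n >= 3")
    if max_k < 1 or max_k > n - 2:
        raise ValueError("max_k must be in [1, n-2]")
    remaining = list(range(n))
    removal_order: list[int] = []
    r_stats: list[float] = []
    lambdas: list[float] = []
    for i in range(1, max_k + 1):
        sub = v[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        r_stats.append(float(dev[j] / sd))
        n_i = n - i + 1
        p = 1 - alpha / (2 * n_i)
        t = stats.t.ppf(p, n_i - 2)
        lambdas.append(float((n_i - 1) * t /
                             np.sqrt((n_i - 2 + t * t) * n_i)))
        removal_order.append(remaining.pop(j))
    n_out = 0
    for i, (r, lam) in enumerate(zip(r_stats, lambdas), start=1):
        if r > lam:
            n_out = i
    flagged = tuple(sorted(removal_order[:n_out]))
    return OutlierReport("gesd", flagged,
                         {"R": r_stats, "lambda": lambdas,
                          "removal_order": removal_order})


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p). Degenerate input is an error."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.all(v == v[0]):
        raise ValueError("normality undefined for constant data")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)
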