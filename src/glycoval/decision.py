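"""Bootstrap estimation of candidate-method bias at medical decision limits.

The candidate method's expected reading at each clinical decision value is
the full-data Passing-Bablok line evaluated at that value; uncertainty comes
from case resampling (specimen pairs drawn with replacement), refitting the
line per replicate and taking percentile confidence intervals over the
replicate predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .comparison import _slope_intercept
from .core import DecisionLimits, PairedDataset

__all__ = ["DecisionBiasRow", "bootstrap_decision_bias"]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class DecisionBiasRow:
    """Modelled candidate value, bias and relative bias at one decision limit."""

    limit: float
    modeled: float
    modeled_ci: tuple[float, float]
    difference: float
    difference_ci: tuple[float, float]
    relative_difference: float  # percent of the limit
    relative_difference_ci: tuple[float, float]

    def to_record(self) -> dict:
        return {
            "limit": self.limit,
            "modeled": self.modeled,
            "modeled_ci": list(self.modeled_ci),
            "difference": self.difference,
            "difference_ci": list(self.difference_ci),
            "relative_difference_pct": self.relative_difference,
            "relative_difference_pct_ci": list(self.relative_difference_ci),
        }


def _resample_fit(x: np.ndarray, y: np.ndarray,
                  rng: np.random.Generator) -> tuple[float, float]:
    n = len(x)
    for _ in range(_MAX_REDRAWS):
        idx = rng.integers(0, n, size=n)
        xb = x[idx]
        if np.all(xb == xb[0]):
            continue  # degenerate replicate: redraw
        return _slope_intercept(xb, y[idx])
    raise RuntimeError("could not draw a non-degenerate bootstrap replicate")


def bootstrap_decision_bias(
    data: PairedDataset,
    limits: DecisionLimits | Sequence[float],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    confidence: float = 0.95,
) -> list[DecisionBiasRow]:
    """Bias of the candidate method at clinical decision limits.

    Parameters
    ----------
    data : PairedDataset
        Paired comparative/candidate measurements (n >= 20).
    limits : DecisionLimits or sequence of float
        Decision values in dataset units; values outside the observed
        comparative range trigger an extrapolation warning.
    n_boot : int
        Bootstrap replicates (pair resampling with refit per replicate).
    seed : int, optional
        Seeds the resampling stream; fixed seed gives bit-identical output
        within this implementation.

    Returns
    -------
    list of DecisionBiasRow, one per limit, ordered as given.
    """
    if data.n < 20:
        raise ValueError("decision-bias bootstrap requires n >= 20")
    limit_values = limits.limits if isinstance(limits, DecisionLimits) \
        else tuple(float(v) for v in limits)
    x, y = data.x, data.y
    lo, hi = x.min(), x.max()
    for v in limit_values:
        if v < lo or v > hi:
            warnings.warn(
                f"decision limit {v} outside observed comparative range "
                f"[{lo}, {hi}]; prediction is an extrapolation",
                stacklevel=2,
            )

    slope, intercept = _slope_intercept(x, y)
    point = intercept + slope * np.asarray(limit_values)

    rng = np.random.default_rng(seed)
    preds = np.empty((n_boot, len(limit_values)))
    for b in range(n_boot):
        sb, ab = _resample_fit(x, y, rng)
        preds[b] = ab + sb * np.asarray(limit_values)

    alpha = 100 * (1 - confidence)
    lo_p, hi_p = np.percentile(preds, [alpha / 2, 100 - alpha / 2], axis=0)

    rows = []
    for j, lim in enumerate(limit_values):
        diff = point[j] - lim
        rows.append(DecisionBiasRow(
            limit=lim,
            modeled=float(point[j]),
            modeled_ci=(float(lo_p[j]), float(hi_p[j])),
            difference=float(diff),
            difference_ci=(float(lo_p[j] - lim), float(hi_p[j] - lim)),
            relative_difference=float(100 * diff / lim),
            relative_difference_ci=(float(100 * (lo_p[j] - lim) / lim),
                                    float(100 * (hi_p[j] - lim) / lim)),
        ))
    return rows
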