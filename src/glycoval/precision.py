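"""Single-site precision analysis on a day x replicate nested design.

A level is measured R times per run, one run per day, over D days (the
default design is 5x5).  A one-way nested ANOVA with day as the grouping
factor separates repeatability (within-run) variance from between-day
variance; within-laboratory variance is their sum.  All components are
reported as percent coefficients of variation of the grand mean.  The
single-run-per-day design collapses run and day, so the between component
is labelled "day".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import UnitSystem

__all__ = [
    "ReplicateDesign",
    "PrecisionResult",
    "ep05_variance_components",
    "EP05Precision",
    "precision_report",
    "IFCC_CV_CRITERION",
]

#: performance criterion for HbA1c: within-laboratory CV below 2.5 %
IFCC_CV_CRITERION = 2.5


@dataclass(frozen=True)
class ReplicateDesign:
    """One concentration level: values indexed by (day, replicate)."""

    level_label: str
    values: np.ndarray  # shape (days, replicates)
    unit: Optional[UnitSystem] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("replicate table must be 2-D (days x replicates)")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 days and 2 replicates per day")
        if np.any(~np.isfinite(v)):
            raise ValueError(
                "incomplete design: missing cells are out of contract; "
                "supply a complete balanced day x replicate table"
            )
        if np.any(v <= 0):
            raise ValueError("replicate values must be strictly positive")
        object.__setattr__(self, "values", v)

    @property
    def days(self) -> int:
        return self.values.shape[0]

    @property
    def replicates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, level_label: str,
                   unit: Optional[UnitSystem] = None) -> "ReplicateDesign":
        """Build from a long table with columns day, replicate, value."""
        sub = frame[frame["level"] == level_label] if "level" in frame else frame
        pivot = sub.pivot(index="day", columns="replicate", values="value")
        if pivot.isna().any().any():
            raise ValueError(f"level {level_label!r}: unbalanced or incomplete "
                             "day x replicate design")
        return cls(level_label, pivot.to_numpy(), unit=unit)


@dataclass(frozen=True)
class PrecisionResult:
    """Variance components of one level as percent CVs of the grand mean."""

    level_label: str
    mean: float
    cv_r: float
    cv_day: float
    cv_wl: float
    days: int
    replicates: int
    unit: Optional[UnitSystem] = None
    var_r: float = 0.0
    var_day: float = 0.0        # truncated at zero
    var_day_raw: float = 0.0    # moment estimate before truncation

    def to_record(self) -> dict:
        return {
            "level": self.level_label,
            "unit": self.unit.value if self.unit else None,
            "mean": self.mean,
            "cv_r_pct": self.cv_r,
            "cv_day_pct": self.cv_day,
            "cv_wl_pct": self.cv_wl,
            "design": f"{self.days}x{self.replicates}",
        }


def ep05_variance_components(design: ReplicateDesign) -> PrecisionResult:
    """Nested one-way ANOVA variance components for one level.

    V_r = MS_within; V_day = max(0, (MS_between - MS_within)/R) — a negative
    moment estimate is truncated to zero; V_wl = V_r + V_day.  CVs are
    100*sqrt(V)/grand-mean.
    """
    v = design.values
    d, r = v.shape
    grand = v.mean()
    day_means = v.mean(axis=1)
    ms_within = float(np.sum((v - day_means[:, None]) ** 2) / (d * (r - 1)))
    ms_between = float(r * np.sum((day_means - grand) ** 2) / (d - 1))
    v_r = ms_within
    v_day_raw = (ms_between - ms_within) / r
    v_day = max(0.0, v_day_raw)
    v_wl = v_r + v_day
    return PrecisionResult(
        level_label=design.level_label,
        mean=float(grand),
        cv_r=float(100 * np.sqrt(v_r) / grand),
        cv_day=float(100 * np.sqrt(v_day) / grand),
        cv_wl=float(100 * np.sqrt(v_wl) / grand),
        days=d, replicates=r, unit=design.unit,
        var_r=float(v_r), var_day=float(v_day),
        var_day_raw=float(v_day_raw),
    )


class EP05Precision:
    """Precision model over one or more concentration levels.

    fit() runs the nested ANOVA per level and returns the list of
    :class:`PrecisionResult`; :func:`precision_report` assembles them into a
    report record with the 2.5 % CV performance flag.
    """

    def __init__(self, designs: Sequence[ReplicateDesign]):
        if len(designs) == 0:
            raise ValueError("at least one level required")
        self.designs = list(designs)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   unit: Optional[UnitSystem] = None) -> "EP05Precision":
        if "level" not in frame:
            raise ValueError("long table must have a 'level' column")
        labels = list(dict.fromkeys(frame["level"]))
        return cls([ReplicateDesign.from_frame(frame, lab, unit=unit)
                    for lab in labels])

    def fit(self) -> list[PrecisionResult]:
        return [ep05_variance_components(d) for d in self.designs]


def precision_report(results: Sequence[PrecisionResult],
                     criterion: float = IFCC_CV_CRITERION) -> dict:
    """Table-shaped precision record with per-level performance flags."""
    if len(results) == 0:
        raise ValueError("empty result list")
    rows = []
    for res in results:
        rec = res.to_record()
        rec["flag"] = ("within criterion" if res.cv_wl <= criterion
                       else "exceeds criterion")
        rows.append(rec)
    return {"criterion_cv_wl_pct": criterion, "levels": rows}
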