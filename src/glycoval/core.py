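"""Shared domain types, unit systems and delimited-file I/O.

HbA1c is reported on two scales: NGSP percent and IFCC mmol/mol, linked by
the NGSP master equation ``NGSP% = 0.09148 * IFCC + 2.152``.  Every dataset
in this package carries an explicit :class:`UnitSystem` label so that
decision limits, allowable-error bands and biological-variation constants
are always interpreted on the right scale.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("glycoval")

#: NGSP master equation constants (NGSP% = slope * IFCC + intercept).
NGSP_MASTER_SLOPE = 0.09148
NGSP_MASTER_INTERCEPT = 2.152


class UnitSystem(enum.Enum):
    """Reporting scale for HbA1c values."""

    NGSP_PERCENT = "NGSP_percent"
    IFCC_MMOL_PER_MOL = "IFCC_mmol_per_mol"

    @property
    def symbol(self) -> str:
        return "%" if self is UnitSystem.NGSP_PERCENT else "mmol/mol"

    #: plausible assay range used to sanity-check decision limits
    @property
    def plausible_range(self) -> tuple[float, float]:
        if self is UnitSystem.NGSP_PERCENT:
            return (3.0, 20.0)
        return (10.0, 200.0)


def ifcc_to_ngsp(value):
    """Convert IFCC mmol/mol to NGSP percent via the master equation.

    Accepts scalars or arrays; negative input raises ``ValueError``.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("IFCC HbA1c values must be non-negative")
    out = NGSP_MASTER_SLOPE * arr + NGSP_MASTER_INTERCEPT
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def ngsp_to_ifcc(value):
    """Inverse master equation: NGSP percent to IFCC mmol/mol."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("NGSP HbA1c values must be non-negative")
    out = (arr - NGSP_MASTER_INTERCEPT) / NGSP_MASTER_SLOPE
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def ifcc_diff_to_ngsp_diff(delta):
    """Convert an IFCC *difference* to an NGSP difference.

    Only the slope applies: the master-equation intercept cancels in
    differences, so the map is exactly linear (f(a+b) = f(a)+f(b)).
    """
    arr = np.asarray(delta, dtype=float)
    out = NGSP_MASTER_SLOPE * arr
    return float(out) if np.isscalar(delta) or arr.ndim == 0 else out


def ngsp_diff_to_ifcc_diff(delta):
    """Inverse of :func:`ifcc_diff_to_ngsp_diff`."""
    arr = np.asarray(delta, dtype=float)
    out = arr / NGSP_MASTER_SLOPE
    return float(out) if np.isscalar(delta) or arr.ndim == 0 else out


@dataclass(frozen=True)
class PairedDataset:
    """Specimen-wise paired measurements: comparative (x) vs candidate (y).

    Parameters
    ----------
    x, y : array-like
        Comparative-method and candidate-method values, same unit.
    unit : UnitSystem
        Reporting scale shared by both columns.
    ids : sequence of str, optional
        Specimen labels.
    """

    x: np.ndarray
    y: np.ndarray
    unit: UnitSystem
    ids: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("all paired values must be finite")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("HbA1c values must be strictly positive")
        if self.ids is not None and len(self.ids) != len(x):
            raise ValueError("ids length must match number of pairs")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.ids is not None:
            object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))

    @property
    def n(self) -> int:
        return len(self.x)

    def differences(self) -> np.ndarray:
        """Candidate minus comparative, the sign convention used throughout."""
        return self.y - self.x

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"comparative": self.x, "candidate": self.y})
        if self.ids is not None:
            frame.insert(0, "specimen", list(self.ids))
        return frame

    def summary_row(self) -> dict:
        """Median and observed range per method (Table-2-style metadata)."""
        return {
            "n": self.n,
            "unit": self.unit.value,
            "comparative_median": float(np.median(self.x)),
            "comparative_range": (float(self.x.min()), float(self.x.max())),
            "candidate_median": float(np.median(self.y)),
            "candidate_range": (float(self.y.min()), float(self.y.max())),
        }


@dataclass(frozen=True)
class DecisionLimits:
    """Ordered clinical decision values (e.g. 39/47/53/64 mmol/mol)."""

    limits: tuple[float, ...]
    unit: UnitSystem

    def __post_init__(self):
        vals = tuple(float(v) for v in self.limits)
        if len(vals) == 0:
            raise ValueError("at least one decision limit required")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("decision limits must be strictly increasing")
        lo, hi = self.unit.plausible_range
        if vals[0] < lo or vals[-1] > hi:
            raise ValueError(
                f"decision limits outside plausible {self.unit.symbol} "
                f"range [{lo}, {hi}]"
            )
        object.__setattr__(self, "limits", vals)

    @classmethod
    def ifcc_defaults(cls) -> "DecisionLimits":
        return cls((39.0, 47.0, 53.0, 64.0), UnitSystem.IFCC_MMOL_PER_MOL)

    @classmethod
    def ngsp_defaults(cls) -> "DecisionLimits":
        return cls((5.7, 6.4, 7.0, 8.0), UnitSystem.NGSP_PERCENT)


@dataclass(frozen=True)
class ATELimits:
    """Symmetric allowable-total-error band, ±half_width in dataset units."""

    half_width: float
    unit: UnitSystem

    def __post_init__(self):
        if not self.half_width > 0:
            raise ValueError("ATE half-width must be positive")

    @classmethod
    def default_for(cls, unit: UnitSystem) -> "ATELimits":
        # ±5 mmol/mol, the minimum difference prompting a therapy change,
        # and its NGSP equivalent ±0.46 %
        if unit is UnitSystem.IFCC_MMOL_PER_MOL:
            return cls(5.0, unit)
        return cls(0.46, unit)


_COMMA_DECIMAL = re.compile(r"^\s*-?\d+,\d+\s*$")


def read_paired_table(
    path,
    x_col: str = "comparative",
    y_col: str = "candidate",
    unit: UnitSystem = UnitSystem.IFCC_MMOL_PER_MOL,
    id_col: Optional[str] = None,
) -> PairedDataset:
    """Read a delimited paired-measurement table into a :class:`PairedDataset`.

    The delimiter (comma or tab) is auto-detected; decimal commas are
    rejected with the offending line number.  Rows with missing or
    non-numeric entries in either value column are dropped with a logged
    count; fewer than three usable rows is an error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path.name}: empty file")
    header = lines[0]
    sep = "\t" if "\t" in header else (";" if ";" in header else ",")
    n_fields = len(header.split(sep))
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        if sep != "," :
            for cell in cells:
                if _COMMA_DECIMAL.match(cell):
                    raise ValueError(
                        f"{path.name}, line {lineno}: decimal comma in "
                        f"{cell!r}; use decimal points"
                    )
        elif len(cells) > n_fields:
            # a decimal comma in a comma-delimited file shows up as extra fields
            raise ValueError(
                f"{path.name}, line {lineno}: mixed decimal separators "
                "(extra comma-separated fields); use decimal points"
            )
    frame = pd.read_csv(path, sep=sep)
    for col in (x_col, y_col):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    numeric = frame[[x_col, y_col]].apply(pd.to_numeric, errors="coerce")
    mask = numeric.notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.warning("%s: dropped %d row(s) with missing/non-numeric values",
                       path.name, dropped)
    kept = numeric[mask]
    if len(kept) < 3:
        raise ValueError(
            f"{path.name}: only {len(kept)} usable rows; need at least 3"
        )
    ids = None
    if id_col is not None and id_col in frame.columns:
        ids = tuple(str(v) for v in frame.loc[mask, id_col])
    return PairedDataset(kept[x_col].to_numpy(), kept[y_col].to_numpy(),
                         unit=unit, ids=ids)


def read_replicate_table(
    path,
    level_col: str = "level",
    day_col: str = "day",
    rep_col: str = "replicate",
    value_col: str = "value",
) -> pd.DataFrame:
    """Read a long-format replicate table (level x day x replicate)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    for col in (level_col, day_col, rep_col, value_col):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {Path(path).name}")
    out = frame[[level_col, day_col, rep_col, value_col]].copy()
    out.columns = ["level", "day", "replicate", "value"]
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    if out["value"].isna().any():
        raise ValueError("non-numeric replicate values present")
    return out
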