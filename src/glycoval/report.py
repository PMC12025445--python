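"""Assembly of stage outputs into a validation report.

The report mirrors the canonical lab-validation table set: method
comparison (Passing-Bablok), concordance, Bland-Altman with ATE verdicts,
decision-limit bias, precision, and the misinterpretation-risk summary.
Numbers are kept at full precision in JSON; the markdown rendering applies
display rounding (one decimal for NGSP, whole numbers for IFCC levels).
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .agreement import BlandAltman, lin_ccc
from .comparison import (PassingBablok, generalized_esd, grubbs_two_sided,
                         normality_test, tukey_outliers)
from .core import ATELimits, DecisionLimits, PairedDataset
from .decision import bootstrap_decision_bias
from .precision import PrecisionResult, precision_report
from .risk import MisinterpretationRisk, RiskParams, individuality_index


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_compare(
    data: PairedDataset,
    ate: Optional[ATELimits] = None,
    decision_limits: Optional[DecisionLimits | Sequence[float]] = None,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> dict:
    """Full comparison pipeline: screens, regression, agreement, decision bias.

    Outlier screens run first and are reported only — points are never
    removed.  Stage failures are re-raised with the stage name attached.
    """
    report: dict = {
        "software": {"name": "glycoval", "version": __version__},
        "dataset": data.summary_row(),
        "seed": seed,
    }

    diffs = data.differences()
    stage = "outlier screens"
    try:
        report["screens"] = {
            "tukey": tukey_outliers(diffs).__dict__ | {},
            "grubbs": grubbs_two_sided(diffs).__dict__ | {},
            "gesd": generalized_esd(diffs, max_k=min(5, data.n - 2)).__dict__ | {},
        }
        for rec in report["screens"].values():
            rec["flagged_indices"] = list(rec["flagged_indices"])
        try:
            w, p = normality_test(diffs)
            report["normality"] = {"shapiro_W": w, "p": p}
        except ValueError:
            # constant differences (perfect agreement): test undefined
            report["normality"] = None

        stage = "method comparison"
        pb = PassingBablok(data).fit()
        report["comparison"] = pb.to_record()

        stage = "agreement"
        ba = BlandAltman(data, ate).fit()
        report["bland_altman"] = ba.to_record()
        report["ccc"] = lin_ccc(data).to_record()
        report["mountain_points"] = ba.mountain_points().tolist()

        if decision_limits is not None:
            stage = "decision bias"
            rows = bootstrap_decision_bias(data, decision_limits,
                                           n_boot=n_boot, seed=seed)
            report["decision_bias"] = {
                "n_boot": n_boot, "seed": seed,
                "rows": [r.to_record() for r in rows],
            }
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    return _jsonable(report)


def run_precision(results: Sequence[PrecisionResult]) -> dict:
    return _jsonable(precision_report(results))


def run_risk(params: RiskParams, grid=None) -> dict:
    """Risk summary: probabilities at both decision limits plus full curves."""
    model = MisinterpretationRisk(params)
    curve = model.curves(grid)
    idx, cls = individuality_index(params.bv_w, params.bv_b)
    summary = {
        "params": {
            "unit": params.unit.value, "B": params.B, "cv_wl": params.cv_wl,
            "bv_w": params.bv_w, "bv_b": params.bv_b,
            "L": params.L, "U": params.U, "delta": params.delta,
        },
        "at_limits": {
            "p_below_L_at_U_pct": 100 * model.at(params.U)["p_below_L"],
            "p_below_L_at_U_ideal_pct":
                100 * model.at(params.U)["p_below_L_ideal"],
            "p_above_U_at_L_pct": 100 * model.at(params.L)["p_above_U"],
            "p_above_U_at_L_ideal_pct":
                100 * model.at(params.L)["p_above_U_ideal"],
        },
        "individuality_index": idx,
        "individuality_class": cls,
        "curve": curve.to_frame().to_dict(orient="list"),
    }
    return _jsonable(summary)


def to_json(report: dict, path=None, indent: int = 2) -> str:
    text = json.dumps(report, indent=indent)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def markdown_comparison_table(report: dict) -> str:
    """Markdown rendering of the comparison/agreement sections."""
    comp = report.get("comparison", {})
    ba = report.get("bland_altman", {})
    ccc = report.get("ccc", {})
    lines = [
        "| quantity | estimate | 95% CI |",
        "|---|---|---|",
        f"| slope | {comp.get('slope', float('nan')):.2f} | "
        f"{comp.get('slope_ci', [float('nan')]*2)[0]:.2f} to "
        f"{comp.get('slope_ci', [float('nan')]*2)[1]:.2f} |",
        f"| intercept | {comp.get('intercept', float('nan')):.2f} | "
        f"{comp.get('intercept_ci', [float('nan')]*2)[0]:.2f} to "
        f"{comp.get('intercept_ci', [float('nan')]*2)[1]:.2f} |",
        f"| Cusum p | {comp.get('cusum_p', float('nan')):.2f} | |",
        f"| Spearman rho | {comp.get('spearman_rho', float('nan')):.3f} | "
        f"{comp.get('spearman_ci', [float('nan')]*2)[0]:.3f} to "
        f"{comp.get('spearman_ci', [float('nan')]*2)[1]:.3f} |",
        f"| bias | {ba.get('bias', float('nan')):.2f} | "
        f"{ba.get('bias_ci', [float('nan')]*2)[0]:.2f} to "
        f"{ba.get('bias_ci', [float('nan')]*2)[1]:.2f} |",
        f"| rho_c | {ccc.get('rho_c', float('nan')):.4f} | "
        f"{ccc.get('rho_c_ci', [float('nan')]*2)[0]:.4f} to "
        f"{ccc.get('rho_c_ci', [float('nan')]*2)[1]:.4f} |",
    ]
    return "\n".join(lines)
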