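"""Confusion matrices, screening metrics, and diagnosis bookkeeping.

Positive means malignant / "requires further investigation" throughout.  The
five screening metrics are overall accuracy, sensitivity, specificity,
positive predictive value and negative predictive value; integer-percent
renderings use half-up rounding (so 78.5% prints as 79).  A metric whose
denominator is zero is reported as explicitly undefined (None), never as a
silently propagated NaN.

Exact Clopper-Pearson 95% confidence intervals are available as an extension
beyond the headline point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .simulate import ABSENT, BENIGN, MALIGNANT, NONDIAGNOSTIC

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; positive = malignant."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigurationError("confusion-matrix cells must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.tp, self.tn, self.fp, self.fn)


def percent_half_up(value: float) -> int:
    """Round 100*value to an integer percent, halves away from zero."""
    return int(Decimal(100 * value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScreeningMetrics:
    """The five screening proportions plus integer-percent renderings.

    A proportion is None when its denominator is zero (e.g. PPV with no
    positive calls); its percent rendering is then None as well.
    """

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    @property
    def rounded_percent(self) -> Dict[str, Optional[int]]:
        return {
            name: (None if v is None else percent_half_up(v))
            for name, v in zip(METRIC_NAMES, self.as_tuple())
        }

    def as_tuple(self):
        return (self.accuracy, self.sensitivity, self.specificity, self.ppv, self.npv)

    def to_dict(self) -> dict:
        d = {name: v for name, v in zip(METRIC_NAMES, self.as_tuple())}
        d["rounded_percent"] = self.rounded_percent
        return d


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(cm: ConfusionMatrix) -> ScreeningMetrics:
    """Accuracy, sensitivity, specificity, PPV, NPV from a confusion matrix."""
    if cm.total == 0:
        raise ConfigurationError("empty confusion matrix")
    return ScreeningMetrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


def metric_confidence_intervals(
    cm: ConfusionMatrix, level: float = 0.95
) -> Dict[str, Optional[Tuple[float, float]]]:
    """Exact (Clopper-Pearson) binomial CIs for each metric.

    Extension beyond the headline point estimates; each metric is treated as
    a binomial proportion successes/denominator.
    """
    pairs = {
        "accuracy": (cm.tp + cm.tn, cm.total),
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    alpha = 1 - level
    out: Dict[str, Optional[Tuple[float, float]]] = {}
    for name, (k, n) in pairs.items():
        if n == 0:
            out[name] = None
            continue
        lo = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        hi = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
        out[name] = (float(lo), float(hi))
    return out


def resolve_diagnosis(cytology_label: str, histopath_label: str = ABSENT) -> Optional[str]:
    """Definitive diagnosis: histopathology overrides cytology.

    Returns ``benign``/``malignant``, or None when the lesion must be
    excluded (non-diagnostic cytology with no histopathology).
    """
    valid_cyt = {BENIGN, MALIGNANT, NONDIAGNOSTIC}
    valid_hist = {BENIGN, MALIGNANT, ABSENT}
    if cytology_label not in valid_cyt:
        raise ConfigurationError(f"unknown cytology label {cytology_label!r}")
    if histopath_label not in valid_hist:
        raise ConfigurationError(f"unknown histopathology label {histopath_label!r}")
    if histopath_label != ABSENT:
        return histopath_label
    if cytology_label == NONDIAGNOSTIC:
        return None
    return cytology_label


def per_type_report(
    predictions: pd.DataFrame, records: pd.DataFrame
) -> pd.DataFrame:
    """Per tumor-type breakdown of predictions, with class and grand totals.

    ``predictions`` needs a ``label`` column (benign vs flagged) indexed by
    lesion_id; ``records`` needs ``tumor_type`` and a resolved ``diagnosis``
    per lesion.  The output has one row per (diagnosis class, tumor type)
    plus a total row per class and a grand-total row, with columns
    ``pred_benign``, ``pred_malignant``, ``total``.
    """
    missing = predictions.index.difference(records.index)
    if len(missing):
        raise ConfigurationError(f"predictions without records: {list(missing)[:5]}")
    if len(predictions) == 0:
        return pd.DataFrame(
            [{"class": "all", "tumor_type": "Grand total", "pred_benign": 0,
              "pred_malignant": 0, "total": 0}]
        )
    df = records.loc[predictions.index, ["tumor_type", "diagnosis"]].copy()
    if df["diagnosis"].isna().any():
        raise ConfigurationError("every prediction needs a resolved diagnosis")
    df["pred"] = np.where(
        predictions["label"].to_numpy() == "benign", "pred_benign", "pred_malignant"
    )

    rows = []
    for cls in (BENIGN, MALIGNANT):
        sub = df[df["diagnosis"] == cls]
        ct = (
            sub.groupby(["tumor_type", "pred"], sort=True).size().unstack(fill_value=0)
            if len(sub)
            else pd.DataFrame()
        )
        for col in ("pred_benign", "pred_malignant"):
            if col not in ct.columns:
                ct[col] = 0
        for tumor_type, r in ct.iterrows():
            rows.append(
                {
                    "class": cls,
                    "tumor_type": tumor_type,
                    "pred_benign": int(r["pred_benign"]),
                    "pred_malignant": int(r["pred_malignant"]),
                }
            )
        rows.append(
            {
                "class": cls,
                "tumor_type": f"{cls.capitalize()} total",
                "pred_benign": int(ct["pred_benign"].sum()) if len(ct) else 0,
                "pred_malignant": int(ct["pred_malignant"].sum()) if len(ct) else 0,
            }
        )
    rows.append(
        {
            "class": "all",
            "tumor_type": "Grand total",
            "pred_benign": int((df["pred"] == "pred_benign").sum()),
            "pred_malignant": int((df["pred"] == "pred_malignant").sum()),
        }
    )
    out = pd.DataFrame(rows)
    out["total"] = out["pred_benign"] + out["pred_malignant"]
    return out


def report_confusion(report: pd.DataFrame) -> ConfusionMatrix:
    """Collapse a per-type report back into a confusion matrix."""
    ben = report[(report["class"] == BENIGN) & report["tumor_type"].str.endswith("total")]
    mal = report[(report["class"] == MALIGNANT) & report["tumor_type"].str.endswith("total")]
    if len(ben) != 1 or len(mal) != 1:
        raise ConfigurationError("report lacks class total rows")
    return ConfusionMatrix(
        tp=int(mal["pred_malignant"].iloc[0]),
        tn=int(ben["pred_benign"].iloc[0]),
        fp=int(ben["pred_malignant"].iloc[0]),
        fn=int(mal["pred_benign"].iloc[0]),
    )


def report_correct_total(report: pd.DataFrame) -> int:
    """Correctly classified lesions: benign predicted benign + malignant flagged."""
    cm = report_confusion(report)
    return cm.tp + cm.tn


def render_report_text(report: pd.DataFrame) -> str:
    """Human-readable fixed-width rendering of a per-type report."""
    lines = [f"{'Class':<10} {'Tumor type':<40} {'Benign':>7} {'Malig.':>7} {'Total':>7}"]
    for _, r in report.iterrows():
        lines.append(
            f"{r['class']:<10} {r['tumor_type']:<40} "
            f"{r['pred_benign']:>7d} {r['pred_malignant']:>7d} {r['total']:>7d}"
        )
    return "\n".join(lines)
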