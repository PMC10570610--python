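"""Thermal-decay feature extraction, normalization, and selection.

Each lesion contributes a pair of curves (mass site, adjacent healthy site).
Per-site features summarise the heat-cool signal; differential features
subtract the healthy-site value from the mass-site value, cancelling patient-
and site-level effects (resting temperature, perfusion baseline, probe
contact).  The catalog is a documented stand-in for the device's proprietary
feature set and is extensible through :data:`FEATURE_REGISTRY`.

Cohort-level normalization is z-scoring with statistics frozen from the
training table, so a validated model is a genuinely fixed algorithm.
Selection ranks features by absolute point-biserial correlation with the
benign/malignant label and keeps the top three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, QualityError
from .scan import PHASE_COOLING, PHASE_HEATING, TemperatureCurve
from .simulate import CohortDataset, MALIGNANT

LOG_EPS = 1e-6  # kelvin floor inside the log-linear decay fit
MIN_COOLING_FRAMES = 10

LABEL_COL = "diagnosis"
DOG_COL = "dog_id"
TYPE_COL = "tumor_type"
META_COLS = (LABEL_COL, DOG_COL, TYPE_COL)


@dataclass(frozen=True)
class DecayFit:
    """Exponential cooling fit T(t) - T_base = amplitude * exp(-rate * t).

    ``rate`` is 1/s, ``amplitude`` kelvin, ``r_squared`` the goodness of the
    log-linear fit; ``flagged`` marks degenerate fits (no excess temperature).
    """

    rate: float
    amplitude: float
    r_squared: float
    flagged: bool = False


def fit_decay(curve: TemperatureCurve, baseline: Optional[float] = None) -> DecayFit:
    """Log-linear least-squares fit of the cooling segment.

    Ordinary least squares of ``ln(max(T(t) - T_base, eps))`` against time
    since cooling onset, restricted to frames with positive excess
    temperature; ``rate`` is minus the slope and ``amplitude`` the
    exponentiated intercept.  The floor ``eps`` only guards the logarithm —
    any frame with excess above it is fitted exactly, so a noiseless
    exponential is recovered to machine precision.  A curve that never
    exceeds baseline during cooling yields a flagged zero-rate fit rather
    than an error.
    """
    t_base = curve.baseline_temp() if baseline is None else baseline
    t_cool, v_cool = curve.phase_values(PHASE_COOLING)
    if len(t_cool) < MIN_COOLING_FRAMES:
        raise QualityError(f"need >= {MIN_COOLING_FRAMES} cooling frames, got {len(t_cool)}")
    excess = v_cool - t_base
    usable = excess > 0
    if usable.sum() < 2:
        return DecayFit(rate=0.0, amplitude=0.0, r_squared=0.0, flagged=True)
    t = t_cool[usable] - t_cool[0]
    y = np.log(np.maximum(excess[usable], LOG_EPS))
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(
        rate=float(-slope),
        amplitude=float(math.exp(intercept)),
        r_squared=float(min(max(r2, 0.0), 1.0)),
    )


def _peak_rise(curve: TemperatureCurve, base: float) -> float:
    return float(curve.values.max() - base)


def _heating_slope(curve: TemperatureCurve) -> float:
    """OLS slope (K/s) of temperature against time over the heating phase."""
    t, v = curve.phase_values(PHASE_HEATING)
    if len(t) < 2:
        raise QualityError("heating phase too short for a slope")
    slope, _ = np.polyfit(t, v, 1)
    return float(slope)


def _cooling_auc_norm(curve: TemperatureCurve, base: float) -> float:
    """Normalized cooling area: trapezoid integral of the cooling excess
    divided by (peak rise x cooling duration); dimensionless in [0, ~1]."""
    t, v = curve.phase_values(PHASE_COOLING)
    peak = _peak_rise(curve, base)
    dt = float(np.median(np.diff(curve.timestamps)))
    duration = len(t) * dt
    if peak <= 0 or duration <= 0:
        return 0.0
    area = float(np.trapezoid(v - base, t))
    return area / (peak * duration)


PER_SITE_FEATURES: Dict[str, Callable[[TemperatureCurve, float], float]] = {
    "peak_rise": lambda c, b: _peak_rise(c, b),
    "heat_slope": lambda c, b: _heating_slope(c),
    "cool_rate": lambda c, b: fit_decay(c, baseline=b).rate,
    "cool_half_time": lambda c, b: _half_time(fit_decay(c, baseline=b).rate),
    "cool_auc": lambda c, b: _cooling_auc_norm(c, b),
}

#: Extension point: name -> callable(curve, baseline) for extra per-site features.
FEATURE_REGISTRY: Dict[str, Callable[[TemperatureCurve, float], float]] = dict(
    PER_SITE_FEATURES
)


def _half_time(rate: float) -> float:
    return math.log(2.0) / rate if rate > 0 else math.inf


def feature_names() -> List[str]:
    names = ["baseline_delta"]
    for f in FEATURE_REGISTRY:
        names += [f"{f}_mass", f"{f}_healthy", f"{f}_diff"]
    return names


def compute_features(
    mass_curve: TemperatureCurve,
    healthy_curve: TemperatureCurve,
    ratios: bool = False,
) -> Dict[str, float]:
    """Full feature vector for one lesion (per-site + differential).

    Differential entries are mass minus healthy exactly, so swapping the two
    curves negates every differential feature.  Subtraction is the default
    combination because it stays defined when healthy values sit near zero;
    ``ratios`` additionally emits mass/healthy ratio variants (NaN-guarded).
    """
    base_m = mass_curve.baseline_temp()
    base_h = healthy_curve.baseline_temp()
    out: Dict[str, float] = {"baseline_delta": base_m - base_h}
    for name, fn in FEATURE_REGISTRY.items():
        vm = fn(mass_curve, base_m)
        vh = fn(healthy_curve, base_h)
        out[f"{name}_mass"] = vm
        out[f"{name}_healthy"] = vh
        out[f"{name}_diff"] = vm - vh
        if ratios:
            out[f"{name}_ratio"] = vm / vh if vh != 0 else math.nan
    return out


def build_feature_table(cohort: CohortDataset, diagnostic_only: bool = False) -> pd.DataFrame:
    """Per-lesion feature table with diagnosis, dog and tumor-type metadata.

    Rows are keyed by lesion_id.  The ``diagnosis`` column holds the
    definitive label (histopathology overrides cytology) or NaN for
    non-diagnostic lesions; with ``diagnostic_only`` those rows are dropped.
    Rows with non-finite feature values (degenerate fits) are dropped as QC.
    """
    from .metrics import resolve_diagnosis  # deferred: metrics imports nothing from here

    rows = []
    for rec in cohort.records:
        mc, hc = cohort.curves[rec.lesion_id]
        feats = compute_features(mc, hc)
        label = resolve_diagnosis(rec.cytology_label, rec.histopath_label)
        rows.append(
            {
                "lesion_id": rec.lesion_id,
                DOG_COL: rec.dog_id,
                TYPE_COL: rec.tumor_type,
                LABEL_COL: label,
                **feats,
            }
        )
    df = pd.DataFrame(rows).set_index("lesion_id")
    feat_cols = [c for c in df.columns if c not in META_COLS]
    finite = np.isfinite(df[feat_cols].to_numpy(dtype=float)).all(axis=1)
    df = df.loc[finite]
    if diagnostic_only:
        df = df[df[LABEL_COL].notna()]
    return df


@dataclass
class NormalizationStats:
    """Frozen per-feature mean/sd from a training table.

    Features whose training variance is zero are recorded in ``dropped`` and
    excluded from normalized output (a zero-variance feature carries no
    cohort-level information and would divide by zero).
    """

    mean: Dict[str, float]
    sd: Dict[str, float]
    dropped: List[str] = field(default_factory=list)

    @property
    def features(self) -> List[str]:
        return list(self.mean)

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "dropped": self.dropped}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]), dropped=list(d.get("dropped", [])))


def normalize(
    table: pd.DataFrame, stats: Optional[NormalizationStats] = None
) -> Tuple[pd.DataFrame, NormalizationStats]:
    """Z-score feature columns; fit stats from the table unless supplied.

    Metadata columns pass through untouched.  With fitted stats every
    retained column has mean 0 and sd 1 (population sd); re-applying the
    returned stats to the same table reproduces the output exactly.
    """
    feat_cols = [c for c in table.columns if c not in META_COLS]
    if stats is None:
        x = table[feat_cols].to_numpy(dtype=float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0)  # population sd
        dropped = [c for c, s in zip(feat_cols, sd) if s <= 0]
        kept = [c for c in feat_cols if c not in dropped]
        stats = NormalizationStats(
            mean={c: float(m) for c, m in zip(feat_cols, mean) if c in kept},
            sd={c: float(s) for c, s in zip(feat_cols, sd) if c in kept},
            dropped=dropped,
        )
    missing = [c for c in stats.features if c not in table.columns]
    if missing:
        raise ConfigurationError(f"table lacks features required by stats: {missing}")
    out = table[[c for c in META_COLS if c in table.columns]].copy()
    for c in stats.features:
        out[c] = (table[c].astype(float) - stats.mean[c]) / stats.sd[c]
    return out, stats


def select_features(table: pd.DataFrame, k: int = 3, label_col: str = LABEL_COL) -> List[str]:
    """Top-k features by absolute point-biserial correlation with the label.

    Point-biserial correlation is the Pearson correlation between a feature
    and the 0/1 (benign/malignant) label.  Ties are broken by lexicographic
    feature name, making the ranking fully deterministic.
    """
    feat_cols = [c for c in table.columns if c not in META_COLS]
    y = (table[label_col] == MALIGNANT).to_numpy(dtype=float)
    if y.std() == 0:
        raise ConfigurationError("both classes required for feature selection")
    scores: List[Tuple[float, str]] = []
    for c in feat_cols:
        x = table[c].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        scores.append((abs(r), c))
    if len(scores) < k:
        raise ConfigurationError(f"need >= {k} features with nonzero variance, got {len(scores)}")
    scores.sort(key=lambda rc: (-rc[0], rc[1]))
    return [c for _, c in scores[:k]]
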