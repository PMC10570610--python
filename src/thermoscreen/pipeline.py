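"""End-to-end experiments: training with leave-one-out, fixed-model validation.

Mirrors the two studies the screening device went through: first a training
cohort is simulated (or loaded), features are extracted, the classifier is
evaluated by leave-one-out and then frozen; second, the frozen model is
applied unchanged to a validation cohort, with non-diagnostic lesions
excluded and histopathology overriding cytology.  Every artifact embeds the
seed and a configuration hash so identical runs are identical byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .features import LABEL_COL, build_feature_table
from .metrics import confusion_metrics, per_type_report, render_report_text
from .model import LinearModel, TrainConfig, config_hash, evaluate_fixed, loo_cross_validate, train
from .simulate import (
    CohortConfig,
    CohortDataset,
    generate_cohort,
    training_cohort_config,
    validation_cohort_config,
)

log = logging.getLogger("thermoscreen")


def _stage(name: str, msg: str) -> None:
    log.info(json.dumps({"stage": name, "message": msg}))


@dataclass
class ExperimentConfig:
    """Everything a training or validation run needs."""

    cohort: CohortConfig
    classifier: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def hash(self) -> str:
        return config_hash(
            {
                "cohort": {
                    "n_dogs": self.cohort.n_dogs,
                    "class_counts": self.cohort.class_counts,
                    "nondiagnostic_counts": self.cohort.nondiagnostic_counts,
                    "masses_per_dog": self.cohort.masses_per_dog,
                    "histopath_fraction": self.cohort.histopath_fraction,
                    "seed": self.cohort.seed,
                },
                "classifier": {
                    "min_sensitivity": self.classifier.min_sensitivity,
                    "n_features": self.classifier.n_features,
                    "group_by_dog": self.classifier.group_by_dog,
                },
                "seed": self.seed,
            }
        )


def default_training_experiment(seed: int = 0) -> ExperimentConfig:
    return ExperimentConfig(cohort=training_cohort_config(seed=seed), seed=seed)


def default_validation_experiment(seed: int = 0) -> ExperimentConfig:
    return ExperimentConfig(cohort=validation_cohort_config(seed=seed), seed=seed)


def _provenance(config: ExperimentConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.hash(), "version": __version__}


def run_training_experiment(
    config: ExperimentConfig,
    cohort: Optional[CohortDataset] = None,
    out_dir: Optional[str | Path] = None,
) -> Dict[str, object]:
    """Simulate/load the training cohort, run LOO, and freeze the final model.

    Returns a dict with the LOO confusion matrix, the five screening
    metrics, the frozen model and provenance; writes ``model.json`` and
    ``training_metrics.json`` when ``out_dir`` is given.
    """
    _stage("simulate", "generating training cohort")
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    _stage("features", "extracting thermal features")
    table = build_feature_table(cohort, diagnostic_only=True)
    if len(table) < 10:
        raise ConfigurationError("training cohort must retain >= 10 diagnostic lesions")
    _stage("loo", f"leave-one-out over {len(table)} lesions")
    cm, loo_preds = loo_cross_validate(table, config.classifier)
    _stage("train", "fitting final fixed model")
    model = train(table, config.classifier)
    model.metadata.update(_provenance(config))

    result = {
        "confusion": dict(zip(("tp", "tn", "fp", "fn"), cm.as_tuple())),
        "metrics": confusion_metrics(cm).to_dict(),
        "n_lesions": int(len(table)),
        "model": model,
        "loo_predictions": loo_preds,
        **_provenance(config),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model.save(out_dir / "model.json")
        payload = {k: v for k, v in result.items() if k not in ("model", "loo_predictions")}
        (out_dir / "training_metrics.json").write_text(json.dumps(payload, indent=2))
    return result


def run_validation_experiment(
    config: ExperimentConfig,
    model: LinearModel,
    cohort: Optional[CohortDataset] = None,
    out_dir: Optional[str | Path] = None,
) -> Dict[str, object]:
    """Apply a frozen model to the validation cohort.

    Non-diagnostic lesions are excluded (cytology non-diagnostic without
    histopathology); histopathology overrides cytology for the rest.  No
    model parameter is refit.
    """
    _stage("simulate", "generating validation cohort")
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    _stage("features", "extracting thermal features")
    full_table = build_feature_table(cohort, diagnostic_only=False)
    n_total = len(full_table)
    table = full_table[full_table[LABEL_COL].notna()]
    n_excluded = n_total - len(table)
    _stage("validate", f"fixed-model evaluation on {len(table)} diagnostic lesions")
    cm, preds = evaluate_fixed(model, table)
    report = per_type_report(preds, table)

    result = {
        "confusion": dict(zip(("tp", "tn", "fp", "fn"), cm.as_tuple())),
        "metrics": confusion_metrics(cm).to_dict(),
        "n_scanned": n_total,
        "n_excluded_nondiagnostic": n_excluded,
        "n_evaluated": int(len(table)),
        "per_type_report": report,
        "predictions": preds,
        **_provenance(config),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "per_type_report.csv", index=False)
        (out_dir / "per_type_report.txt").write_text(render_report_text(report))
        payload = {
            k: v for k, v in result.items() if k not in ("per_type_report", "predictions")
        }
        (out_dir / "validation_metrics.json").write_text(json.dumps(payload, indent=2))
    return result
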