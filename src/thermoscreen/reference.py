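"""Published screening results used as exact test vectors.

The device's raw scans are proprietary, but the published study results —
the training and validation confusion matrices and the per-tumor-type
prediction table of the validation cohort — are exact inputs that the
metrics layer can be checked against.  They live here as plain constants;
nothing in this module is computed.
"""

from __future__ import annotations

from typing import List, Tuple

import pandas as pd

from .metrics import ConfusionMatrix

#: Training cohort (233 masses, leave-one-out): TP, TN, FP, FN.
TRAINING_CONFUSION = ConfusionMatrix(tp=37, tn=146, fp=40, fn=10)

#: Validation cohort (431 diagnostic masses, fixed model): TP, TN, FP, FN.
VALIDATION_CONFUSION = ConfusionMatrix(tp=45, tn=253, fp=125, fn=8)

#: Validation cohort composition: 525 scanned masses, 94 non-diagnostic.
VALIDATION_N_MASSES = 525
VALIDATION_N_NONDIAGNOSTIC = 94
VALIDATION_N_DIAGNOSTIC = 431
VALIDATION_N_BENIGN = 378
VALIDATION_N_MALIGNANT = 53

#: Per tumor-type device predictions on the validation cohort:
#: (class, tumor type, predicted benign, predicted malignant).
VALIDATION_PER_TYPE: List[Tuple[str, str, int, int]] = [
    ("benign", "Benign epithelial/adnexal cyst/tumor", 37, 57),
    ("benign", "Benign melanoma", 3, 1),
    ("benign", "Calcinosis circumscripta", 0, 1),
    ("benign", "Histiocytoma", 1, 2),
    ("benign", "Hyperplasia", 1, 2),
    ("benign", "Inflammatory process", 5, 17),
    ("benign", "Lipoma", 206, 44),
    ("benign", "Perineal adenoma", 0, 1),
    ("malignant", "Carcinoma", 0, 2),
    ("malignant", "Mast cell tumor", 8, 30),
    ("malignant", "Soft tissue sarcoma", 0, 13),
]


def validation_per_type_records() -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Expand the published per-type table into per-lesion records.

    Returns (records, predictions) frames indexed by a synthetic lesion id,
    suitable for :func:`thermoscreen.metrics.per_type_report`; summing the
    report reproduces the published marginals exactly.
    """
    recs, preds = [], []
    i = 0
    for cls, tumor_type, n_ben, n_mal in VALIDATION_PER_TYPE:
        for pred_label, n in (("benign", n_ben), ("requires_further_investigation", n_mal)):
            for _ in range(n):
                lid = f"P{i:04d}"
                recs.append({"lesion_id": lid, "tumor_type": tumor_type, "diagnosis": cls})
                preds.append({"lesion_id": lid, "label": pred_label})
                i += 1
    records = pd.DataFrame(recs).set_index("lesion_id")
    predictions = pd.DataFrame(preds).set_index("lesion_id")
    return records, predictions
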