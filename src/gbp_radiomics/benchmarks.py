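"""Published clinical benchmark values for the 100-lesion pilot cohort.

The clinical study this pipeline models reported its SVM classification
results on a private 100-lesion cohort (71 cholesterol / 29 neoplastic
polyps).  Those patient images are not deposited, so the metric values cannot
be recomputed here; the printed summary tables are kept as reference
constants for arithmetic cross-checks (Youden's index identity, model-pair
mean differences) and for calibrating the synthetic cohort generator.
"""

from __future__ import annotations

from typing import Dict, Tuple

#: per model: test-set metric means (AUC, ACC, SEN, SPE, YI)
CLINICAL_TEST_MEANS: Dict[str, Dict[str, float]] = {
    "B": {"auc": 0.804, "acc": 0.802, "sen": 0.831, "spe": 0.792, "yi": 0.622},
    "SMI": {"auc": 0.782, "acc": 0.756, "sen": 0.856, "spe": 0.718, "yi": 0.574},
    "dual": {"auc": 0.850, "acc": 0.828, "sen": 0.892, "spe": 0.803, "yi": 0.695},
}

#: per model: training-set metric means
CLINICAL_TRAIN_MEANS: Dict[str, Dict[str, float]] = {
    "B": {"auc": 0.874, "acc": 0.832, "sen": 0.792, "spe": 0.851, "yi": 0.636},
    "SMI": {"auc": 0.872, "acc": 0.814, "sen": 0.880, "spe": 0.793, "yi": 0.668},
    "dual": {"auc": 0.899, "acc": 0.861, "sen": 0.852, "spe": 0.864, "yi": 0.716},
}

#: printed dual-vs-single test-set mean differences (and 95% CI)
CLINICAL_DIFFERENCES: Dict[Tuple[str, str], Dict[str, Tuple[float, float, float]]] = {
    ("dual", "B"): {
        "auc": (0.045, -0.003, 0.093),
        "acc": (0.026, -0.020, 0.072),
        "sen": (0.061, -0.022, 0.144),
        "spe": (0.012, -0.066, 0.090),
        "yi": (0.073, 0.001, 0.145),
    },
    ("dual", "SMI"): {
        "auc": (0.068, 0.039, 0.097),
        "acc": (0.072, 0.037, 0.107),
        "sen": (0.036, -0.045, 0.117),
        "spe": (0.085, 0.016, 0.154),
        "yi": (0.121, 0.068, 0.174),
    },
}

#: cohort composition and per-class lesion statistics used to calibrate the
#: synthetic generator: counts, diameter median (range) in mm, vascular counts
CLINICAL_COHORT = {
    "n_lesions": 100,
    "n_cholesterol": 71,
    "n_neoplastic": 29,
    "diameter_mm": {
        "cholesterol": {"median": 13.0, "min": 8.0, "max": 21.0},
        "neoplastic": {"median": 17.0, "min": 8.0, "max": 28.0},
    },
    "vascular": {"cholesterol": (38, 33), "neoplastic": (26, 3)},  # (yes, no)
}

#: reported feature counts
FEATURE_COUNTS = {
    "spatial_per_modality": 91,
    "morphological": 15,
    "glcm": 60,
    "dual_columns": 197,
}


def youden_index(sen: float, spe: float) -> float:
    """YI = SEN + SPE - 1."""
    return sen + spe - 1.0


def recomputed_differences() -> Dict[Tuple[str, str], Dict[str, float]]:
    """Dual-vs-single mean differences recomputed from the test-set means."""
    out: Dict[Tuple[str, str], Dict[str, float]] = {}
    for single in ("B", "SMI"):
        out[("dual", single)] = {
            m: CLINICAL_TEST_MEANS["dual"][m] - CLINICAL_TEST_MEANS[single][m]
            for m in ("auc", "acc", "sen", "spe", "yi")
        }
    return out
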