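"""End-to-end orchestration: simulate -> extract -> select/train -> report.

`run_pipeline` executes every stage from a `PipelineConfig` and writes a
reproducible results bundle (images, masks, feature tables, ICC reports,
selection results, metric summaries, paired comparisons, ROC/calibration
curves and a manifest keyed by config hash + seed).  Reruns with the same
config produce byte-identical metric CSVs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import classify, features, stats, synthdata
from .classify import ModalityData, ProtocolResult
from .config import PipelineConfig, derive_seed
from .features import FeatureTables
from .selection import icc_filter
from .synthdata import DELINEATION_KEYS, DualModalCase

FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    cohort: List[DualModalCase]
    tables_by_delineation: Dict[Tuple[str, int], FeatureTables]
    protocol: ProtocolResult
    comparisons: pd.DataFrame
    manifest: Dict


def extract_all_delineations(
    cohort: List[DualModalCase], config: PipelineConfig
) -> Dict[Tuple[str, int], FeatureTables]:
    """Feature tables for each of the three delineations."""
    return {
        key: features.build_tables(
            cohort, key, margin_px=config.reference_margin_px,
            pixel_spacing=config.pixel_spacing,
        )
        for key in DELINEATION_KEYS
    }


def modality_data(
    tables: Dict[Tuple[str, int], FeatureTables]
) -> Dict[str, ModalityData]:
    """Per-modality primary table (observer A, rep 1) + replicate tables."""
    primary_key = ("A", 1)
    return {
        "B": ModalityData(
            primary=tables[primary_key].b,
            delineations={k: t.b for k, t in tables.items()},
        ),
        "SMI": ModalityData(
            primary=tables[primary_key].smi,
            delineations={k: t.smi for k, t in tables.items()},
        ),
        "dual": ModalityData(
            primary=tables[primary_key].dual,
            delineations={k: t.dual for k, t in tables.items()},
        ),
    }


def run_protocol(
    tables: Dict[Tuple[str, int], FeatureTables],
    config: PipelineConfig,
    labels: pd.Series | None = None,
) -> ProtocolResult:
    data = modality_data(tables)
    if labels is None:
        labels = tables[("A", 1)].labels
    return classify.repeat_protocol(
        data, labels,
        n_repeats=config.n_repeats,
        master_seed=derive_seed(config.master_seed, "protocol"),
        ratio=config.train_ratio,
        icc_threshold=config.icc_threshold,
        selection_scope=config.selection_scope,
        c_grid=[2.0**e for e in config.svm_c_exponents],
        gamma_grid=[2.0**e for e in config.svm_gamma_exponents],
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute all stages; write the results bundle when ``out_dir`` is given."""
    timings = {}

    t0 = time.perf_counter()
    try:
        cohort = synthdata.generate_cohort(config.cohort_spec())
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    timings["simulate_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        tables = extract_all_delineations(cohort, config)
    except Exception as exc:
        raise StageError("extract", exc) from exc
    timings["extract_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        protocol = run_protocol(tables, config)
    except Exception as exc:
        raise StageError("train", exc) from exc
    timings["train_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        if config.n_repeats >= 3:
            matrices = {m: protocol.metric_matrix("test", m) for m in stats.METRICS}
            comparisons = stats.compare_all(matrices)
        else:  # paired tests need n >= 3
            comparisons = pd.DataFrame(
                columns=["metric", "pair", "mean_diff", "ci95_low", "ci95_high",
                         "p_value", "test_used", "normality_p"]
            )
    except Exception as exc:
        raise StageError("stats", exc) from exc
    timings["stats_s"] = time.perf_counter() - t0

    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_cases": len(cohort),
        "n_features": {
            "B": int(tables[("A", 1)].b.shape[1]),
            "SMI": int(tables[("A", 1)].smi.shape[1]),
            "dual": int(tables[("A", 1)].dual.shape[1]),
        },
        "timings": timings,
    }
    result = PipelineResult(cohort, tables, protocol, comparisons, manifest)
    if out_dir is not None:
        write_bundle(result, config, Path(out_dir))
    return result


def write_bundle(result: PipelineResult, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    img_dir = out / "images"
    synthdata.save_cohort(result.cohort, img_dir)

    primary = result.tables_by_delineation[("A", 1)]
    for name, df in (("features_B", primary.b), ("features_SMI", primary.smi),
                     ("features_dual", primary.dual)):
        features.save_table(df, primary.labels, out / f"{name}.csv")
    (out / "extractor_params.json").write_text(
        json.dumps(dict(features.EXTRACTOR_PARAMS), indent=2)
    )

    # whole-cohort ICC reports per modality (descriptive; the protocol refits
    # its own train-scoped filters inside each repeat)
    data = modality_data(result.tables_by_delineation)
    for name, d in data.items():
        icc_filter(d.delineations, threshold=config.icc_threshold).to_csv(
            out / f"icc_{name}.csv"
        )

    result.protocol.runs.to_csv(out / "metrics_runs.csv", index=False,
                                float_format=FLOAT_FMT)
    classify.summary_table(result.protocol).to_csv(
        out / "metrics_summary.csv", index=False
    )
    result.comparisons.to_csv(out / "comparisons.csv", index=False,
                              float_format=FLOAT_FMT)
    (out / "comparisons.md").write_text(stats.comparison_markdown(result.comparisons))

    selections = {
        f"repeat{rep.repeat_index}": {
            name: sel.to_json_dict() for name, sel in rep.selection.items()
        }
        for rep in result.protocol.repeats
    }
    (out / "selection.json").write_text(json.dumps(selections, indent=2))

    _write_curves(result, out)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))


def _write_curves(result: PipelineResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = result.tables_by_delineation[("A", 1)].labels
    rep = result.protocol.repeats[0]
    y = (labels.loc[rep.test_rows] == classify.POSITIVE).astype(int).to_numpy()

    roc_rows, cal_rows = [], []
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for name in ("B", "SMI", "dual"):
        pts = classify.roc_points(rep.test_scores[name], y)
        axes[0].plot(pts[:, 0], pts[:, 1], label=name)
        roc_rows += [{"model": name, "fpr": f, "tpr": t} for f, t in pts]
        cal = classify.calibration_points(rep.test_probs[name], y, n_bins=5)
        axes[1].plot(cal[:, 0], cal[:, 1], marker="o", label=name)
        cal_rows += [{"model": name, "mean_pred": p, "frac_pos": f} for p, f in cal]
    axes[0].plot([0, 1], [0, 1], "k:", lw=0.8)
    axes[0].set(xlabel="1 - specificity", ylabel="sensitivity", title="ROC (repeat 1, test)")
    axes[1].plot([0, 1], [0, 1], "k:", lw=0.8)
    axes[1].set(xlabel="predicted risk", ylabel="observed fraction",
                title="Calibration (repeat 1, test)")
    for ax in axes:
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "curves.png", dpi=120)
    plt.close(fig)
    pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False,
                                  float_format=FLOAT_FMT)
    pd.DataFrame(cal_rows).to_csv(out / "calibration_points.csv", index=False,
                                  float_format=FLOAT_FMT)
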