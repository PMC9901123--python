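"""Paired comparison of the dual-modality model against each single modality.

For every metric (AUC, ACC, SEN, SPE, YI) the per-repeat test-set values of
two models are differenced pairwise; the differences are tested for normality
(Shapiro-Wilk at alpha = 0.05) and compared with a paired t-test when normal,
otherwise with the Wilcoxon signed-rank test (exact for n <= 25, zeros
dropped).  The mean difference and its t-based 95% CI are always reported
descriptively, mirroring how published comparison tables print a CI next to a
Wilcoxon p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

METRICS = ("auc", "acc", "sen", "spe", "yi")
NORMALITY_ALPHA = 0.05


@dataclass
class PairedComparison:
    metric: str
    model_pair: Tuple[str, str]
    mean_diff: float
    ci95: Tuple[float, float]
    p_value: float
    test_used: str          # "paired-t" or "wilcoxon"
    normality_p: float
    degenerate: bool = False


def paired_compare(
    a: Sequence[float], b: Sequence[float],
    metric: str = "", model_pair: Tuple[str, str] = ("", ""),
    alpha: float = NORMALITY_ALPHA,
) -> PairedComparison:
    """Compare two paired per-run metric series (a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D series with n >= 3")
    d = a - b
    mean_diff = float(d.mean())
    n = len(d)

    if np.allclose(d, 0.0):
        return PairedComparison(metric, model_pair, 0.0, (0.0, 0.0), 1.0,
                                "paired-t", 1.0, degenerate=True)

    if np.ptp(d) == 0:
        # constant nonzero difference: normality test undefined, t degenerate
        normality_p = 1.0
    else:
        normality_p = float(sps.shapiro(d).pvalue)

    sd = d.std(ddof=1)
    tcrit = sps.t.ppf(0.975, n - 1)
    half = tcrit * sd / np.sqrt(n)
    ci = (mean_diff - half, mean_diff + half)

    if normality_p >= alpha:
        if sd == 0:
            p = 0.0
        else:
            p = float(sps.ttest_rel(a, b).pvalue)
        test = "paired-t"
    else:
        res = sps.wilcoxon(d, zero_method="wilcox",
                           method="exact" if n <= 25 else "auto")
        p = float(res.pvalue)
        test = "wilcoxon"
    return PairedComparison(metric, model_pair, mean_diff, ci, p, test, normality_p)


def compare_all(
    metric_matrices: Dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """All 10 dual-vs-single comparisons (5 metrics x 2 pairs).

    ``metric_matrices`` maps each metric name to a repeats x models DataFrame
    of test-set values with columns including 'B', 'SMI' and 'dual'.
    """
    rows = []
    for metric in METRICS:
        mat = metric_matrices[metric]
        for single in ("B", "SMI"):
            cmp = paired_compare(mat["dual"], mat[single], metric=metric,
                                 model_pair=("dual", single))
            rows.append({
                "metric": metric.upper(),
                "pair": f"dual-{single}",
                "mean_diff": cmp.mean_diff,
                "ci95_low": cmp.ci95[0],
                "ci95_high": cmp.ci95[1],
                "p_value": cmp.p_value,
                "test_used": cmp.test_used,
                "normality_p": cmp.normality_p,
            })
    return pd.DataFrame(rows)


def comparison_markdown(report: pd.DataFrame) -> str:
    """Markdown comparison table; Wilcoxon rows carry the asterisk marker."""
    lines = ["| Metric | Pair | Difference (95% CI) | p-value |",
             "|---|---|---|---|"]
    for _, row in report.iterrows():
        star = "*" if row["test_used"] == "wilcoxon" else ""
        p = row["p_value"]
        p_str = "< 0.001" if p < 0.001 else f"{p:.3f}"
        lines.append(
            f"| {row['metric']} | {row['pair']} | "
            f"{row['mean_diff']:.3f} ({row['ci95_low']:.3f}–{row['ci95_high']:.3f}) | "
            f"{p_str}{star} |"
        )
    lines.append("")
    lines.append("\\* Wilcoxon signed-rank test (non-normal differences); "
                 "other rows: paired t-test.")
    return "\n".join(lines)
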