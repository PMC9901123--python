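"""SVM classification protocol: repeated 8:2 splits, grid-searched RBF SVM,
per-repeat metrics, ROC and calibration curves.

Protocol (per repeat): one stratified 8:2 train/test split shared by the
B-mode, SMI and dual-modality models; within the training rows each modality
runs its own selection cascade (ICC filter, z-scoring, LASSO) followed by an
exhaustive grid search over the RBF-SVM cost and kernel width with stratified
5-fold cross-validation maximizing AUC; the refit model is then scored on the
held-out test rows.  Five repeats yield the mean +/- SD metric summary.

The positive class is the neoplastic polyp throughout (sensitivity = the
neoplastic detection rate).  Hard classification uses the decision-score
threshold 0, equivalently probability 0.5: the operating score fed to
`evaluate` is the Platt log-odds (probabilities from Platt scaling fitted
within the training folds), a strictly monotone transform of the raw SVM
margin, so AUC is unchanged while the 0 threshold sits at calibrated risk
0.5 rather than at the unscaled margin midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import calibration_curve
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .selection import SelectionResult, select_features

POSITIVE = "neoplastic"

#: RBF grid: cost 2^-5..2^15 and width 2^-15..2^3, stepped by powers of 4
#: (the width endpoint 2^3 appended since stepping from -15 lands on 1).
DEFAULT_C_GRID: Tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 4))
DEFAULT_GAMMA_GRID: Tuple[float, ...] = tuple(2.0**e for e in (-15, -11, -7, -3, 1, 3))


@dataclass
class RunMetrics:
    model: str          # "B", "SMI" or "dual"
    repeat_index: int   # 1-based
    split: str          # "train" or "test"
    auc: float
    acc: float
    sen: float
    spe: float
    yi: float

    def as_dict(self) -> Dict[str, float]:
        return {"auc": self.auc, "acc": self.acc, "sen": self.sen,
                "spe": self.spe, "yi": self.yi}


def stratified_split(
    rows: Sequence, labels: Sequence, ratio: float = 0.8, seed: int = 0
) -> Tuple[List, List]:
    """Stratified train/test partition at the given train fraction."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to stratify")
    train, test = train_test_split(
        list(rows), train_size=ratio, stratify=labels, random_state=seed
    )
    return list(train), list(test)


class _ConstantScoreModel:
    """Fallback when selection retains no feature: uninformative scores."""

    def decision_function(self, X):
        return np.zeros(len(X))

    def predict_proba(self, X):
        return np.full((len(X), 2), 0.5)


class SvmGridClassifier(BaseEstimator, ClassifierMixin):
    """RBF SVM tuned by exhaustive grid search over (C, gamma).

    Selects the grid point maximizing mean stratified 5-fold CV AUC, refits on
    all training rows, and exposes a continuous decision score and a Platt-
    calibrated probability.
    """

    def __init__(self, c_grid: Sequence[float] = DEFAULT_C_GRID,
                 gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                 cv_folds: int = 5, random_state: int = 0):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        if len(self.c_grid) == 0 or len(self.gamma_grid) == 0:
            raise ValueError("empty parameter grid")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        cv = StratifiedKFold(self.cv_folds, shuffle=True,
                             random_state=self.random_state)
        # search on plain SVCs (no Platt fits), then refit once with Platt
        # scaling so the final model exposes calibrated probabilities.
        # Mean CV AUC is the selection criterion; exact AUC ties (common on
        # strongly separable data) break on CV accuracy, then grid order.
        search = GridSearchCV(
            SVC(kernel="rbf"),
            param_grid={"C": list(self.c_grid), "gamma": list(self.gamma_grid)},
            scoring={"auc": "roc_auc", "acc": "accuracy"},
            cv=cv, n_jobs=None, refit=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X, y)
            res = search.cv_results_
            # lexsort: primary key mean AUC (desc), secondary mean ACC (desc);
            # remaining ties resolve to grid order
            order = np.lexsort((-res["mean_test_acc"], -res["mean_test_auc"]))
            best = int(order[0])
            self.best_params_ = dict(res["params"][best])
            self.cv_auc_ = float(res["mean_test_auc"][best])
            self.model_ = SVC(
                kernel="rbf", probability=True, random_state=self.random_state,
                **self.best_params_,
            ).fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def decision_function(self, X):
        return self.model_.decision_function(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        # operate at calibrated probability 0.5, consistent with the
        # protocol's decision-score threshold 0
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def tune_svm(
    train_table: pd.DataFrame, labels: Sequence, folds: int = 5, seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> SvmGridClassifier:
    """Grid-search an RBF SVM on normalized training features."""
    return SvmGridClassifier(
        c_grid=c_grid, gamma_grid=gamma_grid, cv_folds=folds, random_state=seed
    ).fit(train_table, np.asarray(labels))


def evaluate(
    scores: np.ndarray, y_true: np.ndarray,
    model: str = "", repeat_index: int = 0, split: str = "",
    threshold: float = 0.0,
) -> RunMetrics:
    """Metrics from continuous decision scores (positive = neoplastic = 1).

    AUC is the rank statistic (ties counted half); ACC/SEN/SPE are taken at
    the decision-score threshold (default 0); YI = SEN + SPE - 1.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(s) == 0:
        raise ValueError("no rows to evaluate")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined with a single class present")
    auc = float(roc_auc_score(y, s))
    pred = (s > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    return RunMetrics(
        model=model, repeat_index=repeat_index, split=split,
        auc=auc, acc=(tp + tn) / len(y), sen=sen, spe=spe, yi=sen + spe - 1.0,
    )


@dataclass
class ModalityData:
    """Primary feature table plus the replicate delineation tables."""

    primary: pd.DataFrame
    delineations: Mapping[Tuple[str, int], pd.DataFrame]


@dataclass
class RepeatResult:
    repeat_index: int
    train_rows: List
    test_rows: List
    selection: Dict[str, SelectionResult]
    metrics: List[RunMetrics]
    test_scores: Dict[str, np.ndarray] = field(default_factory=dict)
    test_probs: Dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class ProtocolResult:
    runs: pd.DataFrame          # model, repeat, split, auc..yi (long form)
    summary: pd.DataFrame       # model x split -> metric mean/SD
    repeats: List[RepeatResult]

    def metric_matrix(self, split: str, metric: str) -> pd.DataFrame:
        """repeats x models matrix of one metric, for paired comparisons."""
        sub = self.runs[self.runs["split"] == split]
        return sub.pivot(index="repeat_index", columns="model", values=metric)


def _fit_and_score_modality(
    name: str,
    data: ModalityData,
    labels: pd.Series,
    train_rows: Sequence,
    test_rows: Sequence,
    repeat_index: int,
    seed: int,
    icc_threshold: float,
    selection_scope: str,
    c_grid: Sequence[float],
    gamma_grid: Sequence[float],
) -> Tuple[SelectionResult, List[RunMetrics], np.ndarray, np.ndarray]:
    sel_result, norm = select_features(
        data.primary, data.delineations, labels, train_rows,
        modality=name, icc_threshold=icc_threshold, seed=seed,
        scope=selection_scope,
    )
    y = (labels == POSITIVE).astype(int)
    if norm.shape[1] == 0:
        model: object = _ConstantScoreModel()
    else:
        model = tune_svm(norm.loc[train_rows], y.loc[train_rows], seed=seed,
                         c_grid=c_grid, gamma_grid=gamma_grid)
    metrics, scores, probs = [], None, None
    for split, rows in (("train", train_rows), ("test", test_rows)):
        if norm.shape[1]:
            p = model.predict_proba(norm.loc[rows])
            pos_col = 1
            if hasattr(model, "classes_"):
                pos_col = int(np.nonzero(np.asarray(model.classes_) == 1)[0][0])
            p_pos = p[:, pos_col]
            # operating score: Platt log-odds, so threshold 0 <=> p = 0.5
            s = _logit(p_pos)
        else:
            p_pos = np.full(len(rows), 0.5)
            s = np.zeros(len(rows))
        metrics.append(
            evaluate(s, y.loc[rows], model=name, repeat_index=repeat_index, split=split)
        )
        if split == "test":
            scores = s
            probs = p_pos
    return sel_result, metrics, scores, probs


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def repeat_protocol(
    tables: Mapping[str, ModalityData],
    labels: pd.Series,
    n_repeats: int = 5,
    master_seed: int = 0,
    ratio: float = 0.8,
    icc_threshold: float = 0.6,
    selection_scope: str = "train",
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> ProtocolResult:
    """Run the repeated split/tune/evaluate protocol for all three models.

    Each repeat draws one stratified 8:2 split shared by every modality so the
    per-repeat test metrics are paired across models.
    """
    rows = list(labels.index)
    repeats: List[RepeatResult] = []
    records: List[Dict] = []
    for r in range(1, n_repeats + 1):
        seed_r = (master_seed * 10007 + r * 101) % (2**31 - 1)
        train_rows, test_rows = stratified_split(rows, labels.loc[rows], ratio, seed_r)
        rep = RepeatResult(r, train_rows, test_rows, selection={}, metrics=[])
        for name, data in tables.items():
            sel, metrics, scores, probs = _fit_and_score_modality(
                name, data, labels, train_rows, test_rows, r, seed_r,
                icc_threshold, selection_scope, c_grid, gamma_grid,
            )
            rep.selection[name] = sel
            rep.metrics.extend(metrics)
            rep.test_scores[name] = scores
            rep.test_probs[name] = probs
            for m in metrics:
                records.append({"model": m.model, "repeat_index": m.repeat_index,
                                "split": m.split, **m.as_dict()})
        repeats.append(rep)

    runs = pd.DataFrame.from_records(records)
    summary = (
        runs.groupby(["model", "split"])[["auc", "acc", "sen", "spe", "yi"]]
        .agg(["mean", "std"])
    )
    return ProtocolResult(runs=runs, summary=summary, repeats=repeats)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) at every distinct threshold, endpoints (0,0) and (1,1)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined with a single class present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float),
                            drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def calibration_points(
    probabilities: np.ndarray, labels: np.ndarray, n_bins: int = 5
) -> np.ndarray:
    """Reliability-curve points: (mean predicted risk, observed fraction).

    Equal-width bins on predicted risk; empty bins are omitted.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.size == 0:
        raise ValueError("empty input")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    frac_pos, mean_pred = calibration_curve(y, p, n_bins=n_bins, strategy="uniform")
    return np.column_stack([mean_pred, frac_pos])


def summary_table(result: ProtocolResult) -> pd.DataFrame:
    """Mean +/- SD metric strings in the published results-table layout."""
    rows = []
    for split in ("train", "test"):
        for model in ("B", "SMI", "dual"):
            if (model, split) not in result.summary.index:
                continue
            row = {"split": split, "model": model}
            for metric in ("auc", "acc", "sen", "spe", "yi"):
                mean = result.summary.loc[(model, split), (metric, "mean")]
                sd = result.summary.loc[(model, split), (metric, "std")]
                row[metric.upper()] = f"{mean:.3f} ± {sd:.3f}"
            rows.append(row)
    return pd.DataFrame(rows)
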