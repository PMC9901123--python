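"""Reproducibility filtering (ICC), normalization and LASSO feature selection.

Features that cannot be delineated reproducibly carry no diagnostic value, so
the bank is first filtered on the inter-observer intraclass correlation
coefficient: a feature passes iff ICC > 0.6 (strict) between the two
observers' first delineations.  The intra-observer ICC (observer A's two
repetitions) is reported alongside but does not gate.  The ICC form is
ICC(2,1): two-way random effects, absolute agreement, single measurement --
the conventional choice for radiomics reproducibility studies.

Surviving features are z-scored (mean/SD estimated on training rows only) and
reduced with an L1-penalized logistic regression over a 100-point lambda path
from lambda_max (the all-zero solution) down four decades; the penalty is
chosen by 5-fold cross-validated deviance and the selected set is the nonzero
coefficients at that penalty, ordered by |coefficient|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import l1_min_c
from sklearn.utils.validation import check_is_fitted


def icc_two_way(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Parameters
    ----------
    ratings : (n_subjects, n_raters) array of finite values.

    From the two-way ANOVA mean squares (rows = subjects, columns = raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    A table with zero total variance is perfect trivial agreement and returns
    1.0 with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (n_subjects >= 2, n_raters >= 2)")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        warnings.warn("zero total variance: ICC defined as 1", stacklevel=2)
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


@dataclass
class ICCReport:
    """Per-feature inter- and intra-observer ICC and the pass flag."""

    table: pd.DataFrame  # columns: inter_icc, intra_icc, passed
    threshold: float = 0.6

    @property
    def passed_features(self) -> List[str]:
        return list(self.table.index[self.table["passed"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.10g")


def icc_filter(
    tables: Mapping[Tuple[str, int], pd.DataFrame],
    threshold: float = 0.6,
    rows: Sequence | None = None,
) -> ICCReport:
    """Filter features on inter-observer ICC computed from repeat delineations.

    ``tables`` maps delineation keys to row/column-aligned feature tables and
    must contain (A,1), (A,2) and (B,1).  Inter-observer ICC pairs (A,1) with
    (B,1); intra-observer ICC pairs (A,1) with (A,2).  A feature passes iff
    inter_icc > threshold (strictly).  ``rows`` restricts the computation to a
    subset of cases (e.g. training rows only).
    """
    required = [("A", 1), ("A", 2), ("B", 1)]
    for key in required:
        if key not in tables:
            raise ValueError(f"missing delineation table {key}")
    a1, a2, b1 = (tables[k] for k in required)
    if not (a1.shape == a2.shape == b1.shape) or not (
        a1.columns.equals(a2.columns) and a1.columns.equals(b1.columns)
        and a1.index.equals(a2.index) and a1.index.equals(b1.index)
    ):
        raise ValueError("delineation tables must share rows and columns")
    if rows is not None:
        a1, a2, b1 = a1.loc[rows], a2.loc[rows], b1.loc[rows]

    records = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features are legitimately ICC=1
        for col in a1.columns:
            inter = icc_two_way(np.column_stack([a1[col], b1[col]]))
            intra = icc_two_way(np.column_stack([a1[col], a2[col]]))
            records[col] = {"inter_icc": inter, "intra_icc": intra,
                            "passed": inter > threshold}
    report = pd.DataFrame.from_dict(records, orient="index")
    report.index.name = "feature"
    return ICCReport(table=report, threshold=threshold)


@dataclass
class ZScoreStats:
    mean: pd.Series
    sd: pd.Series
    dropped: List[str] = field(default_factory=list)


def zscore_fit_apply(
    table: pd.DataFrame, fit_rows: Sequence
) -> Tuple[pd.DataFrame, ZScoreStats]:
    """Z-score every column using mean/SD from ``fit_rows`` only.

    Columns constant on the fit rows carry no training information and are
    dropped (and logged in the returned stats).
    """
    fit = table.loc[fit_rows]
    if len(fit) < 2:
        raise ValueError("need at least 2 fit rows")
    scaler = StandardScaler().fit(fit.to_numpy())
    sd = pd.Series(np.sqrt(scaler.var_), index=table.columns)
    keep = sd > 0
    dropped = list(table.columns[~keep])
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    mean = pd.Series(scaler.mean_, index=table.columns)[keep]
    sd = sd[keep]
    out = (table.loc[:, keep.index[keep]] - mean) / sd
    return out, ZScoreStats(mean=mean, sd=sd, dropped=dropped)


class LassoFeatureSelector(SelectorMixin, BaseEstimator):
    """L1-penalized logistic-regression feature selector.

    Fits the lasso path over ``n_lambdas`` log-spaced penalties from
    lambda_max (smallest penalty with an all-zero solution) down ``decades``
    decades, picks the penalty minimizing mean cross-validated deviance
    (5-fold, stratified, shuffled with ``random_state``), and selects the
    features with nonzero coefficients there.

    Attributes
    ----------
    lambda_ : chosen penalty on the glmnet scale (1 / (C * n_samples)).
    coef_ : coefficients at the chosen penalty.
    selected_features_ : names of selected features, |coef| descending
        (available when fitted on a DataFrame).
    """

    def __init__(self, n_lambdas: int = 100, decades: float = 4.0,
                 cv_folds: int = 5, random_state: int = 0, max_iter: int = 10000):
        self.n_lambdas = n_lambdas
        self.decades = decades
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y)
        classes = np.unique(ya)
        if len(classes) != 2:
            raise ValueError("lasso_select requires exactly two classes")
        self.n_features_in_ = Xa.shape[1]

        c_min = l1_min_c(Xa, ya, loss="log")
        cs = c_min * np.logspace(0, self.decades, self.n_lambdas)
        cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.random_state)
        deviance = np.zeros((self.cv_folds, len(cs)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # pathwise fits warm-started from the previous (stronger) penalty;
            # the path only has to rank penalties, so its tolerance is loose
            for f, (tr, va) in enumerate(cv.split(Xa, ya)):
                clf = LogisticRegression(
                    penalty="l1", solver="saga", warm_start=True,
                    max_iter=300, tol=1e-5, random_state=self.random_state,
                )
                for j, c in enumerate(cs):
                    clf.C = c
                    clf.fit(Xa[tr], ya[tr])
                    deviance[f, j] = log_loss(
                        ya[va], clf.predict_proba(Xa[va])[:, 1], labels=clf.classes_
                    )
            # penalty minimizing mean CV deviance; ties resolve to the
            # strongest penalty (sparsest model)
            self.C_ = float(cs[int(np.argmin(deviance.mean(axis=0)))])
            # one tight refit at the chosen penalty for the coefficients
            model = LogisticRegression(
                C=self.C_, penalty="l1", solver="saga",
                max_iter=self.max_iter, tol=1e-9,
                random_state=self.random_state,
            ).fit(Xa, ya)
        self.cv_deviance_ = deviance
        self.cs_ = cs
        self.lambda_ = 1.0 / (self.C_ * len(ya))
        self.coef_ = model.coef_.ravel().copy()
        self.intercept_ = float(model.intercept_[0])
        self.classes_ = model.classes_
        self.support_ = self.coef_ != 0
        order = np.argsort(-np.abs(self.coef_))
        order = order[self.support_[order]]
        if hasattr(self, "feature_names_in_"):
            self.selected_features_ = [str(self.feature_names_in_[i]) for i in order]
        else:
            self.selected_features_ = [int(i) for i in order]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


@dataclass
class SelectionResult:
    """Outcome of the ICC -> z-score -> LASSO cascade for one modality."""

    modality: str
    icc_report: ICCReport
    zscore: ZScoreStats
    lasso_lambda: float
    coefficients: Dict[str, float]
    selected: List[str]

    def to_json_dict(self) -> Dict:
        return {
            "modality": self.modality,
            "icc_threshold": self.icc_report.threshold,
            "n_icc_passed": len(self.icc_report.passed_features),
            "lasso_lambda": self.lasso_lambda,
            "coefficients": self.coefficients,
            "selected": self.selected,
        }


def lasso_select(
    norm_table: pd.DataFrame,
    labels: Sequence,
    n_lambdas: int = 100,
    decades: float = 4.0,
    cv_folds: int = 5,
    seed: int = 0,
) -> Tuple[LassoFeatureSelector, List[str]]:
    """Convenience wrapper: fit the selector on a normalized table."""
    sel = LassoFeatureSelector(
        n_lambdas=n_lambdas, decades=decades, cv_folds=cv_folds, random_state=seed
    ).fit(norm_table, np.asarray(labels))
    return sel, list(sel.selected_features_)


def select_features(
    primary: pd.DataFrame,
    delineation_tables: Mapping[Tuple[str, int], pd.DataFrame],
    labels: pd.Series,
    train_rows: Sequence,
    modality: str,
    icc_threshold: float = 0.6,
    seed: int = 0,
    scope: str = "train",
) -> Tuple[SelectionResult, pd.DataFrame]:
    """Run the full selection cascade for one modality.

    With ``scope='train'`` (default, leakage-free) the ICC filter, the
    normalization statistics and the LASSO are all computed on training rows
    only; ``scope='all'`` reproduces the literal all-cohort reading.
    Returns the selection result and the normalized full table restricted to
    the selected features.
    """
    if scope not in ("train", "all"):
        raise ValueError("scope must be 'train' or 'all'")
    stat_rows = list(train_rows) if scope == "train" else list(primary.index)
    report = icc_filter(delineation_tables, threshold=icc_threshold, rows=stat_rows)
    cols = report.passed_features
    if not cols:
        raise ValueError("no feature passed the ICC filter")
    norm, zstats = zscore_fit_apply(primary[cols], stat_rows)
    y = (labels == "neoplastic").astype(int)
    sel, selected = lasso_select(
        norm.loc[stat_rows], y.loc[stat_rows], cv_folds=5, seed=seed
    )
    coefs = {
        str(name): float(c)
        for name, c in zip(norm.columns, sel.coef_)
        if c != 0
    }
    result = SelectionResult(
        modality=modality,
        icc_report=report,
        zscore=zstats,
        lasso_lambda=sel.lambda_,
        coefficients=coefs,
        selected=selected,
    )
    return result, norm[selected] if selected else norm.iloc[:, :0]
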