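"""IC50 prediction model suite with quintile subsetting and best-of-folds CV.

Models predict IC50 either as a continuous value (evaluated by Spearman rho
on held-out folds) or as a binary above/below-median outcome (evaluated by
ROC AUC). Inputs are either the one-dimensional signature score or the
z-scored expression of each signature gene. Every model runs outer 5-fold
cross-validation; penalized and kernel models tune hyperparameters by inner
10-fold CV on the training fold only. The best fold's metric represents the
model (the optimistic convention the extraction study uses); mean and SD
across folds are reported alongside.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, LogisticRegression, Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.svm import SVC

from .core import DrugResponseTable, ExpressionMatrix
from .scoring import SignatureScoreVector

__all__ = [
    "ModelSpec",
    "ModelResult",
    "make_binary_outcome",
    "quintile_subset",
    "fit_predict_cv",
    "TABLE_SPECS",
]

log = logging.getLogger(__name__)

_CONT_METHODS = {"linear", "elastic_net", "l1", "l2"}
_BIN_METHODS = {"logistic", "elastic_net", "l1", "l2", "svm_linear", "svm_poly",
                "random_forest"}

_LAMBDA_GRID = np.logspace(-3, 2, 15)
_C_GRID = np.logspace(-2, 3, 15)
_SVM_GAMMA = [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]
_SVM_COST = [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]
_SVM_DEGREE = [3, 4, 5]


@dataclass
class ModelSpec:
    """One row of the prediction-model suite."""

    input_kind: str          # 'score' | 'per_gene'
    outcome: str             # 'continuous_ic50' | 'binary_ic50'
    method: str
    subset: str = "all"      # 'all' | 'quintiles'
    seed: int = 1
    inner_cv: int = 10
    fast: bool = False       # trim tuning grids (smaller problems)

    def __post_init__(self) -> None:
        if self.outcome == "continuous_ic50" and self.method not in _CONT_METHODS:
            raise ValueError(f"{self.method!r} does not predict a continuous outcome")
        if self.outcome == "binary_ic50" and self.method not in _BIN_METHODS:
            raise ValueError(f"{self.method!r} does not predict a binary outcome")
        if self.input_kind not in ("score", "per_gene"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.subset not in ("all", "quintiles"):
            raise ValueError(f"unknown subset {self.subset!r}")


@dataclass
class ModelResult:
    spec: ModelSpec
    per_fold_metric: list[float]
    metric_name: str
    n_train: list[int]
    n_test: list[int]
    mean_metric: float = field(init=False)
    sd_metric: float = field(init=False)
    best_metric: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.per_fold_metric, dtype=float)
        finite = vals[np.isfinite(vals)]
        self.best_metric = float(np.max(finite)) if finite.size else float("nan")
        self.mean_metric = float(np.mean(finite)) if finite.size else float("nan")
        self.sd_metric = float(np.std(finite, ddof=1)) if finite.size > 1 else float("nan")

    def as_dict(self) -> dict:
        return {
            "input_kind": self.spec.input_kind,
            "outcome": self.spec.outcome,
            "method": self.spec.method,
            "subset": self.spec.subset,
            "metric_name": self.metric_name,
            "per_fold_metric": self.per_fold_metric,
            "best_metric": self.best_metric,
            "mean_metric": self.mean_metric,
            "sd_metric": self.sd_metric,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def make_binary_outcome(resp: DrugResponseTable, samples: set[str]) -> pd.Series:
    """1 iff IC50 strictly exceeds the included group's median (median itself -> 0)."""
    samples = sorted(samples)
    if len(samples) < 4:
        raise ValueError("need at least 4 samples for a median split")
    vals = resp.ic50.loc[samples]
    if vals.nunique() == 1:
        raise ValueError("all IC50 values identical; median split undefined")
    med = float(vals.median())
    return (vals > med).astype(int)


def quintile_subset(scores: SignatureScoreVector) -> set[str]:
    """Union of the bottom and top floor(n/5) samples by score (ties: sample id)."""
    s = scores.score
    n = len(s)
    if n < 10:
        raise ValueError("need at least 10 samples for quintile subsetting")
    k = math.floor(n / 5)
    if s.nunique() == 1:
        log.warning("quintile_subset: constant scores; selection is lexicographic")
    order = sorted(s.index, key=lambda i: (s[i], i))
    return set(order[:k]) | set(order[-k:])


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _estimator(spec: ModelSpec):
    """Estimator plus hyperparameter grid for inner CV (None = no tuning)."""
    lam = _LAMBDA_GRID[::3] if spec.fast else _LAMBDA_GRID
    cs = _C_GRID[::3] if spec.fast else _C_GRID
    gam = _SVM_GAMMA[::2] if spec.fast else _SVM_GAMMA
    cost = _SVM_COST[::2] if spec.fast else _SVM_COST
    deg = _SVM_DEGREE[:1] if spec.fast else _SVM_DEGREE
    if spec.outcome == "continuous_ic50":
        if spec.method == "linear":
            return LinearRegression(), None, "neg_mean_squared_error"
        if spec.method == "elastic_net":
            return (ElasticNet(l1_ratio=0.5, max_iter=20000),
                    {"alpha": lam}, "neg_mean_squared_error")
        if spec.method == "l1":
            return Lasso(max_iter=20000), {"alpha": lam}, "neg_mean_squared_error"
        if spec.method == "l2":
            return Ridge(), {"alpha": lam}, "neg_mean_squared_error"
    else:
        if spec.method == "logistic":
            return LogisticRegression(penalty=None, max_iter=2000), None, "accuracy"
        if spec.method == "elastic_net":
            return (LogisticRegression(penalty="elasticnet", l1_ratio=0.5,
                                       solver="saga", max_iter=5000),
                    {"C": cs}, "accuracy")
        if spec.method == "l1":
            return (LogisticRegression(penalty="l1", solver="liblinear", max_iter=5000),
                    {"C": cs}, "accuracy")
        if spec.method == "l2":
            return LogisticRegression(max_iter=5000), {"C": cs}, "accuracy"
        if spec.method == "svm_linear":
            return SVC(kernel="linear"), {"C": cost}, "accuracy"
        if spec.method == "svm_poly":
            return (SVC(kernel="poly"),
                    {"degree": deg, "gamma": gam, "C": cost}, "accuracy")
        if spec.method == "random_forest":
            return (RandomForestClassifier(n_estimators=500, random_state=spec.seed),
                    None, "accuracy")
    raise ValueError(f"unsupported spec {spec}")


def _features(spec: ModelSpec, m: ExpressionMatrix, genes: list[str],
              train: list[str], test: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Design matrices with all scaling fit on the training samples only."""
    sub = m.frame.loc[genes]
    tr = sub.loc[:, train].to_numpy()
    te = sub.loc[:, test].to_numpy()
    mu = tr.mean(axis=1, keepdims=True)
    sd = tr.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    ztr = (tr - mu) / sd
    zte = (te - mu) / sd
    if spec.input_kind == "score":
        return np.median(ztr, axis=0)[:, None], np.median(zte, axis=0)[:, None]
    return ztr.T, zte.T


def fit_predict_cv(
    spec: ModelSpec,
    m: ExpressionMatrix,
    resp: DrugResponseTable,
    genes: set[str],
    samples: set[str] | None = None,
) -> ModelResult:
    """Outer 5-fold CV fit/predict for one model spec.

    ``samples`` restricts the dataset (e.g. a quintile subset computed by the
    caller); by default all response-table samples present in the matrix are
    used. Returns NaN for degenerate folds (single-class training data or a
    constant prediction), which are skipped with a warning.
    """
    gene_list = [g for g in m.gene_ids if g in genes]
    if not gene_list:
        raise ValueError("no signature genes present in the matrix")
    pool = sorted(samples if samples is not None else
                  set(resp.sample_ids) & set(m.sample_ids))
    if len(pool) < 10:
        raise ValueError("need at least 10 samples")

    if spec.outcome == "binary_ic50":
        y_all = make_binary_outcome(resp, set(pool))
        metric_name = "auc"
        splitter = StratifiedKFold(5, shuffle=True, random_state=spec.seed)
        split_iter = splitter.split(pool, y_all.loc[pool])
    else:
        y_all = resp.ic50.loc[pool]
        metric_name = "spearman_rho"
        splitter = KFold(5, shuffle=True, random_state=spec.seed)
        split_iter = splitter.split(pool)

    per_fold, n_tr, n_te = [], [], []
    for tr_idx, te_idx in split_iter:
        train = [pool[i] for i in tr_idx]
        test = [pool[i] for i in te_idx]
        xtr, xte = _features(spec, m, gene_list, train, test)
        ytr = y_all.loc[train].to_numpy()
        yte = y_all.loc[test].to_numpy()
        n_tr.append(len(train))
        n_te.append(len(test))

        if spec.outcome == "binary_ic50" and (len(np.unique(ytr)) < 2
                                              or len(np.unique(yte)) < 2):
            log.warning("degenerate fold (single class); skipped")
            per_fold.append(float("nan"))
            continue

        est, grid, scoring = _estimator(spec)
        if grid:
            inner = min(spec.inner_cv, len(train))
            est = GridSearchCV(est, grid, cv=inner, scoring=scoring, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(xtr, ytr)

            if spec.outcome == "continuous_ic50":
                pred = est.predict(xte)
                if np.std(pred) == 0 or np.std(yte) == 0:
                    per_fold.append(float("nan"))
                    continue
                per_fold.append(float(stats.spearmanr(yte, pred).statistic))
            else:
                fitted = est.best_estimator_ if grid else est
                if hasattr(fitted, "predict_proba"):
                    score = fitted.predict_proba(xte)[:, 1]
                else:
                    score = fitted.decision_function(xte)
                if np.std(score) == 0:
                    per_fold.append(float("nan"))
                    continue
                per_fold.append(float(roc_auc_score(yte, score)))

    if not np.isfinite(per_fold).any():
        raise ValueError("all folds degenerate; no metric available")
    return ModelResult(spec, per_fold, metric_name, n_tr, n_te)


def _table_specs(seed: int = 1, fast: bool = False) -> list[ModelSpec]:
    rows: list[ModelSpec] = []
    for subset in ("all", "quintiles"):
        rows.append(ModelSpec("score", "continuous_ic50", "linear", subset, seed, fast=fast))
        for meth in ("elastic_net", "l1", "l2"):
            rows.append(ModelSpec("per_gene", "continuous_ic50", meth, subset, seed, fast=fast))
        for meth in ("logistic", "elastic_net", "l1", "l2", "svm_linear",
                     "svm_poly", "random_forest"):
            rows.append(ModelSpec("per_gene", "binary_ic50", meth, subset, seed, fast=fast))
    return rows


#: the 22-row suite: 4 continuous and 7 binary methods, each on all samples
#: and on the score-quintile subset
TABLE_SPECS = _table_specs()
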