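"""Forward-selected LR and RBF-SVM models of time-to-treatment, LOOCV-validated.

The regression target is the continuous TTT in months; the classification
target is whether a subject's TTT falls at or below the cohort median
("early treatment", the positive class) or above it.  Feature selection
is greedy forward selection up to four predictors, scored on the full
cohort (R-squared for LR, accuracy for SVM) exactly as a two-step
select-then-validate protocol does — which leaks selection information
into the subsequent leave-one-out estimate; a ``nested=True`` mode
re-runs selection inside every fold for honest estimates.

Inside each LOOCV fold, features are z-scored with the training fold's
mean and sample SD (applied to the held-out subject), the model is refit,
and the single held-out prediction retained.  Test metrics pool the K
held-out predictions; training metrics are fold averages.  Held-out
R-squared is 1 - SSE/SST with SST about the held-out outcomes' own mean,
so it can be negative.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .imaging_io import FeatureTable

log = logging.getLogger("petww")

MAX_FEATURES = 4
SVM_C = 1.0
SVM_GAMMA = "scale"  # 1 / (n_features * pooled feature variance)


@dataclasses.dataclass
class OutcomeRecord:
    """One subject's outcome: months to treatment start (or censoring)."""

    subject_id: str
    ttt_months: float
    event: bool  # treatment started

    def __post_init__(self) -> None:
        if not self.ttt_months > 0:
            raise ValueError("ttt_months must be strictly positive")


def median_class_labels(ttt_months) -> np.ndarray:
    """Early-treatment class labels: True where TTT <= cohort median."""
    t = np.asarray(ttt_months, dtype=float)
    return t <= np.median(t)


def zscore(table: FeatureTable) -> FeatureTable:
    """Standardise every feature column to mean 0, sample SD 1."""
    feats = table.features()
    sd = feats.std(ddof=1)
    bad = sd.index[~(sd > 0)]
    if len(bad):
        raise ValueError(f"zero-SD feature column(s): {list(bad)}")
    return table.with_features((feats - feats.mean()) / sd)


def _zscore_df(train: pd.DataFrame, apply_to: pd.DataFrame) -> np.ndarray:
    mu = train.mean().to_numpy()
    sd = train.std(ddof=1).to_numpy()
    sd = np.where(sd > 0, sd, 1.0)
    return (apply_to.to_numpy(dtype=float) - mu) / sd


def _ols_fit_predict(Xtr, ytr, Xte):
    A = np.column_stack([np.ones(len(Xtr)), Xtr])
    beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    yhat_tr = A @ beta
    yhat_te = np.column_stack([np.ones(len(Xte)), Xte]) @ beta
    return yhat_tr, yhat_te


def _r2(y, yhat) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst if sst > 0 else 0.0


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def svm_fit(X, labels, C: float = SVM_C, gamma=SVM_GAMMA) -> SVC:
    """Soft-margin SVM with radial kernel exp(-gamma * ||u-v||^2)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM requires two classes in the training data")
    clf = SVC(C=C, gamma=gamma, kernel="rbf", random_state=0)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def _svm_scores(clf: SVC, X) -> np.ndarray:
    """Signed decision scores oriented so positive = early-treatment class."""
    s = clf.decision_function(np.asarray(X, dtype=float))
    return s if clf.classes_[-1] == 1 else -s


def _full_cohort_score(feats: pd.DataFrame, outcome, cols: list[str], model_kind: str) -> float:
    X = _zscore_df(feats[cols], feats[cols])
    if model_kind == "LR":
        y = np.asarray(outcome, dtype=float)
        yhat, _ = _ols_fit_predict(X, y, X[:0])
        return _r2(y, yhat)
    labels = np.asarray(outcome, dtype=int)
    clf = svm_fit(X, labels)
    return float(np.mean(clf.predict(X) == labels))


def forward_select(
    table: FeatureTable,
    outcome,
    model_kind: str,
    max_k: int = MAX_FEATURES,
) -> tuple[list[str], list[float]]:
    """Greedy forward selection scored on the full cohort.

    ``outcome`` is continuous TTT for ``model_kind="LR"`` and binary class
    labels for ``"SVM"``.  Returns the nested selection order and the
    full-cohort criterion value after each addition.  Ties break in
    feature-registry (column) order.
    """
    if model_kind not in ("LR", "SVM"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    feats = table.features()
    if len(feats.columns) < max_k:
        raise ValueError(f"need at least {max_k} features, have {len(feats.columns)}")
    if table.n_subjects < max_k + 1:
        raise ValueError(
            f"need more subjects ({table.n_subjects}) than features to select ({max_k})"
        )
    selected: list[str] = []
    path_scores: list[float] = []
    remaining = list(feats.columns)
    for _ in range(max_k):
        best_col, best_score = None, -np.inf
        for col in remaining:
            score = _full_cohort_score(feats, outcome, selected + [col], model_kind)
            if score > best_score:
                best_col, best_score = col, score
        selected.append(best_col)
        remaining.remove(best_col)
        path_scores.append(best_score)
    return selected, path_scores


def loocv(
    table: FeatureTable,
    outcome,
    feature_subset: Sequence[str],
    model_kind: str,
) -> dict:
    """Leave-one-out validation of one fixed feature subset.

    Returns pooled test metrics, fold-averaged training metrics and the
    per-fold held-out predictions.
    """
    feats = table.features()[list(feature_subset)]
    n = len(feats)
    if n < 3:
        raise ValueError("LOOCV requires at least 3 subjects")
    ids = feats.index.to_numpy()
    if model_kind == "LR":
        y = np.asarray(outcome, dtype=float)
        preds = np.empty(n)
        tr_rmse, tr_r2 = [], []
        for i in range(n):
            tr = np.arange(n) != i
            Xtr = _zscore_df(feats.iloc[tr], feats.iloc[tr])
            Xte = _zscore_df(feats.iloc[tr], feats.iloc[[i]])
            yhat_tr, yhat_te = _ols_fit_predict(Xtr, y[tr], Xte)
            preds[i] = yhat_te[0]
            tr_rmse.append(_rmse(y[tr], yhat_tr))
            tr_r2.append(_r2(y[tr], yhat_tr))
        return {
            "model": "LR",
            "features": list(feature_subset),
            "test": {"rmse": _rmse(y, preds), "r2": _r2(y, preds)},
            "train": {"rmse": float(np.mean(tr_rmse)), "r2": float(np.mean(tr_r2))},
            "predictions": pd.DataFrame(
                {"subject_id": ids, "y_true": y, "y_pred": preds}
            ),
        }

    labels = np.asarray(outcome, dtype=int)
    preds = np.full(n, -1, dtype=int)
    scores = np.full(n, np.nan)
    tr_acc, tr_prec, tr_sens, tr_auc = [], [], [], []
    skipped = []
    for i in range(n):
        tr = np.arange(n) != i
        ytr = labels[tr]
        if len(np.unique(ytr)) < 2:
            skipped.append(ids[i])
            log.warning("LOOCV fold %s skipped: single-class training set", ids[i])
            continue
        Xtr = _zscore_df(feats.iloc[tr], feats.iloc[tr])
        Xte = _zscore_df(feats.iloc[tr], feats.iloc[[i]])
        clf = svm_fit(Xtr, ytr)
        preds[i] = int(clf.predict(Xte)[0])
        scores[i] = _svm_scores(clf, Xte)[0]
        phat = clf.predict(Xtr)
        str_ = _svm_scores(clf, Xtr)
        tr_acc.append(float(np.mean(phat == ytr)))
        tp = np.sum((phat == 1) & (ytr == 1))
        tr_prec.append(float(tp / max(np.sum(phat == 1), 1)))
        tr_sens.append(float(tp / max(np.sum(ytr == 1), 1)))
        tr_auc.append(float(roc_auc_score(ytr, str_)))
    ok = preds >= 0
    yv, pv, sv = labels[ok], preds[ok], scores[ok]
    tp = np.sum((pv == 1) & (yv == 1))
    test = {
        "accuracy": float(np.mean(pv == yv)),
        "precision": float(tp / max(np.sum(pv == 1), 1)),
        "sensitivity": float(tp / max(np.sum(yv == 1), 1)),
        "auc": float(roc_auc_score(yv, sv)) if len(np.unique(yv)) == 2 else float("nan"),
    }
    return {
        "model": "SVM",
        "features": list(feature_subset),
        "test": test,
        "train": {
            "accuracy": float(np.mean(tr_acc)),
            "precision": float(np.mean(tr_prec)),
            "sensitivity": float(np.mean(tr_sens)),
            "auc": float(np.mean(tr_auc)),
        },
        "skipped_folds": skipped,
        "predictions": pd.DataFrame(
            {"subject_id": ids[ok], "y_true": yv, "y_pred": pv, "score": sv}
        ),
    }


@dataclasses.dataclass
class CvReport:
    """Selection order plus training/testing metrics for k = 1..max_k."""

    model_kind: str
    selected: list[str]                  # nested order, length max_k
    selection_scores: list[float]        # full-cohort criterion per k
    per_k: dict[int, dict]               # k -> loocv() result

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for k, res in sorted(self.per_k.items()):
            for split in ("train", "test"):
                for metric, value in res[split].items():
                    rows.append(
                        {
                            "model": self.model_kind,
                            "k": k,
                            "features": "|".join(res["features"]),
                            "split": split,
                            "metric": metric,
                            "value": value,
                        }
                    )
        return pd.DataFrame(rows)


def cv_report(
    table: FeatureTable,
    outcome,
    model_kind: str,
    max_k: int = MAX_FEATURES,
    nested: bool = False,
) -> CvReport:
    """Forward selection followed by LOOCV at every subset size 1..max_k.

    With ``nested=True`` the selection itself is redone inside each fold
    (honest generalisation estimates); the reported selection order then
    comes from the full cohort but test metrics do not reuse it.
    """
    selected, path = forward_select(table, outcome, model_kind, max_k=max_k)
    per_k: dict[int, dict] = {}
    for k in range(1, max_k + 1):
        if not nested:
            per_k[k] = loocv(table, outcome, selected[:k], model_kind)
        else:
            per_k[k] = _nested_loocv(table, outcome, model_kind, k)
    return CvReport(model_kind=model_kind, selected=selected,
                    selection_scores=path, per_k=per_k)


def _nested_loocv(table: FeatureTable, outcome, model_kind: str, k: int) -> dict:
    """LOOCV where forward selection is re-run within every training fold."""
    feats = table.features()
    n = table.n_subjects
    y = np.asarray(outcome)
    if model_kind == "LR":
        preds = np.empty(n)
        for i in range(n):
            tr = np.arange(n) != i
            sub = FeatureTable(table.data.loc[tr].copy())
            sel, _ = forward_select(sub, y[tr], model_kind, max_k=k)
            Xtr = _zscore_df(feats.iloc[tr][sel], feats.iloc[tr][sel])
            Xte = _zscore_df(feats.iloc[tr][sel], feats.iloc[[i]][sel])
            _, yhat_te = _ols_fit_predict(Xtr, y[tr].astype(float), Xte)
            preds[i] = yhat_te[0]
        yf = y.astype(float)
        return {
            "model": "LR", "features": [f"nested(k={k})"],
            "test": {"rmse": _rmse(yf, preds), "r2": _r2(yf, preds)},
            "train": {}, "predictions": pd.DataFrame({"y_true": yf, "y_pred": preds}),
        }
    labels = y.astype(int)
    preds = np.full(n, -1, dtype=int)
    scores = np.full(n, np.nan)
    for i in range(n):
        tr = np.arange(n) != i
        if len(np.unique(labels[tr])) < 2:
            continue
        sub = FeatureTable(table.data.loc[tr].copy())
        sel, _ = forward_select(sub, labels[tr], model_kind, max_k=k)
        Xtr = _zscore_df(feats.iloc[tr][sel], feats.iloc[tr][sel])
        Xte = _zscore_df(feats.iloc[tr][sel], feats.iloc[[i]][sel])
        clf = svm_fit(Xtr, labels[tr])
        preds[i] = int(clf.predict(Xte)[0])
        scores[i] = _svm_scores(clf, Xte)[0]
    ok = preds >= 0
    yv, pv, sv = labels[ok], preds[ok], scores[ok]
    tp = np.sum((pv == 1) & (yv == 1))
    return {
        "model": "SVM", "features": [f"nested(k={k})"],
        "test": {
            "accuracy": float(np.mean(pv == yv)),
            "precision": float(tp / max(np.sum(pv == 1), 1)),
            "sensitivity": float(tp / max(np.sum(yv == 1), 1)),
            "auc": float(roc_auc_score(yv, sv)) if len(np.unique(yv)) == 2 else float("nan"),
        },
        "train": {},
        "predictions": pd.DataFrame({"y_true": yv, "y_pred": pv, "score": sv}),
    }
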