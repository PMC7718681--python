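"""Leave-one-out diagnosis and SARA-anchored severity estimation.

Diagnosis: LD / QDA / SVM / KNN classifiers evaluated by leave-one-out
cross-validation over subjects, with per-fold standardisation; metrics
(ACC, Recall, Precision, F1, MCC, AUC) from the pooled held-out confusion
counts and scores.  Severity: ridge regression of the SARA upper-limb sum,
held-out predicted scores ps bucketed into the 4-level scale
(ps<4 normal, 4<=ps<7 mild, 7<=ps<10 moderate, ps>=10 severe) and compared
with the clinical levels in an agreement matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.linear_model import RidgeCV
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core_io import AnalysisConfig, catalog_frame
from .selection import selection_frequency
from .stats_inference import spearman

logger = logging.getLogger("ataxkit")

MODELS = ("LD", "QDA", "SVM", "KNN")
LEVEL_EDGES = (4.0, 7.0, 10.0)   # ps bucket boundaries, half-open as printed

TEST_GROUPS: dict[str, tuple[str, ...]] = {
    "G1": ("FCT", "FTT"),
    "G2": ("FCT", "FNT"),
    "G3": ("FCT", "DDKT"),
    "G4": ("FCT", "FNT", "DDKT"),
    "G5": ("FCT", "FTT", "DDKT"),
    "G6": ("FCT", "FTT", "FNT"),
    "all": ("FCT", "FTT", "FNT", "DDKT"),
}


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    recall: float
    precision: float
    f1: float
    mcc: float
    auc: float | None = None


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int,
                           scores: np.ndarray | None = None,
                           labels: np.ndarray | None = None) -> Metrics:
    """Standard binary metrics from confusion counts; AUC from held-out scores.

    MCC uses the 2x2 covariance formula; a zero denominator (a degenerate
    margin) is reported as 0 and logged, keeping the metric defined on
    all-one-class predictions.
    """
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("confusion counts must be non-negative, total > 0")
    total = tp + fp + tn + fn
    acc = (tp + tn) / total
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        logger.info("MCC denominator zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    auc = None
    if scores is not None and labels is not None:
        auc = float(roc_auc_score(labels, scores))
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn, acc=acc, recall=recall,
                   precision=precision, f1=f1, mcc=mcc, auc=auc)


# --------------------------------------------------------------------------
# classifiers under leave-one-out
# --------------------------------------------------------------------------

def _make_model(name: str, X_train: np.ndarray, cfg: AnalysisConfig,
                seed: int):
    if name == "LD":
        return LinearDiscriminantAnalysis()
    if name == "QDA":
        # eigen solver + shrinkage keeps class covariances invertible on
        # folds where a class has fewer subjects than features
        return QuadraticDiscriminantAnalysis(solver="eigen",
                                             shrinkage=cfg.qda_shrinkage)
    if name == "SVM":
        # median-heuristic RBF bandwidth on the (standardised) training fold
        med = np.median(pdist(X_train))
        gamma = 1.0 / (2 * med ** 2) if med > 0 else "scale"
        return SVC(kernel="rbf", gamma=gamma, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=cfg.knn_k)
    raise ValueError(f"unknown model {name!r}; choose from {MODELS}")


def _score_of(model, x: np.ndarray) -> float:
    if hasattr(model, "decision_function"):
        return float(model.decision_function(x)[0])
    if hasattr(model, "predict_proba"):
        return float(model.predict_proba(x)[0, 1])
    return float(model.predict(x)[0])


@dataclass
class EvaluationReport:
    """Pooled LOO diagnosis metrics plus per-subject severity outputs."""

    metrics: Metrics | None = None
    scores: pd.Series | None = None          # held-out classifier scores
    predictions: pd.Series | None = None     # held-out class predictions
    ps: pd.Series | None = None              # held-out severity scores
    predicted_level: pd.Series | None = None
    rho: float | None = None                 # Spearman(ps, SARA-UL)
    agreement: pd.DataFrame | None = None    # 4x4 predicted vs clinical level


def _clean(features: pd.DataFrame, *arrays):
    """Drop subjects with any missing feature used by the model (logged)."""
    ok = features.notna().all(axis=1)
    if not ok.all():
        logger.info("excluding %d subjects with missing features from fit",
                    int((~ok).sum()))
    mask = ok.to_numpy()
    return (features[ok],
            *[np.asarray(a)[mask] for a in arrays])


def loo_classify(features: pd.DataFrame, labels: np.ndarray,
                 model: str = "QDA",
                 config: AnalysisConfig | None = None,
                 seed: int = 0) -> EvaluationReport:
    """Leave-one-out diagnosis: one held-out prediction + score per subject.

    Labels are 1 = ataxic (positive class), 0 = control.  Features are
    standardised on each training fold only; metrics come from the pooled
    confusion counts and AUC from the pooled held-out scores.
    """
    cfg = config or AnalysisConfig()
    features, labels = _clean(features, labels)
    labels = labels.astype(int)
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least 2 subjects per class")
    X = features.to_numpy(dtype=float)
    preds = np.zeros(len(X), dtype=int)
    scores = np.zeros(len(X))
    for i in range(len(X)):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        mu, sd = X[mask].mean(axis=0), X[mask].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[mask] - mu) / sd
        xte = ((X[i] - mu) / sd)[None, :]
        clf = _make_model(model, Xtr, cfg, seed)
        clf.fit(Xtr, labels[mask])
        preds[i] = int(clf.predict(xte)[0])
        scores[i] = _score_of(clf, xte)
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    m = metrics_from_confusion(tp, fp, tn, fn, scores=scores, labels=labels)
    return EvaluationReport(
        metrics=m,
        scores=pd.Series(scores, index=features.index),
        predictions=pd.Series(preds, index=features.index))


# --------------------------------------------------------------------------
# severity regression and bucketing
# --------------------------------------------------------------------------

def bucket(ps: float) -> int:
    """Map a predicted severity score to the 4-level scale."""
    if not np.isfinite(ps):
        raise ValueError("ps must be finite")
    return int(np.searchsorted(LEVEL_EDGES, ps, side="right"))


def agreement_matrix(predicted_levels: np.ndarray,
                     clinical_levels: np.ndarray) -> pd.DataFrame:
    """4x4 count matrix, clinical level in rows, predicted level in columns."""
    mat = np.zeros((4, 4), dtype=int)
    for c, p in zip(clinical_levels, predicted_levels):
        mat[int(min(c, 3)), int(p)] += 1
    idx = pd.Index(range(4), name="clinical_level")
    return pd.DataFrame(mat, index=idx,
                        columns=pd.Index(range(4), name="predicted_level"))


def loo_severity(features: pd.DataFrame, sara_ul: np.ndarray,
                 config: AnalysisConfig | None = None) -> EvaluationReport:
    """Held-out ridge severity scores ps, their SARA correlation and levels.

    The ridge penalty is chosen by inner leave-one-out over a log grid
    within each outer training fold; features are standardised per fold.
    """
    cfg = config or AnalysisConfig()
    features, y = _clean(features, np.asarray(sara_ul, dtype=float))
    if np.allclose(y, y[0]):
        raise ValueError("zero-variance severity response")
    X = features.to_numpy(dtype=float)
    ps = np.zeros(len(X))
    for i in range(len(X)):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        mu, sd = X[mask].mean(axis=0), X[mask].std(axis=0)
        sd[sd == 0] = 1.0
        reg = RidgeCV(alphas=cfg.ridge_grid)  # efficient inner LOO
        reg.fit((X[mask] - mu) / sd, y[mask])
        ps[i] = float(reg.predict(((X[i] - mu) / sd)[None, :])[0])
    rho, _ = spearman(ps, y)
    levels = np.array([bucket(v) for v in ps])
    clinical = np.array([int(round(v / 3.0)) for v in y])
    return EvaluationReport(
        ps=pd.Series(ps, index=features.index),
        predicted_level=pd.Series(levels, index=features.index),
        rho=rho,
        agreement=agreement_matrix(levels, clinical))


# --------------------------------------------------------------------------
# test-combination evaluation
# --------------------------------------------------------------------------

def evaluate_test_groups(features: pd.DataFrame, labels: np.ndarray,
                         sara_ul: np.ndarray,
                         groups: dict[str, tuple[str, ...]] | None = None,
                         model: str = "QDA", top_k: int | None = None,
                         n_iter: int = 100, alpha: float = 0.05,
                         seed: int = 0,
                         config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Re-run selection + LOO diagnosis + severity per test combination.

    Restricts the catalog to each group's tests, reselects the top-k
    features by FBE frequency, and reports the pooled metrics plus the
    severity correlation — one row per group.  Also reports the STAR
    composition (percent per domain) of each group's selected features.
    """
    cfg = config or AnalysisConfig()
    k = top_k or cfg.top_k
    groups = groups or TEST_GROUPS
    cat = catalog_frame()
    rows = []
    for gname, tests in groups.items():
        cols = [c for c in features.columns if cat.loc[c, "test"] in tests]
        if not cols:
            raise ValueError(f"group {gname}: no features from tests {tests}")
        sub = features[cols]
        report = selection_frequency(sub, sara_ul, n_iter=n_iter, alpha=alpha,
                                     seed=seed, groups=labels,
                                     subsample_fraction=cfg.subsample_fraction)
        chosen = report.top_k(min(k, len(cols)))
        clf = loo_classify(sub[chosen], labels, model=model, config=cfg,
                           seed=seed)
        sev = loo_severity(sub[chosen], sara_ul, config=cfg)
        star_pct = (cat.loc[chosen, "star"].value_counts(normalize=True)
                    * 100.0)
        m = clf.metrics
        rows.append({
            "group": gname, "tests": "+".join(tests), "n_features": len(chosen),
            "acc": m.acc, "auc": m.auc, "recall": m.recall,
            "precision": m.precision, "f1": m.f1, "mcc": m.mcc,
            "rho": sev.rho,
            **{f"star_{d}_pct": float(star_pct.get(d, 0.0))
               for d in ("Stability", "Timing", "Accuracy", "Rhythmicity")},
        })
    return pd.DataFrame(rows).set_index("group")
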