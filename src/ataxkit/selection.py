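"""Feature selection: backward elimination with selection frequency (FBE)
plus baseline rankers (random forest, RELIEF, LASSO).

FBE repeatedly (default 100 times) draws 90% of subjects, fits a linear
model of the continuous severity response on the candidate features, and
backward-eliminates the feature with the largest partial p-value until every
survivor is significant at alpha.  The fraction of runs in which a feature
survives is its selection frequency, the primary ranking statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import lasso_path
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("ataxkit")

METHODS = ("FBE", "RF", "RELIEF", "LASSO")


# --------------------------------------------------------------------------
# linear-model backward elimination
# --------------------------------------------------------------------------

def _ols_feature_stats(X: np.ndarray, y: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature partial p-values and F statistics of y ~ 1 + X.

    The partial F-test of dropping a single column from the full model
    equals the squared coefficient t-test, so p-values come from the t
    distribution.  A singular normal matrix triggers a ridge-stabilised
    refit (logged).
    """
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    gram = A.T @ A
    # a vanishing jitter keeps near-collinear designs numerically honest:
    # redundant columns then show the huge standard errors they deserve
    gram += 1e-10 * np.trace(gram) / gram.shape[0] * np.eye(gram.shape[0])
    try:
        beta = np.linalg.solve(gram, A.T @ y)
        cov_unscaled = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        logger.info("singular design (%d x %d): ridge-stabilised refit", n, k)
        gram += 1e-6 * np.trace(gram) / gram.shape[0] * np.eye(gram.shape[0])
        beta = np.linalg.solve(gram, A.T @ y)
        cov_unscaled = np.linalg.inv(gram)
    resid = y - A @ beta
    dof = n - k - 1
    if dof <= 0:
        raise ValueError("more parameters than observations")
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(sigma2 * np.diag(cov_unscaled), 1e-300))
    t = np.clip(beta / se, -1e150, 1e150)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return p[1:], t[1:] ** 2  # drop intercept


def _prefilter(X: pd.DataFrame, y: np.ndarray, max_features: int
               ) -> pd.DataFrame:
    """Marginal-|correlation| prefilter used only when features exceed rows."""
    sd = X.std(ddof=0).to_numpy()
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs((X.to_numpy() - X.to_numpy().mean(0)).T @ yc) \
            / (sd * len(y) * (yc.std() + 1e-300))
    corr = np.nan_to_num(corr)
    keep = np.argsort(-corr)[:max_features]
    logger.info("prefilter: %d -> %d features (p > n guard)",
                X.shape[1], len(keep))
    return X.iloc[:, np.sort(keep)]


def fbe_once(features: pd.DataFrame, response: np.ndarray,
             alpha: float = 0.05,
             rng: np.random.Generator | None = None,
             groups: np.ndarray | None = None,
             subsample_fraction: float = 0.9
             ) -> tuple[set[str], dict[str, float]]:
    """One backward-elimination pass on a stratified 90% row subsample.

    Returns the surviving feature set and, for each survivor, its partial F
    in the final model (used downstream as a tie-break).  Null hypothesis per
    step: the examined feature is independent of the response given the
    remaining features; the feature with the largest partial p-value > alpha
    is dropped until all survivors have p <= alpha.
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(response, dtype=float)
    n = len(features)
    n_sub = max(2, int(round(subsample_fraction * n)))
    if groups is not None:
        idx_parts = []
        groups = np.asarray(groups)
        for g in np.unique(groups):
            g_idx = np.nonzero(groups == g)[0]
            take = max(1, int(round(subsample_fraction * g_idx.size)))
            idx_parts.append(rng.choice(g_idx, size=take, replace=False))
        idx = np.sort(np.concatenate(idx_parts))
    else:
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
    Xs, ys = features.iloc[idx], y[idx]

    if Xs.shape[1] > Xs.shape[0] - 2:
        Xs = _prefilter(Xs, ys, Xs.shape[0] - 2)

    cols = list(Xs.columns)
    Xm = Xs.to_numpy(dtype=float)
    while cols:
        p, f = _ols_feature_stats(Xm, ys)
        worst = int(np.argmax(p))
        if p[worst] <= alpha:
            return set(cols), dict(zip(cols, f))
        del cols[worst]
        Xm = np.delete(Xm, worst, axis=1)
    return set(), {}


@dataclass
class SelectionReport:
    """Per-feature FBE selection frequencies and baseline rankings."""

    frequency: pd.Series                 # in [0, 1], indexed by feature name
    alpha: float
    n_iter: int
    subsample_fraction: float
    mean_partial_f: pd.Series = field(default=None)  # tie-break statistic
    rankings: dict[str, list[str]] = field(default_factory=dict)

    def ranking(self, method: str = "FBE") -> list[str]:
        if method == "FBE":
            order = sorted(
                self.frequency.index,
                key=lambda c: (-self.frequency[c],
                               -float(self.mean_partial_f.get(c, 0.0)), c))
            return order
        if method in self.rankings:
            return self.rankings[method]
        raise KeyError(f"no ranking for method {method!r}")

    def top_k(self, k: int, method: str = "FBE") -> list[str]:
        return self.ranking(method)[:k]


def selection_frequency(features: pd.DataFrame, response: np.ndarray,
                        n_iter: int = 100, alpha: float = 0.05,
                        seed: int | None = None,
                        groups: np.ndarray | None = None,
                        subsample_fraction: float = 0.9) -> SelectionReport:
    """Selection frequency of every feature over ``n_iter`` FBE runs.

    Deterministic given ``seed``.  Rows with any missing feature are dropped
    (logged) before the runs, since the elimination model cannot use them.
    """
    ok = features.notna().all(axis=1)
    if not ok.all():
        logger.info("selection: dropping %d rows with missing features",
                    int((~ok).sum()))
        features = features[ok]
        response = np.asarray(response)[ok.to_numpy()]
        if groups is not None:
            groups = np.asarray(groups)[ok.to_numpy()]
    rng = np.random.default_rng(seed)
    counts = pd.Series(0.0, index=features.columns)
    f_sums = pd.Series(0.0, index=features.columns)
    for _ in range(n_iter):
        survivors, f_stats = fbe_once(features, response, alpha=alpha,
                                      rng=rng, groups=groups,
                                      subsample_fraction=subsample_fraction)
        for c in survivors:
            counts[c] += 1.0
            f_sums[c] += f_stats.get(c, 0.0)
    freq = counts / n_iter
    mean_f = f_sums / counts.replace(0.0, np.nan)
    return SelectionReport(frequency=freq, alpha=alpha, n_iter=n_iter,
                           subsample_fraction=subsample_fraction,
                           mean_partial_f=mean_f.fillna(0.0))


# --------------------------------------------------------------------------
# baseline rankers
# --------------------------------------------------------------------------

def _standardise(X: pd.DataFrame) -> np.ndarray:
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    sd[sd == 0] = 1.0
    return (arr - arr.mean(axis=0)) / sd


def _rank_rf(X: pd.DataFrame, labels: np.ndarray, seed: int) -> list[str]:
    clf = RandomForestClassifier(n_estimators=300, random_state=seed)
    clf.fit(X.to_numpy(), labels)
    imp = permutation_importance(clf, X.to_numpy(), labels, n_repeats=10,
                                 random_state=seed)
    order = np.argsort(-imp.importances_mean)
    return [X.columns[i] for i in order]


def _rank_relief(X: pd.DataFrame, labels: np.ndarray, k: int = 5) -> list[str]:
    # plain ReliefF: reward separation from the k nearest misses, penalise
    # spread among the k nearest hits, per feature, range-normalised
    Z = _standardise(X)
    labels = np.asarray(labels)
    w = np.zeros(Z.shape[1])
    for cls in np.unique(labels):
        same, other = Z[labels == cls], Z[labels != cls]
        kk = min(k + 1, len(same))
        nn_hit = NearestNeighbors(n_neighbors=kk).fit(same)
        nn_miss = NearestNeighbors(n_neighbors=min(k, len(other))).fit(other)
        for x in same:
            _, hi = nn_hit.kneighbors([x])
            _, mi = nn_miss.kneighbors([x])
            hits = same[hi[0][1:]]          # drop the point itself
            misses = other[mi[0]]
            if len(hits):
                w -= np.abs(x - hits).mean(axis=0)
            w += np.abs(x - misses).mean(axis=0)
    order = np.argsort(-w)
    return [X.columns[i] for i in order]


def _rank_lasso(X: pd.DataFrame, labels: np.ndarray) -> list[str]:
    # order of coefficient activation along the regularisation path
    Z = _standardise(X)
    y = np.asarray(labels, dtype=float)
    alphas, coefs, _ = lasso_path(Z, y - y.mean(), alphas=200, eps=1e-4)
    active_at = np.full(Z.shape[1], np.inf)
    for j in range(Z.shape[1]):
        nz = np.nonzero(np.abs(coefs[j]) > 1e-12)[0]
        if nz.size:
            active_at[j] = nz[0]  # path runs from largest alpha down
    max_coef = np.abs(coefs).max(axis=1)
    order = sorted(range(Z.shape[1]),
                   key=lambda j: (active_at[j], -max_coef[j]))
    return [X.columns[j] for j in order]


def rank_features(method: str, features: pd.DataFrame,
                  labels: np.ndarray | None = None,
                  response: np.ndarray | None = None,
                  alpha: float = 0.05, n_iter: int = 100,
                  seed: int = 0,
                  groups: np.ndarray | None = None) -> list[str]:
    """Rank the catalog by one of the four selection methods.

    FBE ranks by selection frequency on the continuous response (ties broken
    by mean partial F); the baselines rank a labelled table by permutation
    importance (RF), relief weights (RELIEF), or activation order along the
    regularisation path (LASSO).
    """
    ok = features.notna().all(axis=1)
    features = features[ok]
    if labels is not None:
        labels = np.asarray(labels)[ok.to_numpy()]
    if response is not None:
        response = np.asarray(response)[ok.to_numpy()]
    if groups is not None:
        groups = np.asarray(groups)[ok.to_numpy()]

    if method == "FBE":
        if response is None:
            if labels is None:
                raise ValueError("FBE needs a response (or labels fallback)")
            # binary-label variant, exposed but not the default usage
            response = labels.astype(float)
        report = selection_frequency(features, response, n_iter=n_iter,
                                     alpha=alpha, seed=seed, groups=groups)
        return report.ranking("FBE")
    if labels is None:
        raise ValueError(f"{method} ranking needs class labels")
    if method == "RF":
        return _rank_rf(features, labels, seed)
    if method == "RELIEF":
        return _rank_relief(features, labels)
    if method == "LASSO":
        return _rank_lasso(features, labels)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
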