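"""Population statistics and outcome prediction.

Three layers: distribution comparisons between compensating and
decompensating subpopulations (Kolmogorov-Smirnov, Anderson-Darling and
chi-square at p < 0.05); single-variable correlations with the pressure
loss; and maximum-margin linear classifiers -- repeated random-split SVM
accuracy trials plus the inductive search for the maximally effective
rubric (MER), the smallest feature set whose held-out accuracy cannot be
sufficiently improved by adding another feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DataError

__all__ = [
    "SIGNIFICANCE",
    "Rubric",
    "compare_distributions",
    "outcome_correlations",
    "svm_accuracy_trials",
    "mer_search",
    "mer_ensemble",
    "feature_columns",
]

SIGNIFICANCE = 0.05

# Columns of the population table that are not predictive features.
NON_FEATURES = ("chain", "patient", "seed",
                "delta_map", "nadir_delta_map", "blood_loss", "outcome")


def feature_columns(table: pd.DataFrame) -> list:
    """All parameters and baseline variables usable as classifier inputs."""
    return [c for c in table.columns if c not in NON_FEATURES]


def compare_distributions(a, b) -> dict:
    """Two-sample KS, Anderson-Darling and chi-square comparison.

    The chi-square test bins both samples into ceil(sqrt(n)) equal-
    probability bins of the pooled sample.  Returns the three statistics
    and p-values plus a ``different`` flag at the fixed 0.05 level.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise DataError("compare_distributions needs at least 5 samples per group")
    ks = stats.ks_2samp(a, b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # AD p-values are capped/floored by scipy
        ad = stats.anderson_ksamp([a, b])
    pooled = np.concatenate([a, b])
    n_bins = int(np.ceil(np.sqrt(len(pooled))))
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    edges[0], edges[-1] = -np.inf, np.inf
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    contingency = np.vstack([ca, cb])
    keep = contingency.sum(axis=0) > 0
    chi2, chi2_p, _, _ = stats.chi2_contingency(contingency[:, keep])
    report = {
        "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
        "ad_stat": float(ad.statistic), "ad_p": float(ad.pvalue),
        "chi2_stat": float(chi2), "chi2_p": float(chi2_p),
    }
    report["different"] = any(report[k] < SIGNIFICANCE for k in ("ks_p", "ad_p", "chi2_p"))
    return report


def outcome_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Pearson r with the pressure loss and a two-group KS test.

    Constant features get r = 0 with a ``constant`` flag instead of NaN.
    """
    if "delta_map" not in table or "outcome" not in table:
        raise DataError("population table lacks hemorrhage outcomes")
    comp = table["outcome"] == "compensator"
    rows = []
    for col in feature_columns(table) + ["delta_map", "blood_loss"]:
        x = table[col].to_numpy(dtype=float)
        constant = np.ptp(x) == 0
        if constant:
            r = 0.0
            ks_p = np.nan
        else:
            r = float(np.corrcoef(x, table["delta_map"])[0, 1])
            ks_p = float(stats.ks_2samp(x[comp], x[~comp]).pvalue)
        rows.append(dict(feature=col, r_delta_map=r, ks_p_outcome=ks_p,
                         significant=bool(ks_p < SIGNIFICANCE) if not constant else False,
                         constant=constant))
    return pd.DataFrame(rows)


def _split(rng, n, test_size, y):
    """Random train/test split, redrawn until the training fold has both classes."""
    for _ in range(1000):
        idx = rng.permutation(n)
        train, test = idx[:-test_size], idx[-test_size:]
        if len(np.unique(y[train])) > 1:
            return train, test
    raise DataError("could not draw a two-class training fold")


def _fit_eval(X, y, train, test, cols=None):
    """Accuracy of a linear SVM trained on the fold (standardized on train only)."""
    Xs = X if cols is None else X[:, cols]
    scaler = StandardScaler().fit(Xs[train])
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(scaler.transform(Xs[train]), y[train])
    acc = float(np.mean(clf.predict(scaler.transform(Xs[test])) == y[test]))
    return acc, clf, scaler


def _fit_eval_scaled(Xtr, Xte, ytr, yte, cols):
    """Accuracy on pre-standardized folds; the hot path of the rubric search."""
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(Xtr[:, cols], ytr)
    return float(np.mean(clf.predict(Xte[:, cols]) == yte)), clf


def svm_accuracy_trials(
    table: pd.DataFrame,
    n_trials: int = 100,
    test_size: int = 75,
    seed=0,
) -> dict:
    """Held-out accuracy of repeated maximum-margin classifiers.

    Each trial draws a uniform random train/test split (225/75 by
    default), standardizes features on the training fold only, trains a
    linear SVM on all parameters and baseline variables, and scores the
    held-out fold.  The confidence interval treats the pooled held-out
    predictions as binomial.
    """
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = (table["outcome"] == "decompensator").to_numpy(dtype=int)
    if len(y) < test_size + 25 or len(np.unique(y)) < 2:
        raise DataError("population too small or single-class for SVM trials")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_trials):
        train, test = _split(rng, len(y), test_size, y)
        acc, _, _ = _fit_eval(X, y, train, test)
        accs.append(acc)
    accs = np.asarray(accs)
    mean = float(accs.mean())
    n_tests = n_trials * test_size
    half = 1.96 * np.sqrt(max(mean * (1 - mean), 1e-12) / n_tests)
    return {
        "accuracies": accs,
        "mean": mean,
        "ci95": (mean - half, mean + half),
        "n_trials": n_trials,
        "test_size": test_size,
    }


@dataclass
class Rubric:
    """A minimal feature set with its maximum-margin classifier."""

    features: tuple
    weights: np.ndarray       # on standardized features
    bias: float
    train_accuracy: float
    test_accuracy: float
    naive_accuracy: float     # majority-class accuracy on the test fold
    is_naive: bool = False    # no single feature beat the naive classifier

    def as_dict(self) -> dict:
        return dict(
            features=list(self.features),
            weights=[float(w) for w in np.atleast_1d(self.weights).ravel()],
            bias=float(self.bias),
            train_accuracy=self.train_accuracy,
            test_accuracy=self.test_accuracy,
            naive_accuracy=self.naive_accuracy,
            is_naive=self.is_naive,
        )


def mer_search(
    table: pd.DataFrame,
    split=None,
    cost_threshold: float = 0.01,
    test_size: int = 75,
    beam: int = 50,
    seed=0,
) -> Rubric:
    """Inductive search for the maximally effective rubric.

    Stage 1 trains a single-feature classifier per feature and retains
    those beating the naive (majority-class) classifier on the held-out
    fold.  Each later stage extends every retained set by one new
    feature and keeps extensions that improve held-out accuracy by at
    least ``cost_threshold``; at most ``beam`` sets survive per stage.
    The search stops when no extension qualifies; the best-accuracy set
    wins, ties broken by fewer features then lexicographic order.
    """
    if cost_threshold <= 0:
        raise DataError("cost_threshold must be positive")
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = (table["outcome"] == "decompensator").to_numpy(dtype=int)
    if split is None:
        rng = np.random.default_rng(seed)
        split = _split(rng, len(y), test_size, y)
    train, test = split
    naive = float(max(np.mean(y[test]), 1 - np.mean(y[test])))

    # features are standardized on the training fold once; classifiers for
    # feature subsets then just slice columns
    scaler = StandardScaler().fit(X[train])
    Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
    ytr, yte = y[train], y[test]

    def key(item):
        feats, acc = item
        return (-acc, len(feats), tuple(cols[j] for j in feats))

    stage = []
    for j in range(len(cols)):
        if np.ptp(Xtr[:, j]) == 0:
            continue
        acc, _ = _fit_eval_scaled(Xtr, Xte, ytr, yte, [j])
        if acc > naive:
            stage.append(((j,), acc))
    if not stage:
        return Rubric(features=(), weights=np.zeros(0), bias=0.0,
                      train_accuracy=naive, test_accuracy=naive,
                      naive_accuracy=naive, is_naive=True)
    stage = sorted(stage, key=key)[:beam]
    best = stage[0]
    while True:
        candidates = {}
        for feats, acc in stage:
            for j in range(len(cols)):
                if j in feats:
                    continue
                nf = tuple(sorted(feats + (j,)))
                if nf in candidates:
                    continue
                a, _ = _fit_eval_scaled(Xtr, Xte, ytr, yte, list(nf))
                if a >= acc + cost_threshold:
                    candidates[nf] = a
        if not candidates:
            break
        stage = sorted(candidates.items(), key=key)[:beam]
        if key(stage[0]) < key(best):
            best = stage[0]
    feats, acc = best
    _, clf = _fit_eval_scaled(Xtr, Xte, ytr, yte, list(feats))
    train_acc = float(np.mean(clf.predict(Xtr[:, feats]) == ytr))
    return Rubric(
        features=tuple(cols[j] for j in feats),
        weights=clf.coef_.ravel(),
        bias=float(clf.intercept_[0]),
        train_accuracy=train_acc,
        test_accuracy=acc,
        naive_accuracy=naive,
    )


def mer_ensemble(
    table: pd.DataFrame,
    n_repeats: int = 37,
    cost_threshold: float = 0.01,
    seed=0,
    test_size: int = 75,
    beam: int = 50,
) -> dict:
    """Repeat the rubric search on independent random splits.

    Reports how often each feature appears, the mean rubric size, and
    the mean held-out accuracy of the returned rubrics.
    """
    cols = feature_columns(table)
    y = (table["outcome"] == "decompensator").to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    rubrics = []
    for _ in range(n_repeats):
        split = _split(rng, len(y), test_size, y)
        rubrics.append(mer_search(table, split=split, cost_threshold=cost_threshold,
                                  test_size=test_size, beam=beam))
    counts = {c: 0 for c in cols}
    for r in rubrics:
        for f in r.features:
            counts[f] += 1
    freq = (
        pd.DataFrame({"feature": list(counts), "count": list(counts.values())})
        .sort_values(["count", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return {
        "rubrics": rubrics,
        "frequency": freq,
        "mean_size": float(np.mean([len(r.features) for r in rubrics])),
        "mean_accuracy": float(np.mean([r.test_accuracy for r in rubrics])),
    }
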