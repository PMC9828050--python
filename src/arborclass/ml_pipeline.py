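"""Feature orthogonalization (z-score + PCA) and supervised classification.

The classification stage mirrors a standard morphometric workflow: the 19
per-cell features are z-scored, orthogonalized by PCA, and the leading
components that together explain at least a retention fraction (default
0.95) of the variance are fed to three classifiers — k-nearest neighbors
(K = 5, Euclidean), a support vector machine with radial kernel, and a
random forest (500 trees, 5 variables per split) — evaluated by repeated
stratified k-fold cross-validation (default 10 folds, 10 repeats) with
sensitivity, specificity, accuracy per fold and a pooled rank-based AUC.

Neurons are the positive class for sensitivity throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

NEURON = "neuron"
GLIA = "glia"


# ---------------------------------------------------------------------------
# standardization


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score each feature column (sample sd, n-1 divisor).

    Constant columns cannot be standardized; they are dropped with a
    warning.  Returns the z-scored table and the per-feature means and
    standard deviations needed to invert the transform.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant feature columns: {constant}")
        table = table.drop(columns=constant)
        means = means.drop(constant)
        sds = sds.drop(constant)
    return (table - means) / sds, means, sds


def destandardize(z: pd.DataFrame, means: pd.Series, sds: pd.Series) -> pd.DataFrame:
    """Invert :func:`standardize`."""
    return z * sds + means


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Fitted PCA with the z-scoring parameters baked in.

    ``loadings`` is (p features × p components), columns orthonormal and
    sign-fixed so each component's largest-magnitude loading is positive.
    ``k_retained`` is the smallest k whose cumulative explained variance
    reaches the retention threshold.
    """

    feature_names: tuple[str, ...]
    means: pd.Series
    sds: pd.Series
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    retention: float
    k_retained: int


def fit_pca(table: pd.DataFrame, retention: float = 0.95) -> PCAModel:
    """Fit PCA on the z-scored feature table.

    Components are ordered by decreasing explained variance; constant
    features are dropped by the internal z-scoring step.
    """
    if len(table) < 2:
        raise ValueError("PCA needs at least 2 cells")
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    z, means, sds = standardize(table)
    X = z.to_numpy(dtype=float)
    # full SVD keeps all p components so the variance fractions sum to 1
    Xc = X - X.mean(axis=0)
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2
    evr = var / var.sum()
    loadings = vt.T  # p × n_components
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip

    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, retention - 1e-12) + 1)
    k = min(k, loadings.shape[1])
    return PCAModel(
        feature_names=tuple(z.columns),
        means=means,
        sds=sds,
        loadings=loadings,
        explained_variance_ratio=evr,
        retention=retention,
        k_retained=k,
    )


def project(model: PCAModel, table: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
    """Scores of cells on the first ``k`` (default ``k_retained``) components."""
    missing = set(model.feature_names) - set(table.columns)
    if missing:
        raise ValueError(f"feature mismatch; table lacks {sorted(missing)}")
    k = model.k_retained if k is None else k
    z = (table[list(model.feature_names)] - model.means) / model.sds
    scores = z.to_numpy(dtype=float) @ model.loadings[:, :k]
    return pd.DataFrame(
        scores, index=table.index, columns=[f"PC{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# classifiers


@dataclass(frozen=True)
class ClassifierSpec:
    """Uniform handle on the three supported classifiers.

    ``name`` is ``knn`` (K = 5 nearest neighbors, Euclidean), ``svm``
    (radial-kernel SVC) or ``rf`` (random forest, 500 trees, 5 features per
    split); ``params`` overrides the defaults.
    """

    name: str
    params: dict = field(default_factory=dict)


def make_classifier(spec: ClassifierSpec, n_features: int, seed: int | None = None):
    if spec.name == "knn":
        return KNeighborsClassifier(**{"n_neighbors": 5, **spec.params})
    if spec.name == "svm":
        return SVC(**{"kernel": "rbf", "gamma": "scale", **spec.params})
    if spec.name == "rf":
        params = {
            "n_estimators": 500,
            "max_features": min(5, n_features),
            "random_state": seed,
            **spec.params,
        }
        return RandomForestClassifier(**params)
    raise ValueError(f"unknown classifier {spec.name!r} (expected knn, svm or rf)")


def _score_for_auc(clf, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Continuous score oriented so that larger means more neuron-like."""
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        col = int(np.where(clf.classes_ == NEURON)[0][0])
        return proba[:, col]
    s = clf.decision_function(X)
    # decision_function is oriented toward classes_[1]
    return s if clf.classes_[1] == NEURON else -s


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    predictions: Sequence[str], truth: Sequence[str], scores: Sequence[float] | None = None
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, AUC); neuron is positive.

    Sensitivity is the fraction of neurons called neuron, specificity the
    fraction of glia called glia; AUC is the rank (Mann-Whitney) statistic
    of ``scores`` (larger = more neuron-like), NaN when scores are absent.
    """
    pred = np.asarray(predictions)
    y = np.asarray(truth)
    pos = y == NEURON
    neg = y == GLIA
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present in the truth labels")
    sens = float((pred[pos] == NEURON).mean())
    spec = float((pred[neg] == GLIA).mean())
    acc = float((pred == y).mean())
    auc = float("nan")
    if scores is not None:
        auc = float(roc_auc_score(pos.astype(int), np.asarray(scores, dtype=float)))
    return sens, spec, acc, auc


@dataclass
class CVResult:
    """Repeated k-fold cross-validation outcome for one classifier."""

    classifier: str
    k: int
    repeats: int
    seed: int | None
    fold_metrics: pd.DataFrame  # columns: repeat, fold, sensitivity, specificity, accuracy
    pooled_auc: float
    fold_mean_auc: float

    @property
    def sensitivity(self) -> float:
        return float(self.fold_metrics["sensitivity"].mean())

    @property
    def specificity(self) -> float:
        return float(self.fold_metrics["specificity"].mean())

    @property
    def accuracy(self) -> float:
        return float(self.fold_metrics["accuracy"].mean())

    def to_report(self) -> pd.DataFrame:
        """Per-fold rows plus a summary row."""
        summary = pd.DataFrame(
            {
                "repeat": ["all"],
                "fold": ["mean"],
                "sensitivity": [self.sensitivity],
                "specificity": [self.specificity],
                "accuracy": [self.accuracy],
            }
        )
        rep = pd.concat([self.fold_metrics, summary], ignore_index=True)
        rep.attrs["pooled_auc"] = self.pooled_auc
        return rep


def run_cv(
    scores: pd.DataFrame,
    labels: Sequence[str],
    classifier_spec: ClassifierSpec,
    k: int = 10,
    repeats: int = 10,
    seed: int | None = 0,
) -> CVResult:
    """Repeated stratified k-fold cross-validation on component scores.

    Folds are stratified by label so every class appears in every training
    split; each cell is tested exactly once per repeat.  The AUC is computed
    both pooled over all test-fold scores (default reporting) and as the
    mean of per-fold AUCs.

    Labels beyond the binary neuron/glia task are accepted as a generic
    multi-class hook: accuracy is still reported per fold, while
    sensitivity, specificity and AUC (binary notions here) come back NaN.
    """
    X = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ValueError(f"each class needs at least k={k} cells; counts: {counts.to_dict()}")
    binary = set(counts.index) == {NEURON, GLIA}

    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    rows = []
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    fold_aucs: list[float] = []
    for i, (train, test) in enumerate(splitter.split(X, y)):
        clf = make_classifier(classifier_spec, X.shape[1], seed=seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        if binary:
            s = _score_for_auc(clf, X[test], clf.classes_)
            sens, spec, acc, auc = evaluate(pred, y[test], s)
        else:
            s = np.zeros(len(test))
            sens = spec = auc = float("nan")
            acc = float((pred == y[test]).mean())
        rows.append(
            {
                "repeat": i // k,
                "fold": i % k,
                "sensitivity": sens,
                "specificity": spec,
                "accuracy": acc,
            }
        )
        fold_aucs.append(auc)
        pooled_scores.append(s)
        pooled_truth.append(y[test])

    if binary:
        pooled = roc_auc_score(
            (np.concatenate(pooled_truth) == NEURON).astype(int),
            np.concatenate(pooled_scores),
        )
    else:
        pooled = float("nan")
    return CVResult(
        classifier=classifier_spec.name,
        k=k,
        repeats=repeats,
        seed=seed,
        fold_metrics=pd.DataFrame(rows),
        pooled_auc=float(pooled),
        fold_mean_auc=float(np.mean(fold_aucs)),
    )
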