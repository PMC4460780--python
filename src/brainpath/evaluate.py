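"""Cross-validated classification harness and random-forest feature selection.

Evaluates a samples × features table with four classifier families (Gaussian
naive Bayes, logistic regression, RBF-kernel SVM, random forest) under
stratified 10-fold cross-validation.  Accuracy, sensitivity and specificity
are averaged over folds; AUC is reported both pooled over held-out decision
scores and fold-averaged.  Feature importance uses the random forest's
permutation-based mean decrease in accuracy (MDA), with an elbow rule on the
sorted score curve to pick the discriminatory feature count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIERS",
    "ConfusionCounts",
    "EvaluationReport",
    "ImportanceRanking",
    "confusion_metrics",
    "cross_validate",
    "default_grid",
    "rf_mda_importance",
    "roc_auc",
    "select_discriminatory",
    "svm_grid_search",
]

#: the four classifier families of the evaluation harness
CLASSIFIERS = ("nb", "logreg", "svm", "rf")

#: hyperparameter grid for the RBF-kernel SVM: powers of ten, 1e-4 .. 1e4
def default_grid() -> np.ndarray:
    return np.logspace(-4, 4, 9)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table; patients are the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); an empty denominator gives NaN.

    accuracy = (TP+TN)/(TP+FP+TN+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(FP+TN).
    """
    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return (
        ratio(c.tp + c.tn, c.total),
        ratio(c.tp, c.tp + c.fn),
        ratio(c.tn, c.fp + c.tn),
    )


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based AUC: P(random positive outscores a random negative), ties half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels == _positive_label(labels), scores))


def _positive_label(labels: np.ndarray):
    """Positive class = the larger label (later disease stage by convention)."""
    return np.unique(labels)[-1]


def _make_classifier(name: str, seed: int, svm_c: float, svm_gamma: float):
    if name == "nb":
        return GaussianNB()
    if name == "logreg":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000))]
        )
    if name == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", C=svm_c, gamma=svm_gamma)),
            ]
        )
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


@dataclass
class EvaluationReport:
    """Per-classifier cross-validated metrics plus the fold assignment used."""

    metrics: dict[str, dict[str, float]]
    fold_assignment: np.ndarray
    folds: int
    seed: int
    params: dict = field(default_factory=dict)


def cross_validate(
    features,
    labels: Sequence,
    classifiers: Sequence[str] = CLASSIFIERS,
    folds: int = 10,
    seed: int = 0,
    svm_c: float = 1.0,
    svm_gamma: float | str = "scale",
) -> EvaluationReport:
    """Stratified k-fold evaluation of a feature table.

    Each sample is tested exactly once; fold sizes differ by at most one.
    Scaling for the margin/regression classifiers is fit on the training fold
    only.  Reports fold-averaged accuracy/sensitivity/specificity, pooled AUC
    over the concatenated held-out scores, and fold-averaged AUC.
    """
    X = np.asarray(features.to_numpy() if hasattr(features, "to_numpy") else features, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} samples per class for stratified {folds}-fold CV"
        )
    pos = _positive_label(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    fold_assignment = np.empty(len(y), dtype=int)
    for f, (_, test) in enumerate(splits):
        fold_assignment[test] = f

    metrics: dict[str, dict[str, float]] = {}
    for name in classifiers:
        fold_acc, fold_sen, fold_spe, fold_auc = [], [], [], []
        pooled_scores = np.empty(len(y), dtype=float)
        for train, test in splits:
            model = _make_classifier(name, seed, svm_c, svm_gamma)
            model.fit(X[train], y[train])
            pred = model.predict(X[test])
            scores = _decision_scores(model, X[test])
            pooled_scores[test] = scores
            truth = y[test] == pos
            guess = pred == pos
            c = ConfusionCounts(
                tp=int(np.sum(truth & guess)),
                fp=int(np.sum(~truth & guess)),
                tn=int(np.sum(~truth & ~guess)),
                fn=int(np.sum(truth & ~guess)),
            )
            acc, sen, spe = confusion_metrics(c)
            fold_acc.append(acc)
            fold_sen.append(sen)
            fold_spe.append(spe)
            fold_auc.append(roc_auc(scores, y[test]) if truth.any() and (~truth).any() else np.nan)
        metrics[name] = {
            "accuracy": float(np.nanmean(fold_acc)),
            "sensitivity": float(np.nanmean(fold_sen)),
            "specificity": float(np.nanmean(fold_spe)),
            "auc_pooled": roc_auc(pooled_scores, y),
            "auc_fold_mean": float(np.nanmean(fold_auc)),
        }
    return EvaluationReport(
        metrics=metrics,
        fold_assignment=fold_assignment,
        folds=folds,
        seed=seed,
        params={"svm_c": svm_c, "svm_gamma": svm_gamma},
    )


def svm_grid_search(
    features,
    labels: Sequence,
    c_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Tune the RBF-kernel SVM's C and gamma by cross-validated pooled AUC.

    Default grids are the nine powers of ten from 1e-4 to 1e4 (81 pairs).
    Returns the best ``{"C", "gamma", "auc"}`` spec and the full grid report.
    """
    X = np.asarray(features.to_numpy() if hasattr(features, "to_numpy") else features, float)
    if np.all(X.std(axis=0) == 0):
        raise ValueError("degenerate features: every column has zero variance")
    c_grid = np.asarray(c_grid if c_grid is not None else default_grid(), float)
    gamma_grid = np.asarray(gamma_grid if gamma_grid is not None else default_grid(), float)
    if c_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("empty hyperparameter grid")
    rows = []
    for C in c_grid:
        for gamma in gamma_grid:
            rep = cross_validate(
                X, labels, classifiers=("svm",), folds=folds, seed=seed,
                svm_c=float(C), svm_gamma=float(gamma),
            )
            m = rep.metrics["svm"]
            rows.append({"C": float(C), "gamma": float(gamma),
                         "auc": m["auc_pooled"], "accuracy": m["accuracy"]})
    report = pd.DataFrame(rows)
    best = report.loc[report["auc"].idxmax()]
    return {"C": best["C"], "gamma": best["gamma"], "auc": best["auc"]}, report


@dataclass
class ImportanceRanking:
    """Features ranked by MDA score (descending) with the elbow-selected top-K."""

    ranking: pd.DataFrame  # feature, mda — sorted descending
    selected: tuple[str, ...]
    K: int
    elbow_index: int


def _oob_indices(tree, n_samples: int) -> np.ndarray:
    """Out-of-bag sample indices for one bootstrapped tree."""
    rng = np.random.RandomState(tree.random_state)
    sampled = rng.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


def rf_mda_importance(
    features, labels: Sequence, trees: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Mean decrease in accuracy (MDA) from a random forest, out-of-bag.

    The classical permutation importance: for every tree, its accuracy on its
    out-of-bag samples is compared with the accuracy after permuting one
    feature's column among those samples; the importance of the feature is
    the mean accuracy drop over all trees.  Evaluating out-of-bag is what
    makes redundant or memorized features score near zero instead of
    exactly zero.  Deterministic given the seed.
    """
    if trees < 1:
        raise ValueError("need at least one tree")
    names = (
        list(features.columns)
        if hasattr(features, "columns")
        else [f"f{i}" for i in range(np.asarray(features).shape[1])]
    )
    X = np.asarray(features.to_numpy() if hasattr(features, "to_numpy") else features, float)
    y = np.asarray(labels)
    n, p = X.shape
    forest = RandomForestClassifier(n_estimators=trees, random_state=seed, bootstrap=True)
    forest.fit(X, y)
    y_codes = np.searchsorted(forest.classes_, y)
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    used = np.zeros(p)
    for tree in forest.estimators_:
        oob = _oob_indices(tree, n)
        if oob.size == 0:
            continue
        X_oob = np.asarray(X[oob], dtype=np.float32)
        base = np.mean(tree.predict(X_oob, check_input=False) == y_codes[oob])
        for j in range(p):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
            acc = np.mean(tree.predict(X_perm, check_input=False) == y_codes[oob])
            drops[j] += base - acc
            used[j] += 1
    if not used.any():
        raise RuntimeError("no out-of-bag samples; cannot compute MDA")
    return pd.DataFrame({"feature": names, "mda": drops / used})


def select_discriminatory(importances: pd.DataFrame) -> ImportanceRanking:
    """Elbow rule on the sorted MDA curve: keep features before the slope break.

    With scores sorted descending, the changing point is where the curve
    bends from the steep informative block into its flat noise tail,
    located as the position of maximum vertical distance below the chord
    joining the first and last scores (the standard knee/elbow criterion).
    K is the number of features strictly before that point.  A curve with no
    bend (e.g. linear decay) falls back to the position of the largest
    single drop; all-equal scores give K = 1 with a warning.
    """
    if len(importances) < 2:
        raise ValueError("need at least 2 features to select from")
    ranking = importances.sort_values(
        "mda", ascending=False, kind="stable"
    ).reset_index(drop=True)
    scores = ranking["mda"].to_numpy()
    drops = scores[:-1] - scores[1:]
    m = len(scores)
    # vertical distance of each point below the first-to-last chord
    chord = scores[0] + (scores[-1] - scores[0]) * np.arange(m) / (m - 1)
    deviation = chord - scores
    if np.all(drops == 0):
        warnings.warn("all importance scores equal; selecting a single feature")
        elbow = 1
    elif deviation.max() > 0:
        elbow = int(np.argmax(deviation))
    else:
        elbow = int(np.argmax(drops)) + 1
    K = max(elbow, 1)
    return ImportanceRanking(
        ranking=ranking,
        selected=tuple(ranking["feature"].head(K)),
        K=K,
        elbow_index=elbow,
    )
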