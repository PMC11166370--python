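"""Sequential panel selection with a max-margin classifier and repeated CV.

The diagnostic panels are built by *sequential feature accumulation*: within
each training fold, candidate proteins are ranked by a two-sample t-test
between the two diagnostic groups, and a soft-margin linear SVM is trained on
the top-k features for every panel size k.  Panel performance (accuracy,
sensitivity, specificity) is averaged over repeated stratified k-fold
cross-validation (10 x 10-fold by default); the best panel size maximizes mean
accuracy.  Held-out decision scores feed the ROC curve and its trapezoidal
AUC, which equals the Mann-Whitney pair-counting statistic with ties counted
one half.

`SequentialPanelClassifier` packages the rank-then-train step as a
scikit-learn estimator so it composes with sklearn model selection;
`accumulate_cv` is the repeated-CV driver producing a `PanelPerformance`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "common_intersection",
    "rank_features",
    "SequentialPanelClassifier",
    "accumulate_cv",
    "roc_auc",
    "PanelPerformance",
    "load_availability",
    "CONTRASTS",
]

#: The three one-vs-one diagnostic contrasts; the second group is the
#: positive class (sensitivity = its recall).
CONTRASTS = {
    "healthy_vs_early": ("healthy", "early"),
    "healthy_vs_late": ("healthy", "late"),
    "early_vs_late": ("early", "late"),
}


def common_intersection(availability: dict[str, list[str]]) -> list[str]:
    """Markers fully registered in every diagnostic group, sorted
    lexicographically.  Raises if the intersection is empty."""
    if len(availability) < 2:
        raise ValueError("need availability lists for at least two groups")
    sets = [set(v) for v in availability.values()]
    common = set.intersection(*sets)
    if not common:
        raise ValueError(
            "no marker is available in every group; review feature availability"
        )
    return sorted(common)


def rank_features(X, y, feature_names: list[str]) -> pd.DataFrame:
    """t-test feature ranking for a binary contrast.

    Per feature, a two-sample two-tailed t-test between the two classes;
    ordering is ascending p, ties broken by descending |t| then feature name.
    A zero-variance feature ranks first if its class means differ exactly
    (degenerate perfect separation, p set to 0) and last (p = 1) otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("rank_features requires exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    rows = []
    for j, name in enumerate(feature_names):
        va, vb = a[:, j], b[:, j]
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            if va.mean() == vb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(vb.mean() - va.mean()), 0.0
        else:
            t, p = stats.ttest_ind(va, vb)
        rows.append({"feature": name, "t": float(t), "p": float(p)})
    ranking = pd.DataFrame(rows)
    ranking["_abs_t"] = -ranking["t"].abs()
    ranking = (
        ranking.sort_values(["p", "_abs_t", "feature"])
        .drop(columns="_abs_t")
        .reset_index(drop=True)
    )
    return ranking


class SequentialPanelClassifier(BaseEstimator, ClassifierMixin):
    """Top-k t-test-ranked features feeding a standardized soft-margin SVM.

    Fitting ranks the features by two-sample t-test on the training data,
    keeps the ``n_features`` best, and trains a StandardScaler + SVC pipeline
    on them.  Standardization statistics come from the training data only, so
    the estimator is leakage-free inside cross-validation.

    Parameters
    ----------
    n_features : int
        Panel size k (top-ranked features kept).
    C : float
        Soft-margin penalty of the SVM.
    kernel : str
        SVM kernel; linear by default.

    Attributes
    ----------
    ranking_ : pandas.DataFrame
        Training-data feature ranking (feature, t, p).
    support_indices_ : ndarray
        Column indices of the selected panel, in rank order.
    classes_ : ndarray
        Class labels; the second is treated as the positive class.
    """

    def __init__(self, n_features: int = 5, C: float = 1.0, kernel: str = "linear"):
        self.n_features = n_features
        self.C = C
        self.kernel = kernel

    def fit(self, X, y, feature_names: list[str] | None = None):
        X, y = check_X_y(X, y)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
        if not 1 <= self.n_features <= X.shape[1]:
            raise ValueError(
                f"n_features={self.n_features} outside [1, {X.shape[1]}]"
            )
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        self.ranking_ = rank_features(X, y, feature_names)
        top = self.ranking_["feature"].head(self.n_features).tolist()
        name_to_idx = {n: j for j, n in enumerate(feature_names)}
        self.support_indices_ = np.array([name_to_idx[n] for n in top])
        self.feature_names_ = top
        self.pipeline_ = make_pipeline(
            StandardScaler(), SVC(kernel=self.kernel, C=self.C)
        )
        self.pipeline_.fit(X[:, self.support_indices_], y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        X = check_array(X)
        return self.pipeline_.decision_function(X[:, self.support_indices_])

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = check_array(X)
        return self.pipeline_.predict(X[:, self.support_indices_])


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep over the scores) and trapezoidal AUC.

    The curve starts at (0, 0), ends at (1, 1) and is non-decreasing; the
    trapezoidal area equals the Mann-Whitney probability that a random
    positive outscores a random negative, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class PanelPerformance:
    """Aggregated repeated-CV performance for one diagnostic contrast."""

    contrast: str
    per_k: pd.DataFrame  # k, accuracy, sensitivity, specificity (means over folds)
    best_k: int
    best_panel: list[str]  # top-best_k features ranked on the full data
    roc: pd.DataFrame  # pooled held-out scores at best_k, all repeats
    auc: float  # trapezoidal area of `roc`
    auc_per_repeat: list[float] = field(default_factory=list)
    auc_mean: float = float("nan")
    mean_rank: pd.Series | None = None  # per-feature mean rank over folds (1 = best)


def accumulate_cv(
    panel: pd.DataFrame,
    contrast: str,
    universe: list[str],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> PanelPerformance:
    """Sequential feature accumulation under repeated stratified k-fold CV.

    For each repeat (seeded ``seed + r``) and fold: features are ranked on
    the training fold only, and for every panel size k a
    `SequentialPanelClassifier` is trained and evaluated on the held-out
    fold.  Accuracy / sensitivity / specificity are means over all
    ``repeats x folds`` evaluations; ``best_k`` maximizes mean accuracy
    (ties to the smaller panel).  Held-out decision scores at ``best_k``
    are pooled per repeat for per-repeat AUCs, and across all repeats for
    the reported ROC curve.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {sorted(CONTRASTS)}")
    neg, pos = CONTRASTS[contrast]
    sub = panel[panel["group"].isin((neg, pos))]
    X = sub[universe].to_numpy(dtype=float)
    y = (sub["group"] == pos).to_numpy(dtype=int)
    n_neg, n_pos = int((y == 0).sum()), int((y == 1).sum())
    if min(n_neg, n_pos) < folds:
        raise ValueError(
            f"smallest group has {min(n_neg, n_pos)} subjects, fewer than "
            f"{folds} folds; reduce the fold count"
        )

    n_feat = len(universe)
    acc = np.zeros((repeats, folds, n_feat))
    sen = np.zeros((repeats, folds, n_feat))
    spe = np.zeros((repeats, folds, n_feat))
    # held-out decision scores and truths per (repeat, k)
    scores = [[[] for _ in range(n_feat)] for _ in range(repeats)]
    truths = [[[] for _ in range(n_feat)] for _ in range(repeats)]
    rank_pos = np.zeros((repeats, folds, n_feat))

    base = SequentialPanelClassifier(C=C, kernel=kernel)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for f, (train, test) in enumerate(skf.split(X, y)):
            for k in range(1, n_feat + 1):
                clf = clone(base).set_params(n_features=k)
                clf.fit(X[train], y[train], feature_names=universe)
                if k == 1:
                    order = {name: pos + 1 for pos, name
                             in enumerate(clf.ranking_["feature"])}
                    rank_pos[r, f] = [order[name] for name in universe]
                pred = clf.predict(X[test])
                dec = clf.decision_function(X[test])
                yt = y[test]
                acc[r, f, k - 1] = np.mean(pred == yt)
                sen[r, f, k - 1] = (
                    np.mean(pred[yt == 1] == 1) if (yt == 1).any() else np.nan
                )
                spe[r, f, k - 1] = (
                    np.mean(pred[yt == 0] == 0) if (yt == 0).any() else np.nan
                )
                scores[r][k - 1].extend(dec.tolist())
                truths[r][k - 1].extend(yt.tolist())

    per_k = pd.DataFrame(
        {
            "k": np.arange(1, n_feat + 1),
            "accuracy": acc.mean(axis=(0, 1)),
            "sensitivity": np.nanmean(sen, axis=(0, 1)),
            "specificity": np.nanmean(spe, axis=(0, 1)),
        }
    )
    best_k = int(per_k.loc[per_k["accuracy"].idxmax(), "k"])  # idxmax: first max

    auc_per_repeat = []
    for r in range(repeats):
        _, a = roc_auc(scores[r][best_k - 1], truths[r][best_k - 1])
        auc_per_repeat.append(a)
    pooled_scores = [s for r in range(repeats) for s in scores[r][best_k - 1]]
    pooled_truths = [t for r in range(repeats) for t in truths[r][best_k - 1]]
    roc, auc = roc_auc(pooled_scores, pooled_truths)

    full_ranking = rank_features(X, y, universe)
    best_panel = full_ranking["feature"].head(best_k).tolist()

    return PanelPerformance(
        contrast=contrast,
        per_k=per_k,
        best_k=best_k,
        best_panel=best_panel,
        roc=roc,
        auc=auc,
        auc_per_repeat=auc_per_repeat,
        auc_mean=float(np.mean(auc_per_repeat)),
        mean_rank=pd.Series(rank_pos.mean(axis=(0, 1)), index=universe),
    )


def load_availability() -> dict[str, list[str]]:
    """The packaged per-group marker-availability lists (long-format TSV:
    group, marker).  The marker intersection is the reported nine-protein
    feature universe; the per-group gaps among the remaining candidates are
    synthetic stand-ins."""
    path = resources.files("evpanel.fixtures").joinpath("availability_synthetic.tsv")
    df = pd.read_csv(path, sep="\t")
    return {g: sorted(sub["marker"]) for g, sub in df.groupby("group")}
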