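"""Feature ranking, sequential forward selection, and LOOCV classification.

Three classifiers are supported: Fisher's linear discriminant (FLD), a
distance-weighted k-nearest-neighbour rule, and an RBF-kernel SVM.  The
k-NN posterior is the weighted vote

    P(C_j | x) = sum_{i in nbd, y_i = C_j} W_i / sum_{i in nbd} W_i,

with W_i = 1 / (d_i + eps) on standardized Euclidean distances.  All
predictions use leave-one-patient-out cross-validation; feature
standardization and hyperparameter grids are always computed within each
training fold.  Feature ranking and sequential forward selection can be
run once on the whole table (the classical procedure, default) or nested
inside every fold (``selection="nested"``) for a fully honest estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

EPS_DISTANCE = 1e-8

#: Odd neighbour counts searched by the inner CV of the k-NN rule.
DEFAULT_K_GRID = (1, 3, 5, 7, 9, 11)

#: log2 grids for the SVM soft margin C and RBF width gamma.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class FeatureRanking:
    """Features ordered by class-separation significance (ascending p)."""

    features: list[str]
    p_values: np.ndarray
    tests: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p_value": self.p_values, "test": self.tests},
            index=pd.Index(self.features, name="feature"),
        )


@dataclass
class ClassificationResult:
    """LOOCV predictions with posteriors and summary metrics."""

    predictions: pd.Series
    posteriors: pd.Series  # P(positive | x) per patient
    positive: str
    classifier: str
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    auc: float
    auc_ci: tuple[float, float]
    selected_features: list[str]
    separation_p: float
    confusion: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "classifier": self.classifier,
            "positive_class": self.positive,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "auc": self.auc,
            "auc_ci_95": list(self.auc_ci),
            "selected_features": self.selected_features,
            "posterior_separation_p": self.separation_p,
            "confusion": self.confusion,
        }


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if x.size < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > alpha


def _two_sample_p(a: np.ndarray, b: np.ndarray, one_tailed: bool) -> tuple[float, str]:
    """t-test when both samples pass Shapiro-Wilk normality, else
    Mann-Whitney; one-tailed tests take the observed direction."""
    use_t = _is_normal(a) and _is_normal(b)
    if one_tailed:
        alternative = "greater" if np.mean(a) > np.mean(b) else "less"
    else:
        alternative = "two-sided"
    if use_t:
        p = stats.ttest_ind(a, b, alternative=alternative).pvalue
        return float(p), "t"
    p = stats.mannwhitneyu(a, b, alternative=alternative).pvalue
    return float(p), "mann-whitney"


def rank_features(table: pd.DataFrame, labels: pd.Series, positive: str) -> FeatureRanking:
    """Per-feature one-tailed class-difference p-values, sorted ascending.

    Features constant in both classes carry no information and are dropped
    with a warning.
    """
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError("feature ranking requires exactly two classes")
    pos_mask = (labels == positive).to_numpy()
    if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
        raise ValueError("need at least two patients per class")
    names, ps, tests = [], [], []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        a, b = x[pos_mask], x[~pos_mask]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            warnings.warn(f"feature {col!r} constant in both classes; dropped", stacklevel=2)
            continue
        p, test = _two_sample_p(a, b, one_tailed=True)
        names.append(col)
        ps.append(p)
        tests.append(test)
    order = np.lexsort((np.array(names, dtype=object), np.array(ps)))
    return FeatureRanking(
        features=[names[i] for i in order],
        p_values=np.array([ps[i] for i in order]),
        tests=[tests[i] for i in order],
    )


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def knn_posterior(
    x: np.ndarray,
    train_X: np.ndarray,
    train_y: np.ndarray,
    k: int,
    positive: str,
    eps: float = EPS_DISTANCE,
) -> float:
    """Distance-weighted k-NN posterior P(positive | x), W_i = 1/(d_i+eps)."""
    if k < 1 or k > train_X.shape[0]:
        raise ValueError("k must lie between 1 and the training-set size")
    d = np.linalg.norm(train_X - x[None, :], axis=1)
    nbd = np.argsort(d, kind="stable")[:k]
    w = 1.0 / (d[nbd] + eps)
    return float(w[train_y[nbd] == positive].sum() / w.sum())


def _knn_loocv_accuracy(X: np.ndarray, y: np.ndarray, k: int, positive: str) -> float:
    """Vectorized inner-LOOCV accuracy of the weighted k-NN on (X, y)."""
    n = X.shape[0]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nbd = np.argsort(d, axis=1, kind="stable")[:, : min(k, n - 1)]
    w = 1.0 / (np.take_along_axis(d, nbd, axis=1) + EPS_DISTANCE)
    is_pos = (y[nbd] == positive).astype(float)
    post = (w * is_pos).sum(axis=1) / w.sum(axis=1)
    pred_pos = post >= 0.5
    return float(np.mean(pred_pos == (y == positive)))


def _select_k(X: np.ndarray, y: np.ndarray, k_grid: tuple[int, ...], positive: str) -> int:
    best_k, best_acc = None, -1.0
    for k in k_grid:
        if k >= X.shape[0]:
            continue
        acc = _knn_loocv_accuracy(X, y, k, positive)
        if acc > best_acc:  # ties keep the smaller k
            best_k, best_acc = k, acc
    return best_k if best_k is not None else 1


def _svm_loocv_accuracy(X: np.ndarray, y01: np.ndarray, C: float, gamma: float) -> float:
    n = X.shape[0]
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if len(np.unique(y01[tr])) < 2:
            correct += int(np.bincount(y01[tr]).argmax() == y01[i])
            continue
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(X[tr], y01[tr])
        correct += int(clf.predict(X[i : i + 1])[0] == y01[i])
    return correct / n


def _select_svm(
    X: np.ndarray, y01: np.ndarray, c_grid: tuple[float, ...], gamma_grid: tuple[float, ...]
) -> tuple[float, float]:
    best, best_acc = (c_grid[0], gamma_grid[0]), -1.0
    for C in c_grid:
        for gamma in gamma_grid:
            acc = _svm_loocv_accuracy(X, y01, C, gamma)
            if acc > best_acc:
                best, best_acc = (C, gamma), acc
    return best


@dataclass
class ClassifierConfig:
    """Hyperparameter search spaces for the three classifiers."""

    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    tune: bool = True  # inner-CV hyperparameter search per training fold
    fixed_k: int = 3
    fixed_c: float = 1.0
    fixed_gamma: float = 1.0


def _fit_predict_one(
    classifier: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    positive: str,
    cfg: ClassifierConfig,
) -> tuple[str, float, float]:
    """Train on one fold, predict one held-out patient.

    Returns (predicted label, posterior P(positive|x), ranking score).
    """
    classes = np.unique(train_y)
    if len(classes) < 2:
        warnings.warn("training fold contains a single class; majority fallback", stacklevel=2)
        label = classes[0]
        post = 1.0 if label == positive else 0.0
        return label, post, post
    negative = classes[classes != positive][0]
    Xs, xs = _standardize(train_X, test_x[None, :])
    if classifier == "knn":
        k = _select_k(Xs, train_y, cfg.k_grid, positive) if cfg.tune else min(
            cfg.fixed_k, Xs.shape[0] - 1
        )
        post = knn_posterior(xs[0], Xs, train_y, k, positive)
        pred = positive if post >= 0.5 else negative
        return pred, post, post
    if classifier == "fld":
        clf = LinearDiscriminantAnalysis()
        clf.fit(Xs, train_y)
        post = float(clf.predict_proba(xs)[0, list(clf.classes_).index(positive)])
        pred = positive if post >= 0.5 else negative
        return pred, post, post
    if classifier == "svm":
        y01 = (train_y == positive).astype(int)
        if cfg.tune:
            C, gamma = _select_svm(Xs, y01, cfg.c_grid, cfg.gamma_grid)
        else:
            C, gamma = cfg.fixed_c, cfg.fixed_gamma
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(Xs, y01)
        score = float(clf.decision_function(xs)[0])
        post = 1.0 / (1.0 + np.exp(-score))  # monotone logistic squashing
        pred = positive if score >= 0 else negative
        return pred, post, score
    raise ValueError(f"unknown classifier {classifier!r} (expected fld, knn or svm)")


def _loocv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str,
    positive: str,
    cfg: ClassifierConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    posts = np.empty(n)
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        preds[i], posts[i], scores[i] = _fit_predict_one(
            classifier, X[tr], y[tr], X[i], positive, cfg
        )
    return preds, posts, scores


def compute_metrics(
    predictions: np.ndarray | pd.Series, labels: np.ndarray | pd.Series, positive: str
) -> dict:
    """Sensitivity, specificity and accuracy in percent, plus the counts."""
    pred = np.asarray(predictions, dtype=object)
    truth = np.asarray(labels, dtype=object)
    pos = truth == positive
    tp = int(np.sum(pos & (pred == positive)))
    fn = int(np.sum(pos & (pred != positive)))
    tn = int(np.sum(~pos & (pred != positive)))
    fp = int(np.sum(~pos & (pred == positive)))
    n = tp + fn + tn + fp
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    acc = 100.0 * (tp + tn) / n
    return {
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "accuracy_pct": acc,
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
    }


def auc_from_scores(scores: np.ndarray, labels: np.ndarray, positive: str) -> float:
    """Rank (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=object) == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    positive: str,
    n_boot: int = 1000,
    seed: int = 0,
    max_retries: int = 1000,
) -> tuple[float, tuple[float, float]]:
    """Point AUC plus a 95% percentile CI from patient-resampled AUCs.

    Resamples yielding a single class are redrawn (bounded retries).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    point = auc_from_scores(scores, labels, positive)
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries):
            take = rng.integers(0, n, size=n)
            if len(np.unique(labels[take])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        aucs[b] = auc_from_scores(scores[take], labels[take], positive)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return point, (float(lo), float(hi))


def posterior_separation_test(
    posteriors: np.ndarray | pd.Series, labels: np.ndarray | pd.Series, positive: str
) -> float:
    """Two-sample test on P(positive|x) between the true groups, with the
    same normality-dependent test choice as the feature ranking."""
    post = np.asarray(posteriors, dtype=float)
    pos = np.asarray(labels, dtype=object) == positive
    a, b = post[pos], post[~pos]
    if np.ptp(post) == 0:
        return float("nan")
    p, _ = _two_sample_p(a, b, one_tailed=False)
    return p


def sequential_forward_select(
    table: pd.DataFrame,
    labels: pd.Series,
    classifier: str,
    positive: str,
    ranking: FeatureRanking | None = None,
    cfg: ClassifierConfig | None = None,
) -> list[str]:
    """Greedy forward selection in ranked order under LOOCV accuracy.

    Starting from the most significant feature, each next-ranked feature is
    kept only if it strictly improves LOOCV accuracy (ties keep the smaller
    model); the scan terminates after the full ranked list.
    """
    cfg = cfg or ClassifierConfig()
    if ranking is None:
        ranking = rank_features(table, labels, positive)
    y = labels.to_numpy(dtype=object)

    def acc(features: list[str]) -> float:
        X = table[features].to_numpy(dtype=float)
        preds, _, _ = _loocv_predictions(X, y, classifier, positive, cfg)
        return compute_metrics(preds, y, positive)["accuracy_pct"]

    selected = [ranking.features[0]]
    best = acc(selected)
    for feat in ranking.features[1:]:
        candidate = selected + [feat]
        a = acc(candidate)
        if a > best:
            selected, best = candidate, a
    return selected


def loocv_evaluate(
    table: pd.DataFrame,
    labels: pd.Series,
    classifier: str = "knn",
    positive: str = "good",
    cfg: ClassifierConfig | None = None,
    selection: str | None = None,
    features: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ClassificationResult:
    """Leave-one-patient-out evaluation of one classifier.

    ``selection`` is None (use ``features`` or all columns), "global"
    (rank + SFFS once on the whole table, the classical procedure) or
    "nested" (rank + SFFS recomputed inside every training fold, fully
    leakage-free).  Standardization and hyperparameter searches always
    happen within the training fold.
    """
    cfg = cfg or ClassifierConfig()
    if table.shape[0] < 3:
        raise ValueError("LOOCV needs at least three patients")
    if len(labels.unique()) != 2:
        raise ValueError("labels must contain exactly two classes")
    y = labels.to_numpy(dtype=object)
    ids = table.index

    selected: list[str]
    if selection == "global":
        selected = sequential_forward_select(table, labels, classifier, positive, cfg=cfg)
    elif selection == "nested":
        selected = []  # per-fold; recorded as the union for reporting
    elif selection is None:
        selected = list(features) if features is not None else list(table.columns)
    else:
        raise ValueError("selection must be None, 'global' or 'nested'")

    n = table.shape[0]
    preds = np.empty(n, dtype=object)
    posts = np.empty(n)
    scores = np.empty(n)
    if selection == "nested":
        union: set[str] = set()
        idx = np.arange(n)
        for i in range(n):
            tr = idx != i
            sub = table.iloc[tr]
            sub_labels = labels.iloc[tr]
            feats = sequential_forward_select(sub, sub_labels, classifier, positive, cfg=cfg)
            union.update(feats)
            X = table[feats].to_numpy(dtype=float)
            preds[i], posts[i], scores[i] = _fit_predict_one(
                classifier, X[tr], y[tr], X[i], positive, cfg
            )
        selected = sorted(union)
    else:
        X = table[selected].to_numpy(dtype=float)
        preds, posts, scores = _loocv_predictions(X, y, classifier, positive, cfg)

    metrics = compute_metrics(preds, y, positive)
    auc, ci = bootstrap_auc(scores, y, positive, n_boot=n_boot, seed=seed)
    sep = posterior_separation_test(posts, y, positive)
    return ClassificationResult(
        predictions=pd.Series(preds, index=ids, name="prediction"),
        posteriors=pd.Series(posts, index=ids, name="posterior"),
        positive=positive,
        classifier=classifier,
        sensitivity_pct=metrics["sensitivity_pct"],
        specificity_pct=metrics["specificity_pct"],
        accuracy_pct=metrics["accuracy_pct"],
        auc=auc,
        auc_ci=ci,
        selected_features=selected,
        separation_p=sep,
        confusion={k: metrics[k] for k in ("tp", "fn", "tn", "fp")},
    )
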