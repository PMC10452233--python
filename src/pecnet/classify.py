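"""Leave-one-subject-out classification with in-fold feature selection.

The procedure: for each held-out subject, rank all features on the
remaining subjects only (no leakage), then for each candidate feature
count j train the classifier on the top-j features and classify the
held-out subject.  The accuracy curve over j is averaged across folds,
the optimal feature count K is its argmax (smallest K on ties), and the
reported feature set contains the K features that occur most often among
the folds' top-K selections.  Note that K is selected on the same
cross-validated curve that is reported, a mild optimism inherent to the
procedure; a fixed feature count can be passed to avoid it.

Feature-selection methods: absolute Pearson correlation with the label
(Corr), the Fisher score with population group variances (Fisher),
ReliefF with k=10 neighbours (Relief), and the order of entry into the
least-angle-regression active set (LARS).  Classifiers: L2 logistic
regression, AdaBoost (50 stumps), a decision tree, and a 100-tree random
forest, all with seeded internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, lars_path
from sklearn.tree import DecisionTreeClassifier

FS_METHODS = ("Corr", "Fisher", "Relief", "LARS")
CLASSIFIERS = ("LR", "Boost", "Tree", "RF")


@dataclass
class CvResult:
    """Output of one LOOCV run."""

    feature_grid: np.ndarray
    acc_matrix: np.ndarray          # subjects x feature counts, 0/1
    acc_cv: np.ndarray              # mean accuracy per feature count
    K: int
    optimal_features: np.ndarray    # occurrence-ranked indices, best first
    confusion: np.ndarray           # 2x2 counts, rows = true class
    sensitivity: float
    specificity: float
    sem: float
    fold_ranks: list = field(default_factory=list, repr=False)

    @property
    def accuracy(self) -> float:
        return float(self.acc_cv[list(self.feature_grid).index(self.K)])


def _corr_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (len(y) * np.where(sx > 0, sx, np.nan) * sy)
    return np.abs(np.nan_to_num(r, nan=0.0))


def _fisher_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    num = np.zeros(x.shape[1])
    den = np.zeros(x.shape[1])
    for c in np.unique(y):
        xc = x[y == c]
        num += len(xc) * (xc.mean(axis=0) - mu) ** 2
        den += len(xc) * xc.var(axis=0)  # population variance
    with np.errstate(invalid="ignore", divide="ignore"):
        s = num / den
    return np.nan_to_num(s, nan=0.0, posinf=np.finfo(float).max)


def _relieff_scores(x: np.ndarray, y: np.ndarray, k: int = 10) -> np.ndarray:
    """ReliefF weights with range-normalized features, all instances used.

    Deterministic: neighbours are chosen by stable sort on Manhattan
    distance over the normalized features.
    """
    span = np.ptp(x, axis=0)
    live = span > 0
    xn = np.zeros_like(x, dtype=float)
    xn[:, live] = (x[:, live] - x[:, live].min(axis=0)) / span[live]
    n = len(y)
    w = np.zeros(x.shape[1])
    dist = np.abs(xn[:, None, :] - xn[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        same = order[y[order] == y[i]]
        diff = order[y[order] != y[i]]
        hits = same[:min(k, len(same))]
        misses = diff[:min(k, len(diff))]
        if len(hits):
            w -= np.abs(xn[i] - xn[hits]).mean(axis=0)
        if len(misses):
            w += np.abs(xn[i] - xn[misses]).mean(axis=0)
    w /= n
    w[~live] = -np.inf  # constant features rank last
    return w


def _lars_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature order of entry into the LARS active set; non-entering
    features follow in index order."""
    span = np.ptp(x, axis=0)
    live = np.flatnonzero(span > 0)
    order: list[int] = []
    if live.size:
        import warnings

        with warnings.catch_warnings():
            # degenerate active sets are routine at small n; the order of
            # entry up to that point is still well defined
            warnings.simplefilter("ignore")
            _, active, _ = lars_path(x[:, live], y.astype(float),
                                     method="lar")
        order = [int(live[a]) for a in active]
    rest = [f for f in range(x.shape[1]) if f not in set(order)]
    return np.array(order + rest, dtype=int)


def fs_rank(x: np.ndarray, y: np.ndarray, method: str,
            relief_k: int = 10) -> np.ndarray:
    """Deterministic feature ranking (best first) on training data only."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("exactly two classes required")
    if min((y == c).sum() for c in np.unique(y)) < 2:
        raise ValueError("need >= 2 training subjects per class")
    if method == "Corr":
        scores = _corr_scores(x, (y == np.unique(y)[1]).astype(float))
    elif method == "Fisher":
        scores = _fisher_scores(x, y)
    elif method == "Relief":
        scores = _relieff_scores(x, y, k=relief_k)
    elif method == "LARS":
        return _lars_order(x, (y == np.unique(y)[1]).astype(float))
    else:
        raise ValueError(f"unknown FS method {method!r}")
    span = np.ptp(x, axis=0)
    scores = np.where(span > 0, scores, -np.inf)
    # stable descending sort: ties broken by feature index
    return np.argsort(-scores, kind="stable")


def make_classifier(name: str, seed: int = 0):
    if name == "LR":
        return LogisticRegression(C=1.0, max_iter=1000)  # default L2 penalty
    if name == "Boost":
        return AdaBoostClassifier(n_estimators=50, random_state=seed)
    if name == "Tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def default_feature_grid(n_features: int, dense_to: int = 50,
                         n_log: int = 10) -> np.ndarray:
    """1..min(50, F) dense, then log-spaced up to F."""
    dense = np.arange(1, min(dense_to, n_features) + 1)
    if n_features <= dense_to:
        return dense
    logs = np.unique(np.round(np.geomspace(dense_to, n_features, n_log))
                     .astype(int))
    return np.unique(np.concatenate([dense, logs]))


def run_loocv(x: np.ndarray, y: np.ndarray, fs_method: str = "Corr",
              classifier: str = "LR",
              feature_grid: np.ndarray | None = None,
              seed: int = 0, fixed_k: int | None = None) -> CvResult:
    """Leave-one-subject-out CV with in-fold feature selection.

    fixed_k, when given, bypasses the argmax over the accuracy curve and
    reports the result at that feature count (removing the selection-on-
    test-curve optimism of the published argmax rule).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n, f = x.shape
    if n < 4:
        raise ValueError("need at least 4 subjects")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    grid = (default_feature_grid(f) if feature_grid is None
            else np.asarray(feature_grid, dtype=int))
    if grid.min() < 1 or grid.max() > f:
        raise ValueError("feature grid outside 1..F")

    acc = np.zeros((n, len(grid)))
    preds = np.empty((n, len(grid)), dtype=y.dtype)
    fold_ranks = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        rank = fs_rank(x[train], y[train], fs_method)
        fold_ranks.append(rank)
        for gj, j in enumerate(grid):
            sel = rank[:j]
            clf = make_classifier(classifier, seed=seed)
            clf.fit(x[train][:, sel], y[train])
            pred = clf.predict(x[i:i + 1, sel])[0]
            preds[i, gj] = pred
            acc[i, gj] = float(pred == y[i])

    acc_cv = acc.mean(axis=0)
    if fixed_k is not None:
        if fixed_k not in grid:
            raise ValueError("fixed_k must be on the feature grid")
        k_idx = int(np.flatnonzero(grid == fixed_k)[0])
    else:
        k_idx = int(np.argmax(acc_cv))  # argmax returns the smallest on ties
    k = int(grid[k_idx])

    # occurrence-rate ranking of the folds' top-K selections
    occurrence = np.zeros(f)
    pos_sum = np.zeros(f)
    for rank in fold_ranks:
        occurrence[rank[:k]] += 1
        pos_sum[rank] += np.arange(f)
    mean_rankpos = pos_sum / n
    # sort: occurrence desc, then better (lower) mean training rank, then index
    order = np.lexsort((np.arange(f), mean_rankpos, -occurrence))
    optimal = order[:k]

    pred_k = preds[:, k_idx]
    pos = classes[1]  # second class plays the "patient"/positive role
    tp = int(np.sum((y == pos) & (pred_k == pos)))
    fn = int(np.sum((y == pos) & (pred_k != pos)))
    tn = int(np.sum((y != pos) & (pred_k != pos)))
    fp = int(np.sum((y != pos) & (pred_k == pos)))
    confusion = np.array([[tn, fp], [fn, tp]])
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    sem = float(acc[:, k_idx].std(ddof=0) / np.sqrt(n))
    return CvResult(feature_grid=grid, acc_matrix=acc, acc_cv=acc_cv, K=k,
                    optimal_features=optimal, confusion=confusion,
                    sensitivity=float(sens), specificity=float(spec),
                    sem=sem, fold_ranks=fold_ranks)


def summarize_grid(results: dict[tuple[str, str], CvResult]) -> pd.DataFrame:
    """ACC +/- SEM for every FS x classifier combination, best cell first
    flagged; ties go to the earliest combination in the fixed
    (FS_METHODS, CLASSIFIERS) order."""
    rows = []
    for fs in FS_METHODS:
        for clf in CLASSIFIERS:
            if (fs, clf) not in results:
                continue
            r = results[(fs, clf)]
            rows.append({"fs": fs, "classifier": clf, "accuracy": r.accuracy,
                         "sem": r.sem, "K": r.K})
    df = pd.DataFrame(rows)
    df["best"] = False
    if len(df):
        df.loc[df["accuracy"].idxmax(), "best"] = True  # idxmax: first max
    return df
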