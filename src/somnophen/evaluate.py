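"""Monte-Carlo random-forest evaluation framework.

The outer loop repeats a stratified 70/30 split R times.  Within each run,
random-forest hyperparameters are tuned by stratified 10-fold
cross-validation on the training set, with the minority class of the nine
training folds balanced to equality by SMOTE before each fit; the untouched
validation fold never sees a synthetic point.  The final model for the run
is then fit on the full, unaltered training set (no SMOTE) and scored on
the held-out test set.  AUC, F1 and mean-decrease-in-impurity importances
are averaged across runs; the mean ROC is obtained by vertical averaging
on a fixed 101-point false-positive-rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .catalog import FEATURE_SETS, SET_ORDER

FPR_GRID = np.linspace(0.0, 1.0, 101)

DEFAULT_GRID = tuple(
    {"max_depth": d, "max_features": f}
    for d in (5, 10, None)
    for f in ("sqrt", 0.25, 0.5)
)


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings.  ``n_runs`` is 200 for single-set experiments and
    500 for combined/exclusion experiments in the reference protocol; scale
    down for exploratory work."""

    n_runs: int = 200
    train_fraction: float = 0.7
    cv_folds: int = 10
    grid: tuple = DEFAULT_GRID
    smote_k: int = 5
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or not (0 < self.train_fraction < 1):
            raise ValueError("invalid evaluation configuration")


@dataclass
class EvalResult:
    auc_runs: np.ndarray
    f1_runs: np.ndarray
    importance: pd.DataFrame  # feature, mean_importance, mean_rank
    mean_roc: pd.DataFrame  # fpr, tpr
    positive_label: str

    @property
    def mean_auc(self) -> float:
        return float(self.auc_runs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.auc_runs.std(ddof=1)) if self.auc_runs.size > 1 else 0.0

    @property
    def mean_f1(self) -> float:
        return float(self.f1_runs.mean())

    @property
    def sd_f1(self) -> float:
        return float(self.f1_runs.std(ddof=1)) if self.f1_runs.size > 1 else 0.0


def stratified_mc_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class round(train_fraction * n) indices into train; rest test."""
    labels = np.asarray(labels)
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 4:
            raise ValueError(f"class {cls!r} has fewer than 4 members")
        idx = rng.permutation(idx)
        n_train = round(train_fraction * idx.size)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def smote_oversample(
    minority: np.ndarray, n_synthetic: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Interpolated synthetic minority points: x + u * (x_nn - x)."""
    minority = np.asarray(minority, dtype=float)
    if minority.shape[0] < 2:
        raise ValueError("SMOTE needs at least 2 minority points")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    k_eff = min(k, minority.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(minority)
    neighbors = nn.kneighbors(minority, return_distance=False)[:, 1:]
    base = rng.integers(0, minority.shape[0], n_synthetic)
    picks = neighbors[base, rng.integers(0, k_eff, n_synthetic)]
    u = rng.random((n_synthetic, 1))
    return minority[base] + u * (minority[picks] - minority[base])


def _balance_with_smote(X, y, k, rng):
    """Equalize class sizes; returns (X_aug, y_aug, is_synthetic)."""
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    X_parts, y_parts, synth_parts = [X], [y], [np.zeros(len(y), bool)]
    for cls, count in zip(classes, counts):
        deficit = n_max - count
        if deficit > 0:
            synth = smote_oversample(X[y == cls], deficit, k, rng)
            X_parts.append(synth)
            y_parts.append(np.full(deficit, cls, dtype=y.dtype))
            synth_parts.append(np.ones(deficit, bool))
    return (
        np.concatenate(X_parts),
        np.concatenate(y_parts),
        np.concatenate(synth_parts),
    )


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def f1_score(scores, labels, threshold: float = 0.5) -> float:
    """F1 of the positive class at a fixed probability threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    tp = np.sum(pred & labels)
    if tp == 0:
        return 0.0
    precision = tp / pred.sum()
    recall = tp / labels.sum()
    return float(2 * precision * recall / (precision + recall))


def _positive_label(y: np.ndarray) -> str:
    """Positive class = the smaller class (lexicographically later on ties)."""
    classes, counts = np.unique(y, return_counts=True)
    order = np.lexsort((classes, counts))
    return classes[order[0]] if counts[order[0]] < counts[order[-1]] else classes[-1]


def cv_fold_data(X, y, cv_folds, smote_k, rng):
    """Yield (X_train_aug, y_train_aug, is_synthetic, X_val, y_val) per fold.

    SMOTE is applied only to the training portion; validation folds are
    original points only.  Folds with a single-class validation portion are
    re-drawn with a new sub-seed.
    """
    for attempt in range(10):
        seed = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        if all(np.unique(y[val]).size == 2 for _, val in folds):
            break
    for tr, val in folds:
        X_aug, y_aug, synth = _balance_with_smote(X[tr], y[tr], smote_k, rng)
        yield X_aug, y_aug, synth, X[val], y[val]


def tune_hyperparameters(X, y, config: EvalConfig, rng) -> dict:
    """Grid point maximizing mean validation AUC; ties -> first in grid."""
    if not config.grid:
        raise ValueError("hyperparameter grid is empty")
    if len(config.grid) == 1:
        return dict(config.grid[0])
    pos = _positive_label(y)
    folds = list(cv_fold_data(X, y, config.cv_folds, config.smote_k, rng))
    best_params, best_score = None, -np.inf
    for params in config.grid:
        aucs = []
        for X_tr, y_tr, _, X_val, y_val in folds:
            rf = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=int(rng.integers(2**31)),
                **params,
            ).fit(X_tr, y_tr)
            scores = rf.predict_proba(X_val)[:, list(rf.classes_).index(pos)]
            aucs.append(roc_auc(scores, y_val == pos))
        score = float(np.mean(aucs))
        if score > best_score:
            best_params, best_score = dict(params), score
    return best_params


def _impute_train_mean(X_train, X_test):
    finite = np.isfinite(X_train)
    counts = finite.sum(axis=0)
    sums = np.where(finite, X_train, 0.0).sum(axis=0)
    means = np.divide(
        sums, counts, out=np.zeros_like(sums), where=counts > 0
    )  # all-missing columns impute to 0
    fill = lambda X: np.where(np.isfinite(X), X, means)  # noqa: E731
    return fill(X_train), fill(X_test)


def evaluate_task(
    table: pd.DataFrame,
    features: list[str],
    config: EvalConfig,
    group_col: str = "group",
) -> EvalResult:
    """Run the full Monte-Carlo evaluation of one binary task."""
    if not features:
        raise ValueError("empty feature subset")
    y_all = table[group_col].to_numpy(dtype=object)
    if np.unique(y_all).size != 2:
        raise ValueError("evaluate_task requires a binary task")
    X_all = table[list(features)].to_numpy(dtype=float)
    pos = _positive_label(y_all)

    aucs, f1s = np.empty(config.n_runs), np.empty(config.n_runs)
    importances = np.empty((config.n_runs, len(features)))
    tprs = np.empty((config.n_runs, FPR_GRID.size))
    for r in range(config.n_runs):
        rng = np.random.default_rng(config.seed + r)
        train, test = stratified_mc_split(y_all, config.train_fraction, rng)
        X_tr, X_te = _impute_train_mean(X_all[train], X_all[test])
        y_tr, y_te = y_all[train], y_all[test]
        params = tune_hyperparameters(X_tr, y_tr, config, rng)
        rf = RandomForestClassifier(
            n_estimators=config.n_trees,
            random_state=int(rng.integers(2**31)),
            **params,
        ).fit(X_tr, y_tr)
        scores = rf.predict_proba(X_te)[:, list(rf.classes_).index(pos)]
        aucs[r] = roc_auc(scores, y_te == pos)
        f1s[r] = f1_score(scores, y_te == pos)
        importances[r] = rf.feature_importances_
        tprs[r] = _roc_on_grid(scores, y_te == pos)

    ranks = (-importances).argsort(axis=1).argsort(axis=1) + 1
    importance = pd.DataFrame(
        {
            "feature": features,
            "mean_importance": importances.mean(axis=0),
            "mean_rank": ranks.mean(axis=0),
        }
    ).sort_values("mean_rank", ignore_index=True)
    mean_roc = pd.DataFrame({"fpr": FPR_GRID, "tpr": tprs.mean(axis=0)})
    return EvalResult(aucs, f1s, importance, mean_roc, positive_label=pos)


def _roc_on_grid(scores, y_bool) -> np.ndarray:
    """Empirical TPR at each grid FPR (vertical averaging support)."""
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_bool[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    tpr = np.concatenate(([0.0], tp / max(tp[-1], 1)))
    fpr = np.concatenate(([0.0], fp / max(fp[-1], 1)))
    # step-function interpolation: max TPR attained at FPR <= grid value
    return np.array([tpr[fpr <= g].max() for g in FPR_GRID])


def select_top_features(
    rankings_by_set: dict[str, pd.DataFrame], k: int = 8
) -> list[str]:
    """Top-k features per set by mean importance rank; union across sets."""
    selected: list[str] = []
    for set_name in SET_ORDER:
        if set_name not in rankings_by_set:
            continue
        ranking = rankings_by_set[set_name].sort_values("mean_rank")
        selected.extend(ranking["feature"].head(k).tolist())
    return selected


def balanced_exclusion_model(
    rankings_by_set: dict[str, pd.DataFrame],
    excluded_sets: list[str],
    k: int = 8,
    total: int | None = None,
) -> list[str]:
    """Drop excluded sets' top-k and refill round-robin from retained sets'
    next-ranked features until the original size (k x n_sets) is restored."""
    retained = [s for s in SET_ORDER if s in rankings_by_set and s not in excluded_sets]
    if not retained:
        raise ValueError("at least one retained set is required")
    if total is None:
        total = k * len(rankings_by_set)
    queues = {
        s: rankings_by_set[s].sort_values("mean_rank")["feature"].tolist()
        for s in retained
    }
    selected = []
    for s in retained:
        selected.extend(queues[s][:k])
    depth = k
    while len(selected) < total:
        added = False
        for s in retained:
            if len(selected) >= total:
                break
            if depth < len(queues[s]):
                selected.append(queues[s][depth])
                added = True
        if not added:
            break  # retained sets exhausted; return the shortfall
        depth += 1
    return selected[:total]


def group_mean_comparison(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    columns: list[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Welch t-tests of column means between group pairs.

    Percent difference is expressed relative to the second group of each
    pair; Benjamini-Hochberg adjustment is pooled across the whole requested
    family (all columns x all pairs).
    """
    rows = []
    for g1, g2 in pairs:
        a = table[table[group_col] == g1]
        b = table[table[group_col] == g2]
        if a.empty or b.empty:
            raise ValueError(f"empty group in pair ({g1}, {g2})")
        for col in columns:
            x = a[col].dropna().to_numpy(dtype=float)
            y = b[col].dropna().to_numpy(dtype=float)
            m1, m2 = x.mean() if x.size else np.nan, y.mean() if y.size else np.nan
            pct = 100.0 * (m1 - m2) / m2 if m2 not in (0.0,) and np.isfinite(m2) else np.nan
            if x.size > 1 and y.size > 1 and (x.std() > 0 or y.std() > 0):
                t, p = stats.ttest_ind(x, y, equal_var=False)
            elif x.size > 1 and y.size > 1 and m1 == m2:
                t, p = 0.0, 1.0  # identical constants
            else:
                t, p = np.nan, np.nan  # constant in both groups / too small
            rows.append(
                {
                    "pair": f"{g1}_vs_{g2}",
                    "feature": col,
                    "pct_diff": pct,
                    "t": t,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
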