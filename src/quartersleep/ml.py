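"""Resampled, class-balanced classification framework.

For each diagnostic task (NT1 against clinical controls, NT2, IH, NT2+IH, or
all others) the data are split 70/30 stratified by class, repeated over many
(by default 200) realizations.  Inside each realization, strictly on the
training side: missing values are median-imputed, the minority class is
oversampled to parity with SMOTE, redundant features are removed by a
recursive correlation filter, and the classifier (random forest by default;
XGBoost and Gaussian-process backends pluggable) is tuned by small-grid
5-fold cross-validation.  Held-out performance is summarised as F1, AUC_ROC
and AUC_PR across realizations, and feature importance is the drop in
held-out score when a feature is removed and the model refit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, train_test_split

from .errors import CannotAugmentError, EmptyClassError, MetricError, SplitError
from .features import feature_set_columns

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "NT1"

#: The five classification tasks: positive class NT1 versus a negative set.
TASKS: dict[str, tuple[str, ...]] = {
    "nt1_vs_control": ("control",),
    "nt1_vs_nt2": ("NT2",),
    "nt1_vs_ih": ("IH",),
    "nt1_vs_nt2_ih": ("NT2", "IH"),
    "nt1_vs_all": ("NT2", "IH", "control"),
}


@dataclass(frozen=True)
class TaskSpec:
    """A binary task: NT1 (positive) versus a non-empty set of other groups."""

    name: str
    negative_groups: tuple[str, ...]
    positive_class: str = POSITIVE_CLASS

    def __post_init__(self) -> None:
        if not self.negative_groups:
            raise ValueError("negative group set must be non-empty")
        if self.positive_class in self.negative_groups:
            raise ValueError("positive class cannot appear in the negative set")

    @classmethod
    def from_name(cls, name: str) -> "TaskSpec":
        if name not in TASKS:
            raise KeyError(f"unknown task {name!r}; choose from {sorted(TASKS)}")
        return cls(name=name, negative_groups=TASKS[name])


@dataclass
class RealizationResult:
    """Held-out performance and importances of one resampling realization."""

    index: int
    seed: int
    selected_features: list[str]
    f1: float
    auc_roc: float
    auc_pr: float
    importance: dict[str, float] = field(default_factory=dict)


def build_task_table(table: pd.DataFrame, task: TaskSpec,
                     group_col: str = "group") -> pd.DataFrame:
    """Restrict the feature table to the task's groups; add binary ``label``."""
    known = set(table[group_col].unique())
    for g in (task.positive_class, *task.negative_groups):
        if g not in known:
            raise EmptyClassError(f"group {g!r} has no subjects in the table")
    keep = table[group_col].isin((task.positive_class, *task.negative_groups))
    out = table.loc[keep].copy()
    out["label"] = (out[group_col] == task.positive_class).astype(int)
    return out


def split_70_30(table: pd.DataFrame, seed: int,
                label_col: str = "label") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 70/30 split into training and held-out tables."""
    counts = table[label_col].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise SplitError("each class needs at least 2 subjects to stratify")
    train, test = train_test_split(table, test_size=0.3, random_state=seed,
                                   stratify=table[label_col])
    return train, test


def smote_balance(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                  rng: np.random.Generator | int | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to class parity.

    New minority samples are convex combinations x + u * (x_nn - x) of a
    minority member and one of its k nearest minority neighbours (Euclidean),
    u ~ U(0, 1).  k is reduced (with a warning) if the minority class is
    smaller than k+1; a single-member minority cannot be augmented.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE balancing expects a binary task")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise CannotAugmentError("minority class has fewer than 2 members")
    k = min(k_neighbors, len(Xm) - 1)
    if k < k_neighbors:
        logger.warning("minority class of %d: reducing SMOTE k to %d", len(Xm), k)
    # pairwise distances within the minority class
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]
    base = rng.integers(0, len(Xm), size=n_needed)
    pick = nn[base, rng.integers(0, k, size=n_needed)]
    u = rng.random(size=(n_needed, 1))
    synth = Xm[base] + u * (Xm[pick] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def remove_correlated(X: pd.DataFrame, threshold: float = 0.9,
                      importance_hint: dict[str, float] | None = None) -> list[str]:
    """Recursively drop one member of every feature pair with |Spearman rank
    correlation| above ``threshold``.

    The dropped member is the one with the lower preliminary importance hint;
    without hints (or on ties) the member with the higher mean absolute
    correlation to all remaining features goes.  Deterministic given inputs.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return cols
    vals = X.to_numpy(dtype=float)
    # Spearman = Pearson on ranks; NaNs get median rank so they are neutral
    ranks = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        r = rankdata(col, nan_policy="omit")
        med = np.nanmedian(r) if np.any(~np.isnan(col)) else 0.0
        r[np.isnan(col)] = med
        ranks[:, j] = r
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.nan_to_num(np.abs(corr), nan=0.0)
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(cols), dtype=bool)
    hint = importance_hint or {}
    while True:
        sub = np.where(alive[:, None] & alive[None, :], corr, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        hi, hj = hint.get(cols[i]), hint.get(cols[j])
        if hi is not None and hj is not None and hi != hj:
            drop = i if hi < hj else j
        else:
            mean_i = sub[i, alive].mean()
            mean_j = sub[j, alive].mean()
            # higher overall redundancy goes; ties resolved by column order
            drop = i if (mean_i, j) > (mean_j, i) else j
        alive[drop] = False
    return [c for c, a in zip(cols, alive) if a]


def _univariate_hint(X: np.ndarray, y: np.ndarray,
                     cols: Sequence[str]) -> dict[str, float]:
    """Preliminary per-feature importance on training rows: the distance of
    the single-feature rank AUC from chance, |AUC - 0.5|."""
    pos = X[y == 1]
    neg = X[y == 0]
    ranks = rankdata(X, axis=0)
    n_pos, n_neg = len(pos), len(neg)
    auc = (ranks[y == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {c: float(abs(a - 0.5)) for c, a in zip(cols, auc)}


_RF_GRID = {"max_features": ["sqrt", 0.5]}
_XGB_GRID = {"max_depth": [3, 5]}


def make_model(model: str, seed: int):
    """Classifier factory for the three supported backends."""
    if model == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if model == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=100, learning_rate=0.1,
                             random_state=seed, eval_metric="logloss",
                             verbosity=0)
    if model == "gp":
        return GaussianProcessClassifier(kernel=1.0 * RBF(1.0), random_state=seed)
    raise ValueError(f"unknown model {model!r}; choose rf, xgboost or gp")


def _tuned_fit(model: str, seed: int, X: np.ndarray, y: np.ndarray, tune: bool):
    est = make_model(model, seed)
    grid = {"rf": _RF_GRID, "xgboost": _XGB_GRID}.get(model)
    if tune and grid:
        search = GridSearchCV(est, grid, cv=5, scoring="f1", n_jobs=1)
        search.fit(X, y)
        return search.best_estimator_
    est.fit(X, y)
    return est


def _scores(est, X: np.ndarray) -> np.ndarray:
    return est.predict_proba(X)[:, list(est.classes_).index(1)]


def _metric_from_scores(y: np.ndarray, s: np.ndarray, metric: str) -> float:
    if metric == "f1":
        return float(f1_score(y, (s >= 0.5).astype(int)))
    if metric == "auc_roc":
        return float(roc_auc_score(y, s))
    if metric == "auc_pr":
        return float(average_precision_score(y, s))
    raise ValueError(f"unknown metric {metric!r}")


def _evaluate(est, X: np.ndarray, y: np.ndarray) -> dict[str, float]:
    if len(np.unique(y)) < 2:
        raise MetricError("held-out set contains a single class")
    s = _scores(est, X)
    return {m: _metric_from_scores(y, s, m) for m in ("f1", "auc_roc", "auc_pr")}


def fit_and_score(train: pd.DataFrame, test: pd.DataFrame,
                  feature_cols: Sequence[str], model: str = "rf",
                  seed: int = 0, tune: bool = True,
                  smote_k: int = 5,
                  corr_threshold: float = 0.9,
                  compute_importance: bool = True,
                  importance_metric: str = "f1",
                  importance_mode: str = "refit",
                  n_permutations: int = 10,
                  label_col: str = "label") -> RealizationResult:
    """One realization: impute -> SMOTE -> correlation filter -> tune/fit ->
    held-out metrics (and removal importances).

    All data-dependent statistics (medians, neighbour sets, correlations,
    hyperparameters) come from the training rows only.

    ``importance_mode="refit"`` removes each feature and refits the model
    (the literal removal-from-the-classifier reading; expensive, and its
    score drops carry model-refit sampling noise on small held-out sets);
    ``"permutation"`` keeps the fitted model and permutes the feature's
    held-out column over ``n_permutations`` draws (the standard low-variance
    approximation of the same quantity).
    """
    rng = np.random.default_rng(seed)
    Xtr = train[list(feature_cols)].astype(float)
    Xte = test[list(feature_cols)].astype(float)
    ytr = train[label_col].to_numpy()
    yte = test[label_col].to_numpy()

    medians = Xtr.median()
    medians = medians.fillna(0.0)  # all-missing column: neutral constant
    Xtr = Xtr.fillna(medians)
    Xte = Xte.fillna(medians)

    Xb, yb = smote_balance(Xtr.to_numpy(), ytr, k_neighbors=smote_k, rng=rng)
    Xb_df = pd.DataFrame(Xb, columns=list(feature_cols))
    hint = _univariate_hint(Xb, yb, list(feature_cols))
    selected = remove_correlated(Xb_df, threshold=corr_threshold,
                                 importance_hint=hint)

    est = _tuned_fit(model, seed, Xb_df[selected].to_numpy(), yb, tune)
    metrics = _evaluate(est, Xte[selected].to_numpy(), yte)

    importance: dict[str, float] = {}
    if compute_importance:
        baseline = metrics[importance_metric]
        if importance_mode == "refit":
            params = est.get_params()
            for feat in selected:
                remaining = [f for f in selected if f != feat]
                refit = type(est)(**params)
                refit.fit(Xb_df[remaining].to_numpy(), yb)
                dropped = _evaluate(refit, Xte[remaining].to_numpy(), yte)
                importance[feat] = baseline - dropped[importance_metric]
        elif importance_mode == "permutation":
            Xte_sel = Xte[selected].to_numpy()
            n_test, n_feat = Xte_sel.shape
            # batch all (feature, repeat) variants into one prediction call
            big = np.tile(Xte_sel, (n_feat * n_permutations, 1, 1))
            for fi in range(n_feat):
                for rep in range(n_permutations):
                    big[fi * n_permutations + rep, :, fi] = rng.permutation(
                        Xte_sel[:, fi])
            scores = _scores(est, big.reshape(-1, n_feat)).reshape(
                n_feat, n_permutations, n_test)
            for fi, feat in enumerate(selected):
                drops = [baseline - _metric_from_scores(
                    yte, scores[fi, rep], importance_metric)
                    for rep in range(n_permutations)]
                importance[feat] = float(np.mean(drops))
        else:
            raise ValueError(f"unknown importance_mode {importance_mode!r}")

    return RealizationResult(index=-1, seed=seed, selected_features=selected,
                             f1=metrics["f1"], auc_roc=metrics["auc_roc"],
                             auc_pr=metrics["auc_pr"], importance=importance)


def importance_table(results: Sequence[RealizationResult]) -> pd.DataFrame:
    """Mean/SD of per-feature score drops across realizations, ranked.

    Features not selected in a realization contribute a zero drop for that
    realization (they could not have helped the classifier there).
    """
    all_feats = sorted({f for r in results for f in r.importance})
    if not all_feats:
        return pd.DataFrame(columns=["feature", "importance_mean",
                                     "importance_sd", "n_selected", "rank"])
    mat = np.zeros((len(results), len(all_feats)))
    sel = np.zeros((len(results), len(all_feats)), dtype=bool)
    for ri, r in enumerate(results):
        for fi, f in enumerate(all_feats):
            if f in r.importance:
                mat[ri, fi] = r.importance[f]
                sel[ri, fi] = True
    df = pd.DataFrame({
        "feature": all_feats,
        "importance_mean": mat.mean(axis=0),
        "importance_sd": mat.std(axis=0),
        "n_selected": sel.sum(axis=0),
    })
    df = df.sort_values("importance_mean", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def run_realizations(table: pd.DataFrame, task: TaskSpec | str,
                     feature_sets: str | Sequence[str] = "all",
                     model: str = "rf", n_realizations: int = 200,
                     seed: int = 0, tune: bool = True,
                     smote_k: int = 5, corr_threshold: float = 0.9,
                     compute_importance: bool = True,
                     importance_metric: str = "f1",
                     importance_mode: str = "refit",
                     n_permutations: int = 10,
                     max_failure_fraction: float = 0.1
                     ) -> tuple[list[RealizationResult], dict, pd.DataFrame]:
    """Repeat split -> balance -> select -> fit -> score ``n_realizations``
    times and aggregate.

    Returns the per-realization results, a summary dict with the mean and SD
    of each metric, and the importance table.  Realizations that fail on a
    degenerate split are skipped and logged; the run aborts if more than
    ``max_failure_fraction`` fail.
    """
    if isinstance(task, str):
        task = TaskSpec.from_name(task)
    cols = feature_set_columns(feature_sets)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns absent from the table: {missing[:5]}")
    task_table = build_task_table(table, task)
    master = np.random.default_rng(seed)
    results: list[RealizationResult] = []
    failures = 0
    for i in range(n_realizations):
        r_seed = int(master.integers(0, 2**31 - 1))
        try:
            train, test = split_70_30(task_table, seed=r_seed)
            res = fit_and_score(train, test, cols, model=model, seed=r_seed,
                                tune=tune, smote_k=smote_k,
                                corr_threshold=corr_threshold,
                                compute_importance=compute_importance,
                                importance_metric=importance_metric,
                                importance_mode=importance_mode,
                                n_permutations=n_permutations)
        except (SplitError, CannotAugmentError, MetricError) as exc:
            failures += 1
            logger.warning("realization %d skipped: %s", i, exc)
            if failures > max_failure_fraction * n_realizations:
                raise RuntimeError(
                    f"{failures} of {n_realizations} realizations failed") from exc
            continue
        res.index = i
        results.append(res)
    summary = {
        "task": task.name, "model": model,
        "n_realizations": len(results), "n_failed": failures,
    }
    for metric in ("f1", "auc_roc", "auc_pr"):
        vals = np.array([getattr(r, metric) for r in results])
        summary[f"{metric}_mean"] = float(vals.mean())
        summary[f"{metric}_sd"] = float(vals.std())
    return results, summary, importance_table(results)
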