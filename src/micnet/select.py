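"""Ensemble feature selection: random-forest filter/wrapper and gradient boosting.

Each expression layer is reduced independently by two learners and the
results are merged by union:

* **random forest** — a Filter stage scores every feature by a
  standardized tumor-vs-normal mean difference on log counts, then a
  Wrapper stage evaluates forest classifiers on candidate subsets by
  stratified k-fold cross-validation (accuracy and Cohen's kappa) and
  keeps the subset with the smallest prediction error, preferring fewer
  features on ties;
* **gradient boosting (XGBoost)** — an additive tree ensemble with
  logistic loss; the minority class is up-sampled to parity inside the
  training split only, per-iteration error rate / log-loss / AUC / RMSE
  are recorded on training and held-out data, and features are ranked by
  gain.

The union of the two selected sets is the candidate node set handed to
the network stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .io import TUMOR, ExpressionMatrix

__all__ = [
    "SelectionResult",
    "cohen_kappa",
    "rf_rank_and_select",
    "xgb_rank_and_select",
    "union_features",
    "select_features",
]


def _stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from the run seed and a stage name."""
    h = 2166136261
    for ch in stage.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return int((seed * 1_000_003 + h) % (2**31 - 1))


def _labels(m: ExpressionMatrix) -> np.ndarray:
    return np.array([1 if c == TUMOR else 0 for c in m.condition])


def cohen_kappa(confusion) -> float:
    """Chance-corrected agreement from a 2x2 confusion-count matrix.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the agreement expected from the marginals. Degenerate marginals
    (p_e = 1) are defined as kappa 0 with a warning.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("confusion must be a non-negative 2x2 count matrix")
    n = c.sum()
    if n == 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0", stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1 - p_e))


# ---------------------------------------------------------------------------
# random forest: Filter + Wrapper
# ---------------------------------------------------------------------------

def filter_scores(m: ExpressionMatrix) -> pd.Series:
    """Standardized tumor-vs-normal mean difference per feature (descending).

    Computed on log1p expression; identical features get identical scores.
    """
    y = _labels(m)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs both tumor and normal samples")
    logv = np.log1p(m.values)
    mu1 = logv[y == 1].mean(axis=0)
    mu0 = logv[y == 0].mean(axis=0)
    v1 = logv[y == 1].var(axis=0)
    v0 = logv[y == 0].var(axis=0)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    pooled = np.sqrt(v1 / n1 + v0 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.abs(mu1 - mu0) / pooled
    score = np.where(np.isfinite(score), score, 0.0)
    return pd.Series(score, index=m.feature_ids).sort_values(ascending=False, kind="mergesort")


def _cv_accuracy_kappa(x, y, folds, seed, n_estimators):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, kappas = [], []
    for tr, te in skf.split(x, y):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        conf = np.zeros((2, 2))
        np.add.at(conf, (y[te], pred), 1)
        accs.append(float((pred == y[te]).mean()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kappas.append(cohen_kappa(conf))
    return float(np.mean(accs)), float(np.mean(kappas)), float(np.std(accs, ddof=1)), float(np.std(kappas, ddof=1))


def rf_rank_and_select(
    m: ExpressionMatrix,
    k_grid: list[int],
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
    wrapper_budget: int = 10,
    select_k: int | None = None,
):
    """Filter-rank features, cross-validate subset sizes, pick the best subset.

    Returns ``(ranked, cv_table, selected)``: the filter ranking as a list
    of (feature, score), a table with one row per k in ``k_grid`` holding
    fold-mean accuracy/kappa and their SDs, and the winning feature set —
    the evaluated subset with the highest CV accuracy, ties resolved
    toward fewer features. Beyond the top-k subsets, ``wrapper_budget``
    random subsets drawn from the filter-ranked pool are also evaluated.

    With ``select_k`` set, the selected set is pinned to the top-k of the
    filter ranking (the analyst's chosen CV row) instead of the wrapper's
    min-error pick; the cv_table is still reported for audit.
    """
    if not k_grid:
        raise ValueError("k_grid must not be empty")
    if max(k_grid) > m.n_features:
        raise ValueError(f"k={max(k_grid)} exceeds {m.n_features} features")
    y = _labels(m)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per condition")
    folds = min(folds, int(counts.min()))
    if select_k is not None and not 1 <= select_k <= m.n_features:
        raise ValueError(f"select_k={select_k} out of range for {m.n_features} features")
    ranked = filter_scores(m)
    order = list(ranked.index)
    rng = np.random.default_rng(_stage_seed(seed, "rf-wrapper"))

    candidates: list[list[str]] = [order[:k] for k in sorted(k_grid)]
    pool = order[: max(k_grid)]
    if select_k is None:
        for _ in range(wrapper_budget):
            k = int(rng.choice(sorted(k_grid)))
            if k <= len(pool):
                candidates.append(sorted(rng.choice(pool, size=k, replace=False)))

    frame = m.to_frame()
    evals = []
    for subset in candidates:
        x = np.log1p(frame[list(subset)].to_numpy())
        stats = _cv_accuracy_kappa(x, y, folds, _stage_seed(seed, "rf-cv"), n_estimators)
        evals.append((list(subset), stats))

    cv_table = pd.DataFrame(
        [
            {"k": k, "accuracy": st[0], "kappa": st[1], "accuracy_sd": st[2], "kappa_sd": st[3]}
            for k, (_, st) in zip(sorted(k_grid), evals[: len(k_grid)])
        ]
    )
    if select_k is not None:
        selected = order[:select_k]
    else:
        # smallest prediction error first, then fewer features, then name order
        best = min(evals, key=lambda e: (-e[1][0], len(e[0]), tuple(sorted(e[0]))))
        selected = sorted(best[0], key=lambda f: (order.index(f), f))
    return list(ranked.items()), cv_table, selected


# ---------------------------------------------------------------------------
# gradient boosting
# ---------------------------------------------------------------------------

def _upsample_to_parity(x, y, rng):
    """Sample the minority class with replacement until classes balance."""
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    if counts[minority] == 0:
        raise ValueError("cannot up-sample: one class has no samples")
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return x, y
    idx = np.flatnonzero(y == minority)
    extra = rng.choice(idx, size=deficit, replace=True)
    keep = np.concatenate([np.arange(len(y)), extra])
    return x[keep], y[keep]


def xgb_rank_and_select(
    m: ExpressionMatrix,
    n_rounds: int = 50,
    top_k: int = 10,
    seed: int = 0,
    test_size: float = 0.25,
    max_depth: int = 3,
    learning_rate: float = 0.3,
):
    """Boosted-tree ranking with per-iteration train/held-out metrics.

    The model is an additive ensemble y_hat^(t) = y_hat^(t-1) + f_t(x)
    minimizing the second-order regularized logistic objective. Tumor
    labels are 1; the minority class is up-sampled to parity *inside the
    training split only*, so held-out metrics are leakage-free. Returns
    ``(ranked, metrics, selected)``: features ordered by gain importance,
    a DataFrame with per-iteration error rate / log-loss / AUC / RMSE for
    train and test, and the ``top_k`` features.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    y = _labels(m)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for supervised selection")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 samples per condition")
    rng = np.random.default_rng(_stage_seed(seed, "xgb-upsample"))
    x = m.values
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, stratify=y,
        random_state=_stage_seed(seed, "xgb-split") % (2**32),
    )
    x_tr, y_tr = _upsample_to_parity(x_tr, y_tr, rng)
    dtrain = xgb.DMatrix(x_tr, label=y_tr, feature_names=list(m.feature_ids))
    dtest = xgb.DMatrix(x_te, label=y_te, feature_names=list(m.feature_ids))
    params = {
        "objective": "binary:logistic",
        "eval_metric": ["error", "logloss", "auc", "rmse"],
        "max_depth": max_depth,
        "eta": learning_rate,
        "seed": _stage_seed(seed, "xgb-train"),
        "nthread": 1,
    }
    history: dict = {}
    booster = xgb.train(
        params, dtrain, num_boost_round=n_rounds,
        evals=[(dtrain, "train"), (dtest, "test")],
        evals_result=history, verbose_eval=False,
    )
    metrics = pd.DataFrame(
        {
            f"{split}_{metric}": history[split][metric]
            for split in ("train", "test")
            for metric in ("error", "logloss", "auc", "rmse")
        }
    )
    metrics.insert(0, "iteration", np.arange(1, n_rounds + 1))
    gain = booster.get_score(importance_type="gain")
    ranked = sorted(
        ((f, gain.get(f, 0.0)) for f in m.feature_ids),
        key=lambda t: (-t[1], t[0]),
    )
    selected = [f for f, g in ranked[:top_k] if g > 0]
    return ranked, metrics, selected


def union_features(a, b, rank_a=None, rank_b=None) -> list[str]:
    """Union of two selected sets in a deterministic order.

    Features are ordered by their best (smallest) rank across the two
    input orderings, ties broken by name. Passing plain sets falls back
    to name order for the rank.
    """
    list_a, list_b = list(a), list(b)
    rank_a = rank_a or {f: i for i, f in enumerate(sorted(list_a) if isinstance(a, (set, frozenset)) else list_a)}
    rank_b = rank_b or {f: i for i, f in enumerate(sorted(list_b) if isinstance(b, (set, frozenset)) else list_b)}
    members = set(list_a) | set(list_b)
    big = len(members) + 1

    def best_rank(f):
        return min(rank_a.get(f, big), rank_b.get(f, big))

    return sorted(members, key=lambda f: (best_rank(f), f))


@dataclass
class SelectionResult:
    """Everything the two learners produced for one layer."""

    layer: str
    ranked_features: dict[str, list] = field(default_factory=dict)
    selected_union: list[str] = field(default_factory=list)
    cv_table: pd.DataFrame | None = None
    boosting_metrics: pd.DataFrame | None = None
    rf_selected: list[str] = field(default_factory=list)
    xgb_selected: list[str] = field(default_factory=list)


def select_features(
    m: ExpressionMatrix,
    k_grid: list[int],
    folds: int = 10,
    n_rounds: int = 50,
    top_k: int | None = None,
    seed: int = 0,
    **rf_kwargs,
) -> SelectionResult:
    """Run both learners on one layer and merge their picks by union."""
    if top_k is None:
        top_k = min(k_grid)
    rf_ranked, cv_table, rf_sel = rf_rank_and_select(m, k_grid, folds, seed, **rf_kwargs)
    xgb_ranked, metrics, xgb_sel = xgb_rank_and_select(m, n_rounds, top_k, seed)
    union = union_features(rf_sel, xgb_sel)
    return SelectionResult(
        layer=m.layer,
        ranked_features={"rf": rf_ranked, "xgb": xgb_ranked},
        selected_union=union,
        cv_table=cv_table,
        boosting_metrics=metrics,
        rf_selected=list(rf_sel),
        xgb_selected=list(xgb_sel),
    )
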