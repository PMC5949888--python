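"""Imbalanced classification of functional sequences with importance tables.

The learning stage mirrors a careful screen-analysis protocol: redundancy
pruning (correlation clusters, exact linear combinations, near-zero
variance), per-fold centering/scaling, repeated (or grouped) k-fold
cross-validation with minority-class subsampling on the training side only,
penalized logistic regressions (lasso/ridge over a lambda grid) and
gradient-boosted trees over a fixed hyper-parameter grid, one-standard-error
model selection, a bootstrap-weighted stacked model, precision-recall AUC
evaluation against the prevalence baseline, and per-method relative feature
importances with directions.

Everything is exposed sklearn-style: the pruners are transformers and
:class:`TADActivityClassifier` is a classifier with ``fit``/``predict_proba``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .features import FORCED_KEEP_FEATURES

__all__ = [
    "MLDataset",
    "NearZeroVariancePruner",
    "CorrelationPruner",
    "LinearCombinationPruner",
    "make_preprocessor",
    "split_holdout",
    "make_folds",
    "subsample_minority",
    "lambda_grid",
    "boosted_grid",
    "train_model",
    "evaluate",
    "select_one_se",
    "stack_models",
    "StackedModel",
    "importance_table",
    "TADActivityClassifier",
]


@dataclass
class MLDataset:
    """Feature matrix with labels and optional group/origin annotations."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray | None = None
    origin: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y).astype(int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y are misaligned")
        for name in ("groups", "origin"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if len(val) != len(self.y):
                    raise ValueError(f"{name} misaligned with y")
                setattr(self, name, val)


# ---------------------------------------------------------------------------
# feature pruning transformers


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class NearZeroVariancePruner(TransformerMixin, BaseEstimator):
    """Remove features whose value distribution is nearly degenerate.

    A feature is dropped when the frequency ratio of its most common to its
    second most common value exceeds ``freq_ratio`` (default 95/5 = 19);
    constant features are always dropped.
    """

    def __init__(self, freq_ratio: float = 95 / 5):
        self.freq_ratio = freq_ratio

    def fit(self, X, y=None):
        X = _as_frame(X)
        keep = []
        for col in X.columns:
            counts = X[col].value_counts().to_numpy()
            if len(counts) < 2:
                continue  # constant
            if counts[0] / counts[1] > self.freq_ratio:
                continue
            keep.append(col)
        self.keep_ = keep
        return self

    def transform(self, X):
        return _as_frame(X)[self.keep_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.keep_, dtype=object)


class CorrelationPruner(TransformerMixin, BaseEstimator):
    """Keep one representative per cluster of correlated features.

    Features are nodes, connected when |Pearson r| >= ``threshold``; within
    each connected component the member with the lowest mean absolute
    correlation to the others survives (ties broken by feature id).
    ``forced_keep`` features are always retained.
    """

    def __init__(self, threshold: float = 0.75, forced_keep: tuple = ()):
        self.threshold = threshold
        self.forced_keep = forced_keep

    def fit(self, X, y=None):
        X = _as_frame(X)
        cols = list(X.columns)
        values = X.to_numpy(dtype=float)
        sd = values.std(axis=0)
        variable = [i for i, s in enumerate(sd) if s > 0]
        # constant columns pass through (near-zero variance handles them)
        keep = {cols[i] for i in range(len(cols)) if sd[i] == 0}
        if variable:
            corr = np.corrcoef(values[:, variable], rowvar=False)
            corr = np.atleast_2d(corr)
            graph = nx.Graph()
            graph.add_nodes_from(range(len(variable)))
            absr = np.abs(corr)
            for i in range(len(variable)):
                for j in range(i + 1, len(variable)):
                    if absr[i, j] >= self.threshold:
                        graph.add_edge(i, j)
            for component in nx.connected_components(graph):
                comp = sorted(component)
                if len(comp) == 1:
                    keep.add(cols[variable[comp[0]]])
                    continue
                scores = [
                    (
                        float(np.mean([absr[i, j] for j in comp if j != i])),
                        cols[variable[i]],
                    )
                    for i in comp
                ]
                keep.add(min(scores)[1])
        keep.update(c for c in self.forced_keep if c in cols)
        self.keep_ = [c for c in cols if c in keep]
        return self

    def transform(self, X):
        return _as_frame(X)[self.keep_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.keep_, dtype=object)


class LinearCombinationPruner(TransformerMixin, BaseEstimator):
    """Iteratively remove columns that are exact linear combinations.

    Pivoted QR decomposition identifies rank-deficient column sets; one
    member of each detected dependent set is removed per pass (the highest
    feature id, so low-id features survive deterministically) until the
    matrix has full column rank.
    """

    def __init__(self, tol: float = 1e-8, forced_keep: tuple = ()):
        self.tol = tol
        self.forced_keep = forced_keep

    def fit(self, X, y=None):
        X = _as_frame(X)
        cols = list(X.columns)
        while True:
            mat = X[cols].to_numpy(dtype=float)
            if mat.shape[1] == 0:
                break
            _, r, piv = linalg.qr(mat, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            scale = diag.max() if diag.size else 0.0
            if scale == 0:
                break
            rank = int((diag > self.tol * scale).sum())
            if rank >= len(cols):
                break
            indep = [piv[i] for i in range(rank)]
            dep = piv[rank]
            # express the dependent column on the independent ones to find
            # the participating set
            coefs, *_ = np.linalg.lstsq(mat[:, indep], mat[:, dep], rcond=None)
            involved = [cols[dep]] + [
                cols[indep[i]] for i, c in enumerate(coefs) if abs(c) > 1e-6
            ]
            removable = [c for c in involved if c not in self.forced_keep]
            if not removable:
                removable = [cols[dep]]
            drop = max(removable)
            cols = [c for c in cols if c != drop]
        self.keep_ = cols
        return self

    def transform(self, X):
        return _as_frame(X)[self.keep_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.keep_, dtype=object)


def make_preprocessor(forced_keep: tuple = FORCED_KEEP_FEATURES) -> Pipeline:
    """NZV -> correlation -> linear-combination pruning -> center/scale.

    Fit strictly on training rows; validation/testing rows are transformed
    with the frozen parameters (zero-variance columns are centered only:
    the scaler leaves their scale at 1).
    """
    return Pipeline(
        [
            ("nzv", NearZeroVariancePruner()),
            ("corr", CorrelationPruner(forced_keep=forced_keep)),
            ("lincomb", LinearCombinationPruner(forced_keep=forced_keep)),
            ("scale", StandardScaler()),
        ]
    )


# ---------------------------------------------------------------------------
# dataset splitting


def split_holdout(dataset: MLDataset, train_frac: float = 0.75, seed: int = 0):
    """Stratified-by-label random split into training and testing sets."""
    idx = np.arange(len(dataset.y))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_frac,
        random_state=seed,
        stratify=dataset.y,
        shuffle=True,
    )

    def subset(i):
        return MLDataset(
            X=dataset.X.iloc[i].reset_index(drop=True),
            y=dataset.y[i],
            groups=None if dataset.groups is None else dataset.groups[i],
            origin=None if dataset.origin is None else dataset.origin[i],
        )

    return subset(train_idx), subset(test_idx)


def make_folds(
    y: np.ndarray,
    mode: str = "repeated_kfold",
    groups: np.ndarray | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cross-validation plan: k * repeats train/validation index pairs.

    ``repeated_kfold`` uses stratified folds (at ~1% prevalence unstratified
    folds can lack positives entirely). ``group_kfold`` partitions the group
    labels (TAD sets) into k folds per repeat so no group spans both sides;
    13 groups at k=5 give fold sizes {3,3,3,2,2}.
    """
    y = np.asarray(y)
    if mode == "repeated_kfold":
        splitter = RepeatedStratifiedKFold(
            n_splits=k, n_repeats=repeats, random_state=seed
        )
        return [(tr, va) for tr, va in splitter.split(np.zeros_like(y), y)]
    if mode == "group_kfold":
        if groups is None:
            raise ValueError("group_kfold requires group ids")
        unique = np.unique(groups)
        if len(unique) < k:
            raise ValueError(f"need at least {k} groups, got {len(unique)}")
        rng = np.random.default_rng(seed)
        folds = []
        for _ in range(repeats):
            order = rng.permutation(unique)
            for chunk in np.array_split(order, k):
                mask = np.isin(groups, chunk)
                folds.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
        return folds
    raise ValueError(f"unknown fold mode: {mode!r}")


def subsample_minority(
    y: np.ndarray,
    seed: int = 0,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of a class-balanced subsample (training folds only).

    The majority class is downsampled without replacement to the minority
    size; with ``origin`` given, balancing is applied within each library-
    of-origin stratum.
    """
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    if origin is None:
        strata = [np.arange(len(y))]
    else:
        origin = np.asarray(origin)
        strata = [np.flatnonzero(origin == o) for o in np.unique(origin)]
    keep: list[np.ndarray] = []
    for stratum in strata:
        ys = y[stratum]
        pos = stratum[ys == 1]
        neg = stratum[ys == 0]
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("both classes must be present in each stratum")
        n = min(len(pos), len(neg))
        keep.append(rng.choice(pos, size=n, replace=False) if len(pos) > n else pos)
        keep.append(rng.choice(neg, size=n, replace=False) if len(neg) > n else neg)
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# models and grids


def lambda_grid(
    n: int = 50,
    low: float = 1e-5,
    high: float = 0.1,
    spacing: str = "linear",
) -> np.ndarray:
    """Penalty grid: 50 evenly interspersed lambda values on [1e-5, 0.1]."""
    if spacing == "linear":
        return np.linspace(low, high, n)
    if spacing == "log":
        return np.geomspace(low, high, n)
    raise ValueError(f"unknown spacing: {spacing!r}")


def boosted_grid() -> list[dict]:
    """The 32-point boosted-tree hyper-parameter grid."""
    grid = []
    for eta, depth, subsample, rounds, mcw in itertools.product(
        (0.1, 0.3), (2, 4), (0.5, 0.75), (30, 100), (0.5, 1)
    ):
        grid.append(
            {
                "learning_rate": eta,
                "max_depth": depth,
                "subsample": subsample,
                "n_estimators": rounds,
                "min_child_weight": mcw,
                "colsample_bytree": 0.8,
                "gamma": 0,
            }
        )
    return grid


def train_model(X, y, kind: str, params: dict | None = None, seed: int = 0):
    """Fit one classifier emitting the probability of the functional class.

    ``penalized_L1``/``penalized_L2`` map a glmnet-style lambda onto
    sklearn's C as 1/(lambda * n). ``logit_single``/``logit_multi`` are
    plain logistic regressions on one or several features. ``boosted`` is
    an XGBoost classifier with the grid-point hyper-parameters.
    """
    params = dict(params or {})
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    y = np.asarray(y).astype(int)
    if kind in ("penalized_L1", "penalized_L2"):
        lam = params.pop("lambda")
        model = LogisticRegression(
            l1_ratio=1.0 if kind.endswith("L1") else 0.0,
            C=1.0 / (lam * len(y)),
            solver="liblinear",
            max_iter=2000,
            random_state=seed,
        )
    elif kind in ("logit_single", "logit_multi"):
        model = LogisticRegression(C=np.inf, max_iter=2000, random_state=seed)
    elif kind == "boosted":
        model = XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            tree_method="hist",
            **params,
        )
    else:
        raise ValueError(f"unknown model kind: {kind!r}")
    model.fit(X, y)
    return model


def evaluate(probabilities, labels) -> dict:
    """PR-AUC (step-wise/achievable-precision), ROC-AUC and the prevalence
    baseline for the positive class."""
    p = np.asarray(list(probabilities), dtype=float)
    y = np.asarray(list(labels)).astype(int)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class: metrics undefined")
    return {
        "pr_auc": float(average_precision_score(y, p)),
        "roc_auc": float(roc_auc_score(y, p)),
        "baseline_pr_auc": float(y.mean()),
    }


# ---------------------------------------------------------------------------
# model selection


@dataclass
class GridPointResult:
    family: str  # penalized_L1 | penalized_L2 | boosted
    params: dict
    split_scores: list[float] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.split_scores))

    @property
    def se(self) -> float:
        s = np.asarray(self.split_scores)
        return float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0


def _complexity_key(result: GridPointResult):
    # simplest first: penalized models with larger penalties are simpler
    # (L1 before L2); boosted models with fewer rounds, then shallower trees
    if result.family.startswith("penalized"):
        return (
            0 if result.family.endswith("L1") else 1,
            -result.params["lambda"],
        )
    p = result.params
    return (
        p["n_estimators"],
        p["max_depth"],
        p["learning_rate"],
        -p["min_child_weight"],
        -p["subsample"],
    )


def select_one_se(results: list[GridPointResult]) -> GridPointResult:
    """One-standard-error rule: among grid points whose mean score is within
    one SE of the best, pick the simplest under the family's complexity
    ordering."""
    if not results:
        raise ValueError("no cross-validation results to select from")
    best = max(results, key=lambda r: r.mean)
    cutoff = best.mean - best.se
    candidates = [r for r in results if r.mean >= cutoff]
    return min(candidates, key=_complexity_key)


# ---------------------------------------------------------------------------
# stacking


@dataclass
class StackedModel:
    """Logistic meta-learner over base-model probabilities.

    Weights are averaged over bootstrap resamples (minority subsampling on
    the bootstrap-training side); prediction is the logistic combination of
    the base probabilities.
    """

    base_names: list[str]
    weights: np.ndarray
    intercept: float
    n_bootstrap: int

    def predict_proba(self, base_probs: np.ndarray) -> np.ndarray:
        z = np.asarray(base_probs, dtype=float) @ self.weights + self.intercept
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])


def stack_models(
    oof_probs: pd.DataFrame,
    y: np.ndarray,
    n_bootstrap: int = 50,
    seed: int = 0,
) -> StackedModel:
    """Combine base models from their out-of-fold validation predictions.

    For each of ``n_bootstrap`` resamples the rows are drawn with
    replacement as the bootstrap training side (out-of-bag rows validate),
    the training side is subsampled to the minority class, and a logistic
    meta-model is fitted on the base probabilities; the final weights are
    the bootstrap means. A single base model degrades to a monotone
    pass-through of its probabilities.
    """
    y = np.asarray(y).astype(int)
    P = oof_probs.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    coefs, intercepts = [], []
    n = len(y)
    b = 0
    while len(coefs) < n_bootstrap:
        b += 1
        if b > n_bootstrap * 20:
            raise RuntimeError("bootstrap resampling kept producing degenerate splits")
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        try:
            bal = subsample_minority(y[idx], seed=int(rng.integers(2**31)))
        except ValueError:
            continue
        rows = idx[bal]
        model = LogisticRegression(C=np.inf, max_iter=2000)
        model.fit(P[rows], y[rows])
        coefs.append(model.coef_[0])
        intercepts.append(model.intercept_[0])
    return StackedModel(
        base_names=list(oof_probs.columns),
        weights=np.mean(coefs, axis=0),
        intercept=float(np.mean(intercepts)),
        n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# importance


def importance_table(
    models: dict,
    feature_names: list[str],
    X: np.ndarray,
    y: np.ndarray,
    stack: StackedModel | None = None,
) -> pd.DataFrame:
    """Relative feature importances (percent per method) with directions.

    Penalized models: |coefficient| on the standardized features, direction
    from the coefficient sign. Boosted trees: gain importance, direction
    from the sign of the class-conditional mean difference (trees carry no
    sign). Stacked: base importances combined with the |stack weight| of
    each base model. Percentages sum to 100 within each method.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    mean_diff = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
    raw: dict[str, np.ndarray] = {}
    signs: dict[str, np.ndarray] = {}
    for name, model in models.items():
        if hasattr(model, "coef_"):
            coef = np.asarray(model.coef_[0], dtype=float)
            raw[name] = np.abs(coef)
            signs[name] = np.sign(coef)
        else:  # boosted
            booster = model.get_booster()
            gain = booster.get_score(importance_type="gain")
            imp = np.zeros(len(feature_names))
            for key, val in gain.items():
                idx = int(key[1:]) if key.startswith("f") else feature_names.index(key)
                imp[idx] = val
            raw[name] = imp
            signs[name] = np.sign(mean_diff)
    if stack is not None:
        w = np.abs(stack.weights)
        combined = np.zeros(len(feature_names))
        signed = np.zeros(len(feature_names))
        for wi, name in zip(w, stack.base_names):
            total = raw[name].sum()
            if total > 0:
                combined += wi * raw[name] / total
                signed += wi * signs[name] * raw[name] / total
        raw["stacked"] = combined
        signs["stacked"] = np.sign(signed)
    rows = []
    for name, imp in raw.items():
        total = imp.sum()
        pct = imp / total * 100 if total > 0 else imp
        for feat, p, s in zip(feature_names, pct, signs[name]):
            rows.append(
                {
                    "method": name,
                    "feature": feat,
                    "importance_pct": float(p),
                    "direction": "up" if s > 0 else ("down" if s < 0 else "none"),
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["method", "importance_pct"], ascending=[True, False]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# the end-to-end classifier


class TADActivityClassifier(ClassifierMixin, BaseEstimator):
    """Stacked functional-sequence classifier with one-SE model selection.

    ``fit`` runs the full protocol on a feature matrix: per-fold
    preprocessing (pruning + scaling fit on training rows only),
    cross-validated grid search for lasso, ridge and boosted trees with
    minority subsampling on the training folds, one-standard-error
    selection per family, refit of the chosen base models, and a
    bootstrap-weighted logistic stack over out-of-fold predictions.

    Parameters
    ----------
    fold_mode : "repeated_kfold" (random library) or "group_kfold" (design
        library; pass ``groups`` to fit).
    k, repeats : cross-validation plan (5 x 10 = 50 splits).
    n_lambda, lambda_spacing : penalty grid for the penalized models.
    n_bootstrap : stacking bootstrap count.
    subsample_by_origin : balance classes within each library of origin
        (combined-library training).
    """

    def __init__(
        self,
        fold_mode: str = "repeated_kfold",
        k: int = 5,
        repeats: int = 10,
        n_lambda: int = 50,
        lambda_spacing: str = "linear",
        boosted_params: list[dict] | None = None,
        n_bootstrap: int = 50,
        subsample_by_origin: bool = False,
        forced_keep: tuple = FORCED_KEEP_FEATURES,
        random_state: int = 0,
    ):
        self.fold_mode = fold_mode
        self.k = k
        self.repeats = repeats
        self.n_lambda = n_lambda
        self.lambda_spacing = lambda_spacing
        self.boosted_params = boosted_params
        self.n_bootstrap = n_bootstrap
        self.subsample_by_origin = subsample_by_origin
        self.forced_keep = forced_keep
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    def _grids(self):
        lams = lambda_grid(self.n_lambda, spacing=self.lambda_spacing)
        grids = {
            "penalized_L1": [{"lambda": float(l)} for l in lams],
            "penalized_L2": [{"lambda": float(l)} for l in lams],
            "boosted": self.boosted_params
            if self.boosted_params is not None
            else boosted_grid(),
        }
        return grids

    def fit(self, X, y, groups=None, origin=None):
        X = _as_frame(X).reset_index(drop=True)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        folds = make_folds(
            y,
            mode=self.fold_mode,
            groups=groups,
            k=self.k,
            repeats=self.repeats,
            seed=self.random_state,
        )
        rng = np.random.default_rng(self.random_state)

        # per-split preprocessing + balanced training matrices, cached once
        splits = []
        for tr, va in folds:
            pre = make_preprocessor(self.forced_keep).fit(X.iloc[tr])
            bal = subsample_minority(
                y[tr],
                seed=int(rng.integers(2**31)),
                origin=None
                if (origin is None or not self.subsample_by_origin)
                else np.asarray(origin)[tr],
            )
            tr_rows = tr[bal]
            splits.append(
                {
                    "va": va,
                    "Xtr": np.asarray(pre.transform(X.iloc[tr_rows]), dtype=float),
                    "ytr": y[tr_rows],
                    "Xva": np.asarray(pre.transform(X.iloc[va]), dtype=float),
                    "yva": y[va],
                }
            )

        grids = self._grids()
        self.cv_results_ = {}
        self.best_params_ = {}
        oof_sum = {fam: np.zeros(len(y)) for fam in grids}
        oof_count = {fam: np.zeros(len(y)) for fam in grids}
        for family, grid in grids.items():
            results = [GridPointResult(family, params) for params in grid]
            for split in splits:
                Xtr = np.asarray(split["Xtr"], dtype=float)
                for res in results:
                    model = train_model(
                        Xtr,
                        split["ytr"],
                        family,
                        dict(res.params),
                        seed=self.random_state,
                    )
                    probs = model.predict_proba(split["Xva"])[:, 1]
                    if len(np.unique(split["yva"])) < 2:
                        continue
                    res.split_scores.append(
                        float(average_precision_score(split["yva"], probs))
                    )
            results = [r for r in results if r.split_scores]
            self.cv_results_[family] = results
            chosen = select_one_se(results)
            self.best_params_[family] = chosen.params
            # out-of-fold predictions of the chosen grid point for stacking
            for split in splits:
                model = train_model(
                    np.asarray(split["Xtr"], dtype=float),
                    split["ytr"],
                    family,
                    dict(chosen.params),
                    seed=self.random_state,
                )
                probs = model.predict_proba(split["Xva"])[:, 1]
                oof_sum[family][split["va"]] += probs
                oof_count[family][split["va"]] += 1

        seen = np.ones(len(y), dtype=bool)
        for family in grids:
            seen &= oof_count[family] > 0
        oof = pd.DataFrame(
            {
                family: oof_sum[family][seen] / oof_count[family][seen]
                for family in grids
            }
        )

        # final preprocessing and base models on the full training data
        self.preprocessor_ = make_preprocessor(self.forced_keep).fit(X)
        bal = subsample_minority(
            y,
            seed=int(rng.integers(2**31)),
            origin=origin if self.subsample_by_origin else None,
        )
        Xb = np.asarray(self.preprocessor_.transform(X.iloc[bal]), dtype=float)
        self.base_models_ = {
            family: train_model(
                Xb, y[bal], family, dict(self.best_params_[family]), self.random_state
            )
            for family in grids
        }
        self.stack_ = stack_models(
            oof, y[seen], n_bootstrap=self.n_bootstrap, seed=self.random_state
        )
        self.selected_features_ = list(
            self.preprocessor_.named_steps["lincomb"].keep_
        )
        self.importance_ = importance_table(
            self.base_models_,
            self.selected_features_,
            np.asarray(self.preprocessor_.transform(X), dtype=float),
            y,
            stack=self.stack_,
        )
        return self

    def _base_probs(self, X) -> np.ndarray:
        Xt = np.asarray(self.preprocessor_.transform(_as_frame(X)), dtype=float)
        return np.column_stack(
            [
                self.base_models_[name].predict_proba(Xt)[:, 1]
                for name in self.stack_.base_names
            ]
        )

    def predict_proba(self, X) -> np.ndarray:
        return self.stack_.predict_proba(self._base_probs(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def top_features(self, method: str = "stacked", n: int = 10) -> pd.DataFrame:
        """Top-n importance view for one method."""
        table = self.importance_
        return (
            table[table["method"] == method]
            .nlargest(n, "importance_pct")
            .reset_index(drop=True)
        )
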