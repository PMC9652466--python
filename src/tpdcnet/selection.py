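"""RBF-SVM model selection over directed-EC features.

Predicts walking prefrontal EC from resting-state EC features (epsilon-SVR)
or separates patients from controls (SVC), with:

* the Gaussian kernel k(x, x') = exp(-||x - x'||^2 / (2 sigma^2)), sigma set
  by the median-distance heuristic on each training fold and the
  regularisation constant fixed at 1 (no hyperparameter tuning);
* nested k-fold cross-validation (k = 5 outer and inner) as the evaluation
  harness — because hyperparameters are fixed, the inner loop estimates
  scores honestly but never influences the outer-fold results;
* exhaustive enumeration of feature subsets (the 20-feature space holds
  2^20 = 1,048,576 combinations) ranked by best mean outer-fold score with
  minimal standard error;
* Kernel SHAP attribution of the selected model, summarised as the mean
  absolute Shapley value per feature and group, averaged over outer folds.

Subset evaluation runs on precomputed per-feature squared-distance matrices
with a direct libsvm fast path (validated against the public scikit-learn
estimators in the test suite); the public API falls back to SVR/SVC when the
private binding is unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

from .datatypes import TpdcError
from .shapley import KernelShapExplainer

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised indirectly
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover
    _libsvm = None

#: Columns of a cohort table that are not EC features.
META_COLUMNS = ("subject_id", "group", "session", "response")


def adaptive_epsilon(y: np.ndarray) -> float:
    """Scale-adaptive SVR epsilon tube: IQR(y) / 13.49 (floored at 1e-6)."""
    q75, q25 = np.percentile(y, [75, 25])
    return max(float(q75 - q25) / 13.49, 1e-6)


def rbf_kernel(x, x2, sigma: float) -> float:
    """Gaussian (RBF) kernel value exp(-||x - x2||^2 / (2 sigma^2))."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise TpdcError("kernel inputs must have equal dimensions")
    if not (np.isfinite(x).all() and np.isfinite(x2).all()):
        raise TpdcError("kernel inputs must be finite")
    if not sigma > 0:
        raise TpdcError("sigma must be positive")
    return float(np.exp(-np.sum((x - x2) ** 2) / (2.0 * sigma**2)))


def _median_sq(d2_flat: np.ndarray) -> float:
    """Upper median of squared pairwise distances (deterministic partition
    pick, shared by every sigma computation in this module)."""
    if d2_flat.size == 0:
        return 0.0
    k = d2_flat.size // 2
    return float(np.partition(d2_flat, k)[k])


def median_sigma(X: np.ndarray) -> float:
    """Median-distance heuristic kernel width: the (upper) median pairwise
    Euclidean distance; falls back to 1.0 when all points coincide."""
    X = np.asarray(X, dtype=float)
    d2 = np.sum((X[:, None] - X[None]) ** 2, axis=-1)
    iu = np.triu_indices(len(X), k=1)
    med2 = _median_sq(d2[iu])
    return float(np.sqrt(med2)) if med2 > 0 else 1.0


@dataclass
class SVMConfig:
    """SVM settings: task ('regression' or 'classification'), the kernel
    width (``None`` = per-fold median heuristic), the fixed C, and the SVR
    epsilon tube (``None`` = the scale-adaptive convention IQR(y)/13.49,
    computed on each training fold)."""

    task: str = "regression"
    sigma: float | None = None
    C: float = 1.0
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise TpdcError("task must be 'regression' or 'classification'")
        if self.sigma is not None and not self.sigma > 0:
            raise TpdcError("sigma must be positive")


@dataclass
class CVConfig:
    """Nested cross-validation settings (k = 5 outer and inner by default)."""

    outer_k: int = 5
    inner_k: int = 5
    seed: int = 0
    stratified: bool = True


@dataclass
class ModelResult:
    """One evaluated feature subset."""

    subset: tuple[str, ...]
    fold_scores: np.ndarray
    mean_score: float
    score_se: float
    metrics: dict = field(default_factory=dict)
    inner_scores: np.ndarray | None = None
    shapley: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.subset) == 0:
            raise TpdcError("a model needs a non-empty feature subset")


# ---------------------------------------------------------------------------
# fast precomputed-kernel SVM


class _PrecomputedSVM:
    """Minimal SVR/SVC on a precomputed kernel, using the libsvm binding
    directly when available (identical solutions to the public estimators)."""

    def __init__(self, task: str, C: float = 1.0, epsilon: float | None = None):
        self.task = task
        self.C = C
        self.epsilon = epsilon

    def fit(self, K: np.ndarray, y: np.ndarray):
        K = np.ascontiguousarray(K, dtype=np.float64)
        if self.task == "classification":
            self.classes_ = np.unique(y)
            if len(self.classes_) != 2:
                raise TpdcError("classification requires exactly 2 classes")
            y = (np.asarray(y) == self.classes_[1]).astype(np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        eps = self.epsilon if self.epsilon is not None else adaptive_epsilon(y)
        if _libsvm is not None:
            svm_type = 0 if self.task == "classification" else 3
            out = _libsvm.fit(
                K,
                y,
                svm_type=svm_type,
                kernel="precomputed",
                C=self.C,
                epsilon=eps,
                tol=1e-3,
                cache_size=100.0,
            )
            self._support = out[0]
            self._dual = out[3].ravel()
            self._intercept = float(out[4][0])
            self._impl = "libsvm"
        else:  # public fallback
            est = (
                SVC(kernel="precomputed", C=self.C)
                if self.task == "classification"
                else SVR(kernel="precomputed", C=self.C, epsilon=eps)
            )
            self._est = est.fit(K, y)
            self._impl = "sklearn"
        return self

    def decision_values(self, Ktest: np.ndarray) -> np.ndarray:
        if self._impl == "libsvm":
            raw = Ktest[:, self._support] @ self._dual + self._intercept
            # libsvm's raw sign is opposite to sklearn's decision_function
            return -raw if self.task == "classification" else raw
        if self.task == "classification":
            return self._est.decision_function(Ktest)
        return self._est.predict(Ktest)

    def predict(self, Ktest: np.ndarray) -> np.ndarray:
        dec = self.decision_values(Ktest)
        if self.task == "classification":
            return self.classes_[(dec > 0).astype(int)]
        return dec


# ---------------------------------------------------------------------------
# scoring


def classification_metrics(
    y_true, y_pred, positive: str = "PD"
) -> dict[str, float]:
    """Accuracy, sensitivity and specificity in percent (positive class PD).

    A metric whose denominator is empty (a class absent from the fold) is
    returned as NaN and flagged with a warning; aggregation ignores NaNs.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    fp = int(np.sum(~pos & (y_pred == positive)))
    n = len(y_true)
    acc = 100.0 * (tp + tn) / n if n else np.nan
    if tp + fn:
        sens = 100.0 * tp / (tp + fn)
    else:
        logger.warning("no positive-class observations: sensitivity undefined")
        sens = np.nan
    if tn + fp:
        spec = 100.0 * tn / (tn + fp)
    else:
        logger.warning("no negative-class observations: specificity undefined")
        spec = np.nan
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan


def _outer_folds(y: np.ndarray, cv: CVConfig, classify: bool):
    if classify and cv.stratified:
        splitter = StratifiedKFold(cv.outer_k, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(cv.outer_k, shuffle=True, random_state=cv.seed)
    try:
        return list(splitter.split(np.zeros(len(y)), y if classify else None))
    except ValueError as err:
        raise TpdcError(f"cross-validation split failed: {err}") from err


def _feature_distances(X: np.ndarray) -> np.ndarray:
    """Per-feature squared-difference matrices, shape (m, n, n)."""
    diff = X[:, None, :] - X[None, :, :]
    return np.ascontiguousarray((diff**2).transpose(2, 0, 1))


def _eval_on_distances(
    D: np.ndarray,
    y: np.ndarray,
    folds,
    svm: SVMConfig,
    positive: str = "PD",
    collect_metrics: bool = False,
):
    """Outer-fold scores for one subset given its summed distance matrix."""
    classify = svm.task == "classification"
    scores = np.empty(len(folds))
    metrics: dict[str, list[float]] = {}
    for k, (tr, te) in enumerate(folds):
        Dtr = D[np.ix_(tr, tr)]
        if svm.sigma is not None:
            sigma2 = svm.sigma**2
        else:
            iu = np.triu_indices(len(tr), k=1)
            med2 = _median_sq(Dtr[iu])
            sigma2 = med2 if med2 > 0 else 1.0
        gamma = 1.0 / (2.0 * sigma2)
        if classify and len(np.unique(y[tr])) < 2:
            raise TpdcError(
                f"class absent from training fold {k}; use stratified splits"
            )
        model = _PrecomputedSVM(svm.task, C=svm.C, epsilon=svm.epsilon).fit(
            np.exp(-gamma * Dtr), y[tr]
        )
        Kte = np.exp(-gamma * D[np.ix_(te, tr)])
        pred = model.predict(Kte)
        if classify:
            fold_m = classification_metrics(y[te], pred, positive=positive)
            scores[k] = fold_m["accuracy"] / 100.0
            if collect_metrics:
                for name, val in fold_m.items():
                    metrics.setdefault(name, []).append(val)
        else:
            scores[k] = _r2(y[te], pred)
    return scores, {k: np.asarray(v) for k, v in metrics.items()}


def _se(scores: np.ndarray) -> float:
    scores = scores[np.isfinite(scores)]
    if len(scores) < 2:
        return 0.0
    return float(np.std(scores, ddof=1) / np.sqrt(len(scores)))


def _extract_xy(
    table: pd.DataFrame, subset, svm: SVMConfig
) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in subset if f not in table.columns]
    if missing:
        raise TpdcError(f"features not in table: {missing}")
    X = table[list(subset)].to_numpy(dtype=float)
    if svm.task == "classification":
        y = table["group"].to_numpy()
    else:
        if "response" not in table.columns:
            raise TpdcError("regression requires a 'response' column")
        y = table["response"].to_numpy(dtype=float)
    if X.shape[0] < 2 * 5:
        logger.warning("very small sample (n=%d) for nested CV", X.shape[0])
    return X, y


def nested_cv_evaluate(
    table: pd.DataFrame,
    subset,
    svm: SVMConfig | None = None,
    cv: CVConfig | None = None,
    run_inner: bool = True,
) -> ModelResult:
    """Nested cross-validation of one feature subset.

    For each outer fold, an inner k-fold loop on the outer-training data
    re-estimates the score (hyperparameters stay at their fixed defaults, so
    the inner loop is an evaluation harness, not a tuner); the final model is
    fit on the full outer-training data and scored on the untouched
    outer-test fold.  Outer-test rows never influence fitting.
    """
    svm = svm or SVMConfig()
    cv = cv or CVConfig()
    subset = tuple(subset)
    X, y = _extract_xy(table, subset, svm)
    classify = svm.task == "classification"
    folds = _outer_folds(y, cv, classify)
    D = _feature_distances(X).sum(axis=0)
    scores, metrics = _eval_on_distances(
        D, y, folds, svm, collect_metrics=classify
    )
    inner_scores = None
    if run_inner:
        inner_all = []
        for tr, _ in folds:
            y_tr = y[tr]
            inner_cv = CVConfig(
                outer_k=cv.inner_k, inner_k=cv.inner_k, seed=cv.seed + 1,
                stratified=cv.stratified,
            )
            inner_folds = _outer_folds(y_tr, inner_cv, classify)
            s, _ = _eval_on_distances(
                D[np.ix_(tr, tr)], y_tr, inner_folds, svm
            )
            inner_all.append(s.mean())
        inner_scores = np.asarray(inner_all)
    return ModelResult(
        subset=subset,
        fold_scores=scores,
        mean_score=float(np.nanmean(scores)),
        score_se=_se(scores),
        metrics=metrics,
        inner_scores=inner_scores,
    )


def _rank_key(r: ModelResult):
    return (-r.mean_score, r.score_se, len(r.subset), r.subset)


def select_optimal(results) -> ModelResult:
    """Best mean score; ties (within 1e-6) broken by minimal standard error,
    then smaller subset, then lexicographic subset order."""
    results = list(results)
    if not results:
        raise TpdcError("no models to select from")
    best_mean = max(r.mean_score for r in results)
    pool = [r for r in results if r.mean_score >= best_mean - 1e-6]
    min_se = min(r.score_se for r in pool)
    pool = [r for r in pool if r.score_se <= min_se + 1e-6]
    return min(pool, key=lambda r: (len(r.subset), r.subset))


def search_space_size(n_features: int) -> int:
    """Size of the full enumeration space, 2^m subsets (empty set included,
    as conventionally counted)."""
    return 2**n_features


def exhaustive_search(
    table: pd.DataFrame,
    svm: SVMConfig | None = None,
    cv: CVConfig | None = None,
    max_features: int | None = None,
    feature_cols=None,
    budget: int = 200_000,
    budget_override: bool = False,
    top_n: int | None = None,
) -> list[ModelResult]:
    """Evaluate every non-empty feature subset and rank by the optimal-model
    rule.

    The full enumeration space over m features is 2^m subsets (logged before
    any fitting); the evaluated count excludes the empty set and respects
    ``max_features``.  A run-count above ``budget`` is refused unless
    ``budget_override`` is set.  Results are returned ranked; ``top_n``
    truncates the returned list (ranking is computed over all evaluations).
    """
    svm = svm or SVMConfig()
    cv = cv or CVConfig()
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    m = len(feature_cols)
    logger.info(
        "exhaustive search over %d features: full space 2^%d = %d subsets",
        m, m, search_space_size(m),
    )
    cap = max_features or m
    n_eval = sum(comb(m, s) for s in range(1, cap + 1))
    if m > 25 and max_features is None:
        raise TpdcError("more than 25 features requires a max_features cap")
    if n_eval > budget and not budget_override:
        raise TpdcError(
            f"{n_eval} subset evaluations exceed the budget of {budget}; "
            "pass budget_override=True to proceed"
        )
    X, y = _extract_xy(table, feature_cols, svm)
    classify = svm.task == "classification"
    folds = _outer_folds(y, cv, classify)
    Df = _feature_distances(X)  # (m, n, n)

    # Per-fold permuted layout: rows/cols ordered [train..., test...] so that
    # every subset evaluation works on contiguous views instead of fancy
    # indexing.  Subset distance matrices accumulate incrementally along the
    # combination tree (each subset extends its prefix by one feature).
    n = len(y)
    fold_data = []
    for tr, te in folds:
        perm = np.concatenate([tr, te])
        P = np.ascontiguousarray(Df[:, perm[:, None], perm[None, :]])
        ntr = len(tr)
        iu = np.triu_indices(ntr, k=1)
        triu_flat = iu[0] * n + iu[1]  # flat indices into the (n, ntr) block
        y_tr = np.ascontiguousarray(y[tr], dtype=float) if not classify else y[tr]
        y_te = y[te]
        if classify:
            if len(np.unique(y_tr)) < 2:
                raise TpdcError(
                    "class absent from a training fold; use stratified splits"
                )
            classes = np.unique(y_tr)
            y_tr_num = np.ascontiguousarray(
                (y_tr == classes[1]).astype(float)
            )
            y_te_num = (y_te == classes[1]).astype(float)
            fold_data.append((P, ntr, triu_flat, y_tr_num, y_te_num, 0.0))
        else:
            ss_tot = float(np.sum((y_te - y_te.mean()) ** 2))
            fold_data.append((P, ntr, triu_flat, y_tr, y_te, ss_tot))

    svm_type = 0 if classify else 3
    fixed_sigma2 = svm.sigma**2 if svm.sigma is not None else None
    C_ = svm.C
    fold_eps = [
        svm.epsilon if svm.epsilon is not None else adaptive_epsilon(fd[3])
        for fd in fold_data
    ]
    use_fast = _libsvm is not None

    def _score_subset(accs) -> np.ndarray:
        scores = np.empty(len(fold_data))
        for k, (acc, (P, ntr, triu_flat, y_tr, y_te, ss_tot)) in enumerate(
            zip(accs, fold_data)
        ):
            if fixed_sigma2 is not None:
                sigma2 = fixed_sigma2
            else:
                tri = acc[:ntr].ravel()[triu_flat]
                med2 = float(np.partition(tri, tri.size // 2)[tri.size // 2])
                sigma2 = med2 if med2 > 0 else 1.0  # median of squared distances
            K = np.exp(acc[:, :ntr] * (-0.5 / sigma2))
            if use_fast:
                out = _libsvm.fit(
                    K[:ntr], y_tr, svm_type=svm_type, kernel="precomputed",
                    C=C_, epsilon=fold_eps[k], tol=1e-3, cache_size=100.0,
                )
                dec = K[ntr:][:, out[0]] @ out[3].ravel() + out[4][0]
                if classify:
                    # libsvm raw sign: negative decision -> second class
                    pred = (dec < 0).astype(float)
                else:
                    pred = dec
            else:
                model = _PrecomputedSVM(svm.task, C=C_, epsilon=fold_eps[k]).fit(
                    K[:ntr], y_tr
                )
                pred = model.predict(K[ntr:])
                if classify:
                    pred = (pred == model.classes_[1]).astype(float)
            if classify:
                scores[k] = float(np.mean(pred == y_te))
            else:
                ss_res = float(np.sum((y_te - pred) ** 2))
                scores[k] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return scores

    results: list[ModelResult] = []

    def _recurse(start: int, chosen: tuple[int, ...], accs) -> None:
        for j in range(start, m):
            new_accs = [acc + fd[0][j] for acc, fd in zip(accs, fold_data)]
            sub_idx = chosen + (j,)
            scores = _score_subset(new_accs)
            results.append(
                ModelResult(
                    subset=tuple(feature_cols[i] for i in sub_idx),
                    fold_scores=scores,
                    mean_score=float(np.nanmean(scores)),
                    score_se=_se(scores),
                )
            )
            if len(sub_idx) < cap:
                _recurse(j + 1, sub_idx, new_accs)

    zero_accs = [np.zeros((n, n)) for _ in fold_data]
    _recurse(0, (), zero_accs)
    results.sort(key=_rank_key)
    logger.info("evaluated %d subsets", len(results))
    return results[:top_n] if top_n else results


def shapley_by_fold(
    table: pd.DataFrame,
    subset,
    svm: SVMConfig | None = None,
    cv: CVConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature mean |phi| per group for one subset, averaged over folds.

    For every outer fold the model is refit on the training rows, a Kernel
    SHAP explainer is built with that training fold as background, and the
    test-fold observations are explained; group-wise mean absolute Shapley
    values are then averaged across folds.
    """
    svm = svm or SVMConfig()
    cv = cv or CVConfig()
    subset = tuple(subset)
    X, y = _extract_xy(table, subset, svm)
    groups = table["group"].to_numpy() if "group" in table.columns else np.array(
        ["all"] * len(X)
    )
    classify = svm.task == "classification"
    folds = _outer_folds(y, cv, classify)
    fold_tables = []
    for tr, te in folds:
        Xtr, Xte = X[tr], X[te]
        sigma = svm.sigma or median_sigma(Xtr)
        gamma = 1.0 / (2.0 * sigma**2)

        def kernel(A, B=Xtr, g=gamma):
            d2 = np.sum((A[:, None] - B[None]) ** 2, axis=-1)
            return np.exp(-g * d2)

        model = _PrecomputedSVM(svm.task, C=svm.C, epsilon=svm.epsilon).fit(
            kernel(Xtr), y[tr]
        )
        predict = lambda A: model.decision_values(kernel(np.atleast_2d(A)))
        explainer = KernelShapExplainer(predict, Xtr, seed=seed)
        phi = explainer.shap_values(Xte)
        df = pd.DataFrame(phi, columns=list(subset))
        df["group"] = groups[te]
        fold_tables.append(df)
    return aggregate_shapley(fold_tables)


def aggregate_shapley(fold_tables) -> pd.DataFrame:
    """Mean absolute Shapley value per feature and group, averaged over folds.

    ``fold_tables`` are DataFrames with one column per feature plus a
    ``group`` column; the result has features as rows (ranked descending by
    the group average) and groups as columns.
    """
    fold_tables = list(fold_tables)
    if not fold_tables:
        raise TpdcError("no fold tables to aggregate")
    feats = [c for c in fold_tables[0].columns if c != "group"]
    per_fold = []
    for df in fold_tables:
        if [c for c in df.columns if c != "group"] != feats:
            raise TpdcError("inconsistent feature sets across folds")
        per_fold.append(df.groupby("group")[feats].agg(lambda s: s.abs().mean()))
    agg = pd.concat(per_fold).groupby(level=0).mean().T  # features x groups
    return agg.loc[agg.mean(axis=1).sort_values(ascending=False).index]


class ExhaustiveSVMSelector(BaseEstimator):
    """Exhaustive RBF-SVM feature selection with nested CV, sklearn-style.

    ``fit(X, y)`` enumerates feature subsets (up to ``max_features``),
    evaluates each by outer-fold cross-validation with fixed hyperparameters,
    and stores the ranked results.  ``predict`` uses the optimal subset refit
    on the full data.
    """

    def __init__(
        self,
        task: str = "regression",
        max_features: int | None = None,
        outer_k: int = 5,
        inner_k: int = 5,
        seed: int = 0,
        C: float = 1.0,
        sigma: float | None = None,
        budget: int = 200_000,
        budget_override: bool = False,
    ):
        self.task = task
        self.max_features = max_features
        self.outer_k = outer_k
        self.inner_k = inner_k
        self.seed = seed
        self.C = C
        self.sigma = sigma
        self.budget = budget
        self.budget_override = budget_override

    def _configs(self):
        return (
            SVMConfig(task=self.task, sigma=self.sigma, C=self.C),
            CVConfig(outer_k=self.outer_k, inner_k=self.inner_k, seed=self.seed),
        )

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
        table = pd.DataFrame(X, columns=list(feature_names))
        if self.task == "classification":
            table["group"] = np.asarray(y)
        else:
            table["response"] = np.asarray(y, dtype=float)
        svm, cv = self._configs()
        self.n_enumerated_ = search_space_size(X.shape[1])
        self.results_ = exhaustive_search(
            table,
            svm,
            cv,
            max_features=self.max_features,
            feature_cols=list(feature_names),
            budget=self.budget,
            budget_override=self.budget_override,
        )
        self.best_result_ = select_optimal(self.results_)
        self.feature_names_ = list(feature_names)
        # refit the optimal subset on the full data for predict()
        idx = [self.feature_names_.index(f) for f in self.best_result_.subset]
        self._X_fit = X[:, idx]
        sigma = self.sigma or median_sigma(self._X_fit)
        self._gamma = 1.0 / (2.0 * sigma**2)
        self._idx = idx
        K = np.exp(
            -self._gamma
            * np.sum((self._X_fit[:, None] - self._X_fit[None]) ** 2, axis=-1)
        )
        self._model = _PrecomputedSVM(self.task, C=self.C).fit(
            K, np.asarray(y) if self.task == "classification" else np.asarray(y, float)
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)[:, self._idx]
        K = np.exp(
            -self._gamma * np.sum((X[:, None] - self._X_fit[None]) ** 2, axis=-1)
        )
        return self._model.predict(K)
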