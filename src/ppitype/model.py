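"""Per-type logistic classifiers over detection-method features.

One binary logistic model (a plain binomial GLM: p(x) = 1/(1+e^-(b0+b'x)))
is fitted per interaction type, positives against a negative set drawn from
other specific types plus well-annotated untyped interactions.  Performance
is measured by repeated stratified 10-fold cross-validation; the deployment
cutoff per type maximizes sensitivity + specificity on the pooled
out-of-fold scores, after which the model is refitted on the full training
set.

The estimator follows scikit-learn conventions (``fit`` / ``predict_proba``
/ ``get_params``), so it composes with sklearn model selection; the
module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y

from .interactions import UniqueInteraction
from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "TypeLogisticModel",
    "TrainingSet",
    "ROCResult",
    "CVResult",
    "eligible_types",
    "assemble_training_set",
    "fit_logistic",
    "roc_auc",
    "youden_cutoff",
    "cross_validate",
    "train_predictor",
    "predict_all",
]


class TypeLogisticModel(BaseEstimator, ClassifierMixin):
    """Unregularized logistic regression with a tiny-L2 separation fallback.

    The default fit is plain maximum likelihood.  When the optimizer fails
    to converge (the signature of perfect separation on binary features) or
    coefficients diverge, the model is refitted with a tiny L2 penalty
    (``l2_fallback``) and flagged via ``stabilized_``.

    Parameters
    ----------
    type_id:
        Interaction-type term this model predicts (metadata only).
    l2_fallback:
        Ridge strength lambda used by the stabilized refit (default 1e-6).
    max_iter, tol:
        Passed to the underlying lbfgs solver.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients.
    weights_ : dict feature name -> coefficient (when X is a DataFrame).
    stabilized_ : True iff the tiny-L2 fallback was used.
    cutoff_ : decision cutoff on the probability scale; set by
        :func:`train_predictor` (or ``set_cutoff``), not by ``fit``.
    """

    def __init__(
        self,
        type_id: str | None = None,
        l2_fallback: float = 1e-6,
        max_iter: int = 1000,
        tol: float = 1e-8,
    ):
        self.type_id = type_id
        self.l2_fallback = l2_fallback
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        X_arr, y_arr = check_X_y(np.asarray(X, dtype=float), y)
        classes = np.unique(y_arr)
        if len(classes) != 2:
            raise ValueError("TypeLogisticModel requires exactly two classes")
        self.classes_ = classes
        self.stabilized_ = False
        needs_fallback = False
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                inner = LogisticRegression(
                    C=np.inf, solver="lbfgs",
                    max_iter=self.max_iter, tol=self.tol,
                ).fit(X_arr, y_arr)
                # |beta| ~ 30 on binary features means probabilities pinned
                # to 0/1 — the signature of (near-)separation, not a usable MLE
                if np.abs(inner.coef_).max() > 30.0:
                    needs_fallback = True
            except ConvergenceWarning:
                needs_fallback = True
        if needs_fallback:
            # separation or singularity: a tiny ridge pins the fit down
            self.stabilized_ = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                inner = LogisticRegression(
                    C=1.0 / self.l2_fallback, solver="lbfgs",
                    max_iter=self.max_iter, tol=self.tol,
                ).fit(X_arr, y_arr)
        self.coef_ = inner.coef_
        self.intercept_ = inner.intercept_
        self.n_features_in_ = X_arr.shape[1]
        if feature_names is not None:
            self.feature_names_in_ = np.asarray(feature_names, dtype=object)
            self.weights_ = dict(zip(feature_names, self.coef_[0]))
        self.cutoff_ = None
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X_arr = np.asarray(X, dtype=float)
        return X_arr @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        cutoff = self.cutoff_ if self.cutoff_ is not None else 0.5
        return (self.predict_proba(X)[:, 1] >= cutoff).astype(int)

    def set_cutoff(self, cutoff: float) -> "TypeLogisticModel":
        check_is_fitted(self, "coef_")
        self.cutoff_ = float(cutoff)
        return self


@dataclass
class TrainingSet:
    """Positive/negative interaction ids and labels for one type."""

    type_id: str
    positive_ids: list[str]
    negative_ids: list[str]

    @property
    def ids(self) -> list[str]:
        return self.positive_ids + self.negative_ids

    @property
    def y(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positive_ids), dtype=int),
             np.zeros(len(self.negative_ids), dtype=int)]
        )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class CVResult:
    type_id: str
    aucs: list[float]
    pooled_scores: np.ndarray = field(repr=False, default=None)
    pooled_labels: np.ndarray = field(repr=False, default=None)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def eligible_types(
    interactions: Sequence[UniqueInteraction],
    ontology_types: Ontology,
    specific_roots: Iterable[str],
    min_positives: int = 20,
    excluded: Iterable[str] = (),
) -> list[str]:
    """Specific interaction types with enough annotated interactions.

    Candidates are the terms in the subtrees rooted at ``specific_roots``
    (the enzymatic-reaction and covalent-binding branches); types closed-
    annotated to fewer than ``min_positives`` interactions (default 20) and
    explicitly ``excluded`` high-level terms (e.g. the enzymatic-reaction
    root itself, whose prediction would be redundant) are dropped.
    """
    candidates: set[str] = set()
    for root in specific_roots:
        candidates |= ontology_types.subtree(root)
    candidates -= set(excluded)
    counts = {t: 0 for t in candidates}
    for ui in interactions:
        for t in ui.types_closed & candidates:
            counts[t] += 1
    return sorted(t for t, c in counts.items() if c >= min_positives)


def assemble_training_set(
    interactions: Sequence[UniqueInteraction],
    type_id: str,
    matrix: pd.DataFrame,
    rng: np.random.Generator,
    specific_types: Iterable[str],
    min_negatives: int = 100,
    min_direct_methods: int = 4,
) -> TrainingSet:
    """Positives and a sampled negative set for one interaction type.

    Positives: every matrix interaction closed-annotated to ``type_id``.
    Negative target size: max(|positives|, ``min_negatives``).  Negatives
    come first from interactions carrying a different specific type (never
    ``type_id`` — multi-type interactions are barred), subsampled uniformly
    if over target; then topped up with random untyped interactions having
    at least ``min_direct_methods`` direct detection methods.
    """
    specific = set(specific_types)
    in_matrix = set(matrix.index)
    positives, other_type, random_pool = [], [], []
    for ui in interactions:
        pid = ui.pair_id
        if pid not in in_matrix:
            continue
        if type_id in ui.types_closed:
            positives.append(pid)
        elif ui.types_closed & specific:
            other_type.append(pid)
        elif len(ui.methods_direct) >= min_direct_methods:
            random_pool.append(pid)
    if not positives:
        raise ValueError(f"no positive interactions for type {type_id}")
    target = max(len(positives), min_negatives)
    if len(other_type) >= target:
        negatives = list(rng.choice(other_type, size=target, replace=False))
    else:
        negatives = list(other_type)
        need = target - len(negatives)
        if need > len(random_pool):
            logger.warning(
                "type %s: negative pool exhausted (%d < target %d)",
                type_id, len(negatives) + len(random_pool), target,
            )
            need = len(random_pool)
        if need:
            negatives += list(rng.choice(random_pool, size=need, replace=False))
    return TrainingSet(type_id=type_id, positive_ids=positives,
                       negative_ids=negatives)


def fit_logistic(matrix_subset: pd.DataFrame, y, **kwargs) -> TypeLogisticModel:
    """Fit one logistic model; see :class:`TypeLogisticModel`."""
    return TypeLogisticModel(**kwargs).fit(matrix_subset, y)


def roc_auc(scores, y) -> ROCResult:
    """ROC curve and rank-based AUC with tie correction.

    AUC is the normalized Mann-Whitney U of the positive-class scores; the
    curve is evaluated at midpoints between consecutive unique scores plus
    one threshold below the minimum and one above the maximum (a sample is
    called positive when score >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    uniq = np.unique(scores)
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]]
    )
    sens = np.array([(scores[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(scores[y == 0] < t).mean() for t in thresholds])
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=float(auc))


def youden_cutoff(roc: ROCResult) -> float:
    """Threshold maximizing sensitivity + specificity (Youden's J).

    Ties are broken toward higher specificity (the larger threshold).
    """
    j = roc.sensitivity + roc.specificity
    best = np.flatnonzero(j == j.max())
    # among maxima prefer the highest specificity, then the larger threshold
    order = np.lexsort((best, roc.specificity[best]))
    return float(roc.thresholds[best[order[-1]]])


def _stratified_fold_scores(
    X: np.ndarray, y: np.ndarray, k: int, seed: int, max_retries: int = 5,
    **model_kwargs,
) -> np.ndarray:
    """Out-of-fold probability scores from one stratified k-fold pass."""
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + attempt)
        try:
            splits = list(skf.split(X, y))
            if any(len(np.unique(y[tr])) < 2 for tr, _ in splits):
                continue
        except ValueError:
            continue
        scores = np.empty(len(y))
        for train_idx, test_idx in splits:
            m = TypeLogisticModel(**model_kwargs).fit(X[train_idx], y[train_idx])
            scores[test_idx] = m.predict_proba(X[test_idx])[:, 1]
        return scores
    raise ValueError("could not build folds with both classes present")


def cross_validate(
    interactions: Sequence[UniqueInteraction],
    type_id: str,
    matrix: pd.DataFrame,
    specific_types: Iterable[str],
    k: int = 10,
    repeats: int = 20,
    rng: np.random.Generator | None = None,
    min_negatives: int = 100,
    min_direct_methods: int = 4,
    permute_labels: bool = False,
    **model_kwargs,
) -> CVResult:
    """Repeated stratified k-fold cross-validation with fresh negative sets.

    Each repeat draws a new negative set, partitions the data into k
    stratified folds, scores every example out of fold, and yields one AUC
    from the pooled fold scores.  Defaults: k=10, repeats=20.

    ``permute_labels=True`` shuffles the class labels within each repeat's
    training set before fitting — a permutation null whose mean AUC should
    sit at 0.5, useful for calibration checks.
    """
    rng = np.random.default_rng(rng)
    specific = list(specific_types)
    aucs, all_scores, all_labels = [], [], []
    for _ in range(repeats):
        ts = assemble_training_set(
            interactions, type_id, matrix, rng, specific,
            min_negatives=min_negatives, min_direct_methods=min_direct_methods,
        )
        X = matrix.loc[ts.ids].to_numpy(dtype=float)
        y = ts.y
        if permute_labels:
            y = rng.permutation(y)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        scores = _stratified_fold_scores(X, y, k, fold_seed, **model_kwargs)
        aucs.append(roc_auc(scores, y).auc)
        all_scores.append(scores)
        all_labels.append(y)
    return CVResult(
        type_id=type_id,
        aucs=aucs,
        pooled_scores=np.concatenate(all_scores),
        pooled_labels=np.concatenate(all_labels),
    )


def train_predictor(
    interactions: Sequence[UniqueInteraction],
    type_id: str,
    matrix: pd.DataFrame,
    specific_types: Iterable[str],
    k: int = 10,
    repeats: int = 20,
    rng: np.random.Generator | None = None,
    min_negatives: int = 100,
    min_direct_methods: int = 4,
    **model_kwargs,
) -> tuple[TypeLogisticModel, CVResult]:
    """Cross-validate, pick the Youden cutoff from pooled out-of-fold
    scores, and refit the deployed model on a full training set."""
    rng = np.random.default_rng(rng)
    specific = list(specific_types)
    cv = cross_validate(
        interactions, type_id, matrix, specific, k=k, repeats=repeats,
        rng=rng, min_negatives=min_negatives,
        min_direct_methods=min_direct_methods, **model_kwargs,
    )
    cutoff = youden_cutoff(roc_auc(cv.pooled_scores, cv.pooled_labels))
    ts = assemble_training_set(
        interactions, type_id, matrix, rng, specific,
        min_negatives=min_negatives, min_direct_methods=min_direct_methods,
    )
    model = TypeLogisticModel(type_id=type_id, **model_kwargs)
    model.fit(matrix.loc[ts.ids], ts.y)
    model.set_cutoff(np.clip(cutoff, 0.0, 1.0))
    return model, cv


def predict_all(
    predictors: Mapping[str, TypeLogisticModel], matrix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every interaction with every per-type model.

    Returns (scores, calls): DataFrames interactions x types; a call is
    score >= that type's cutoff.  An interaction may receive 0, 1 or
    several types.
    """
    scores = {}
    calls = {}
    for type_id, model in predictors.items():
        if hasattr(model, "feature_names_in_") and list(
            model.feature_names_in_
        ) != list(matrix.columns):
            raise ValueError(
                f"feature mismatch between matrix and predictor {type_id}"
            )
        p = model.predict_proba(matrix.to_numpy(dtype=float))[:, 1]
        scores[type_id] = p
        cutoff = model.cutoff_ if model.cutoff_ is not None else 0.5
        calls[type_id] = p >= cutoff
    score_df = pd.DataFrame(scores, index=matrix.index)
    call_df = pd.DataFrame(calls, index=matrix.index)
    return score_df, call_df
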