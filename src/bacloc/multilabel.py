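"""Label Powerset learning and decision-level OR-consensus.

The Label Powerset (LP) transformation turns the multi-label problem
into one multi-class problem whose classes are the distinct label
subsets observed in training; any probabilistic multi-class classifier
can then act as the base learner (Random Forest by default, RBF-SVM as
the alternative).  Per-label marginal scores are recovered from the
class posterior by summing the posterior mass of every class whose
subset contains the label.

The consensus combiner unions the hard decisions of several LP models
(element-wise OR), which can only add locations — it trades precision
for recall and is how multi-site proteins are recovered from
single-subset members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import FeatureMatrix, LabelMatrix, LabelUniverse, PredictionSet

BASE_CLASSIFIERS = ("rf", "svm")


def _make_base(base: str, seed: int, n_estimators: int, **kwargs):
    if base == "rf":
        return RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, **kwargs
        )
    if base == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", probability=True, random_state=seed, **kwargs),
        )
    raise ValueError(f"base classifier must be one of {BASE_CLASSIFIERS}, got {base!r}")


@dataclass
class LPModel:
    """A fitted Label Powerset model for one feature view."""

    universe: LabelUniverse
    classes: np.ndarray  # K x Q binary matrix, one row per observed label subset
    class_counts: np.ndarray  # training frequency of each class
    base: object  # fitted scikit-learn classifier over class indices
    view: str
    seed: int
    feature_columns: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return self.classes.shape[0]


def lp_fit(
    X: FeatureMatrix,
    Y: LabelMatrix,
    base: str = "rf",
    seed: int = 0,
    n_estimators: int = 500,
    **base_kwargs,
) -> LPModel:
    """Fit the Label Powerset transformation of (X, Y).

    Each distinct observed label subset becomes one multi-class target.
    Classes observed on a single training protein are legal but flagged,
    since they cannot be stratified across cross-validation folds.
    """
    if X.n == 0:
        raise ValueError("cannot fit on an empty feature matrix")
    if X.ids != Y.ids:
        raise ValueError(f"view {X.view}: feature and label ids are not aligned")
    # Zero-width views (e.g. a GO view with an empty vocabulary, when no
    # training protein carries any annotation) are legal: with nothing to
    # split on the model degenerates to the training class prior.
    features = X.X if X.d > 0 else np.zeros((X.n, 1))

    subsets: dict[tuple[int, ...], int] = {}
    targets = np.empty(Y.n, dtype=int)
    for row, y in enumerate(Y.Y):
        key = tuple(int(v) for v in y)
        targets[row] = subsets.setdefault(key, len(subsets))
    classes = np.array(list(subsets), dtype=np.int8)
    counts = np.bincount(targets, minlength=len(subsets))
    singletons = int((counts == 1).sum())
    if singletons:
        warnings.warn(
            f"view {X.view}: {singletons} label-subset class(es) have a single "
            "training example; they cannot be stratified across CV folds",
            stacklevel=2,
        )
    clf = _make_base(base, seed, n_estimators, **base_kwargs)
    clf.fit(features, targets)
    return LPModel(
        universe=Y.universe,
        classes=classes,
        class_counts=counts,
        base=clf,
        view=X.view,
        seed=seed,
        feature_columns=X.columns,
    )


def lp_predict(model: LPModel, X: FeatureMatrix) -> PredictionSet:
    """Predict label subsets and per-label marginal scores.

    The hard prediction is the label subset of the maximum-posterior
    class (ties broken by higher training frequency, then lexicographic
    subset order); the score of label j is the total posterior mass of
    classes containing j, so scores lie in [0, 1] and need not match the
    hard decision's bits.
    """
    if X.columns != model.feature_columns:
        missing = set(model.feature_columns) - set(X.columns)
        extra = set(X.columns) - set(model.feature_columns)
        raise ValueError(
            f"view {model.view}: feature schema mismatch "
            f"(missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]})"
        )
    features = X.X if X.d > 0 else np.zeros((X.n, 1))
    posterior = model.base.predict_proba(features)  # N x K', K' = classes seen by base
    base_classes = np.asarray(model.base.classes_ if hasattr(model.base, "classes_")
                              else model.base[-1].classes_, dtype=int)
    # Expand to the full class list (folds may miss classes; mass 0 there).
    full = np.zeros((X.n, model.n_classes))
    full[:, base_classes] = posterior

    membership = model.classes.astype(float)  # K x Q
    scores = np.clip(full @ membership, 0.0, 1.0)

    # Deterministic argmax: probability desc, then training count desc,
    # then lexicographic class subset.
    subset_rank = np.array(
        sorted(range(model.n_classes), key=lambda k: tuple(model.classes[k]))
    ).argsort()
    predicted = np.empty((X.n, model.universe.q), dtype=np.int8)
    for row in range(X.n):
        p = full[row]
        best = p.max()
        candidates = np.flatnonzero(p == best)
        order = sorted(
            candidates, key=lambda k: (-model.class_counts[k], subset_rank[k])
        )
        predicted[row] = model.classes[order[0]]
    return PredictionSet(
        ids=list(X.ids),
        predicted=predicted,
        scores=scores,
        universe=model.universe,
        model_id=f"lp_{model.view}",
    )


def consensus_or(members: Sequence[PredictionSet], model_id: str = "consensus") -> PredictionSet:
    """Element-wise OR of member hard decisions; scores are element-wise max.

    The max-score combination is used only so the consensus can still be
    ranked (ROC, rank-loss); the decision itself is purely the OR.
    """
    if len(members) < 2:
        raise ValueError("consensus needs at least 2 member prediction sets")
    first = members[0]
    for m in members[1:]:
        if m.ids != first.ids:
            raise ValueError("consensus members must share identical id order")
        if m.universe != first.universe:
            raise ValueError("consensus members must share the label universe")
    predicted = np.bitwise_or.reduce([m.predicted for m in members])
    scores = np.maximum.reduce([m.scores for m in members])
    return PredictionSet(
        ids=list(first.ids),
        predicted=predicted,
        scores=scores,
        universe=first.universe,
        model_id=model_id,
    )


def feature_fusion(views: Sequence[FeatureMatrix], view_name: str | None = None) -> FeatureMatrix:
    """Column-wise concatenation of views sharing the same protein order."""
    if not views:
        raise ValueError("no views to fuse")
    first = views[0]
    for v in views[1:]:
        if v.ids != first.ids:
            raise ValueError(f"view {v.view}: id order differs from {first.view}")
    if len(views) == 1:
        return first
    name = view_name or "+".join(v.view for v in views)
    X = np.hstack([v.X for v in views])
    columns = tuple(f"{v.view}:{c}" for v in views for c in v.columns)
    return FeatureMatrix(list(first.ids), name, X, columns)
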