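"""Multi-label evaluation: example- and label-based metrics, per-location
confusion tables, ROC/AUC and the 5-fold cross-validation harness.

Example-based metrics average a per-instance quantity over the N test
proteins (per-instance Jaccard, precision, recall, F1, exact match,
Hamming mismatch fraction, pairwise ranking loss).  Label-based metrics
first count TP/FP/FN/TN per location and either average per-label ratios
(macro) or pool the counts (micro).

Conventions for degenerate cases (they cannot arise from a Label
Powerset model, whose predictions are always observed subsets, but the
evaluator accepts arbitrary matrices):

* an empty predicted set contributes 0 to the per-instance precision
  (and its Jaccard uses the true set as the union);
* a label with a zero denominator contributes 0 to a macro average and
  is counted in a warning;
* instances whose labels are all relevant or all irrelevant carry no
  ranking information and are excluded (but counted) by the rank loss.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datatypes import FeatureMatrix, GOAnnotationSet, LabelMatrix, LabelUniverse, PredictionSet
from .features import build_go_vocabulary, go_encode
from .multilabel import consensus_or, feature_fusion, lp_fit, lp_predict

logger = logging.getLogger(__name__)


def _as_binary(Y) -> np.ndarray:
    arr = Y.Y if isinstance(Y, LabelMatrix) else np.asarray(Y)
    arr = np.asarray(arr, dtype=np.int8)
    if arr.ndim != 2:
        raise ValueError("expected an N x Q binary matrix")
    return arr


def _check_shapes(Y: np.ndarray, Yhat: np.ndarray) -> None:
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: truth {Y.shape} vs prediction {Yhat.shape}")


# ---------------------------------------------------------------------------
# Example-based metrics


def example_metrics(Y, Yhat) -> dict[str, float]:
    """Instance-averaged accuracy (Jaccard), precision, recall, F1,
    subset accuracy and Hamming loss."""
    Y, Yhat = _as_binary(Y), _as_binary(Yhat)
    _check_shapes(Y, Yhat)
    if (Y.sum(axis=1) == 0).any():
        raise ValueError("every truth row must have at least one location")
    inter = (Y & Yhat).sum(axis=1).astype(float)
    union = (Y | Yhat).sum(axis=1).astype(float)
    sy = Y.sum(axis=1).astype(float)
    sp = Yhat.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision_terms = np.where(sp > 0, inter / np.where(sp > 0, sp, 1), 0.0)
    return {
        "accuracy_score": float((inter / union).mean()),
        "precision": float(precision_terms.mean()),
        "recall": float((inter / sy).mean()),
        "f1": float((2 * inter / (sy + sp)).mean()),
        "subset_accuracy": float((Y == Yhat).all(axis=1).mean()),
        "hamming_loss": float((Y != Yhat).mean()),
    }


def rank_loss(Y, scores, return_excluded: bool = False):
    """Average proportion of (relevant, irrelevant) label pairs ranked in
    the wrong order, with half credit for ties."""
    Y = _as_binary(Y)
    S = np.asarray(scores, dtype=float)
    _check_shapes(Y, S)
    if not np.isfinite(S).all():
        raise ValueError("scores must be finite")
    losses = []
    excluded = 0
    for y, s in zip(Y, S):
        rel = np.flatnonzero(y == 1)
        irr = np.flatnonzero(y == 0)
        if rel.size == 0 or irr.size == 0:
            excluded += 1
            continue
        diff = s[irr][None, :] - s[rel][:, None]
        bad = (diff > 0).sum() + 0.5 * (diff == 0).sum()
        losses.append(bad / (rel.size * irr.size))
    if excluded:
        logger.info("rank_loss: %d instance(s) carry no ranking information", excluded)
    value = float(np.mean(losses)) if losses else 0.0
    return (value, excluded) if return_excluded else value


# ---------------------------------------------------------------------------
# Label-based metrics


def label_metrics_from_counts(
    tp: np.ndarray, fp: np.ndarray, fn: np.ndarray
) -> dict[str, float]:
    """Macro/micro precision, recall and F1 from per-label counts.

    ``macro_f1`` is the harmonic mean of the macro-averaged precision and
    recall; ``macro_f1_per_label`` is the unweighted mean of per-label F1
    scores (both conventions circulate in the literature, so both are
    reported).  Labels with a zero denominator contribute 0 and are
    flagged with a warning.
    """
    tp, fp, fn = (np.asarray(a, dtype=float) for a in (tp, fp, fn))

    def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
        bad = den == 0
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} label(s) with zero denominator in {what}; "
                "they contribute 0 to the macro average",
                stacklevel=3,
            )
        return np.where(bad, 0.0, num / np.where(bad, 1.0, den))

    prec_j = _safe_ratio(tp, tp + fp, "precision")
    rec_j = _safe_ratio(tp, tp + fn, "recall")
    f1_j = _safe_ratio(2 * tp, 2 * tp + fp + fn, "F1")
    macro_p = float(prec_j.mean())
    macro_r = float(rec_j.mean())
    micro_p = float(tp.sum() / (tp.sum() + fp.sum())) if (tp.sum() + fp.sum()) else 0.0
    micro_r = float(tp.sum() / (tp.sum() + fn.sum())) if (tp.sum() + fn.sum()) else 0.0
    return {
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "macro_f1": _harmonic(macro_p, macro_r),
        "macro_f1_per_label": float(f1_j.mean()),
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f1": _harmonic(micro_p, micro_r),
    }


def _harmonic(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def label_metrics(Y, Yhat) -> dict[str, float]:
    """Label-based metrics from truth/prediction matrices."""
    Y, Yhat = _as_binary(Y), _as_binary(Yhat)
    _check_shapes(Y, Yhat)
    tp = ((Y == 1) & (Yhat == 1)).sum(axis=0)
    fp = ((Y == 0) & (Yhat == 1)).sum(axis=0)
    fn = ((Y == 1) & (Yhat == 0)).sum(axis=0)
    return label_metrics_from_counts(tp, fp, fn)


def hamming_loss_from_counts(fp: np.ndarray, fn: np.ndarray, n: int, q: int) -> float:
    """Pooled-count identity for the Hamming loss: (sum FP + sum FN) / (N*Q)."""
    return float((np.sum(fp) + np.sum(fn)) / (n * q))


CONFUSION_COLUMNS = (
    "TP", "FP", "FN", "TN", "Correct", "Wrong",
    "%TP", "%FP", "%FN", "%TN", "%Correct",
)


def location_confusion(Y, Yhat, universe: LabelUniverse) -> pd.DataFrame:
    """Per-location confusion table (TP/FP/FN/TN, Correct/Wrong and the
    display fractions of N, rounded to 2 d.p.)."""
    Y, Yhat = _as_binary(Y), _as_binary(Yhat)
    _check_shapes(Y, Yhat)
    n = Y.shape[0]
    rows = {}
    for j, (code, name) in enumerate(zip(universe.codes, universe.names)):
        tp = int(((Y[:, j] == 1) & (Yhat[:, j] == 1)).sum())
        fp = int(((Y[:, j] == 0) & (Yhat[:, j] == 1)).sum())
        fn = int(((Y[:, j] == 1) & (Yhat[:, j] == 0)).sum())
        tn = int(((Y[:, j] == 0) & (Yhat[:, j] == 0)).sum())
        rows[f"{name} ({code})"] = [
            tp, fp, fn, tn, tp + tn, fp + fn,
            round(tp / n, 2), round(fp / n, 2), round(fn / n, 2),
            round(tn / n, 2), round((tp + tn) / n, 2),
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CONFUSION_COLUMNS))


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(Y, scores, average: str = "micro"):
    """ROC curve and AUC over the flattened (instance, label) pairs.

    Returns ``(auc_value, fpr, tpr)``.  ``average="macro"`` instead
    averages per-label AUCs over labels having both classes present.
    """
    Y = _as_binary(Y)
    S = np.asarray(scores, dtype=float)
    _check_shapes(Y, S)
    if average == "micro":
        truth, flat = Y.ravel(), S.ravel()
        if truth.min() == truth.max():
            raise ValueError("AUC undefined: flattened truth has a single class")
        fpr, tpr, _ = _sk_roc_curve(truth, flat)
        return float(_sk_auc(fpr, tpr)), fpr, tpr
    if average == "macro":
        aucs = []
        for j in range(Y.shape[1]):
            if Y[:, j].min() == Y[:, j].max():
                continue
            fpr, tpr, _ = _sk_roc_curve(Y[:, j], S[:, j])
            aucs.append(_sk_auc(fpr, tpr))
        if not aucs:
            raise ValueError("AUC undefined: no label has both classes present")
        return float(np.mean(aucs)), None, None
    raise ValueError(f"average must be 'micro' or 'macro', got {average!r}")


# ---------------------------------------------------------------------------
# Reports


REPORT_COLUMNS = (
    "accuracy_score", "precision", "recall", "f1", "subset_accuracy",
    "hamming_loss", "rank_loss", "macro_precision", "macro_recall",
    "macro_f1", "micro_precision", "micro_recall", "micro_f1",
)


@dataclass
class MetricsReport:
    """The thirteen-column multi-label report plus AUC and extras."""

    accuracy_score: float
    precision: float
    recall: float
    f1: float
    subset_accuracy: float
    hamming_loss: float
    rank_loss: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    auc: float = float("nan")
    macro_f1_per_label: float = float("nan")
    rank_loss_excluded: int = 0

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}

    def row(self) -> list[float]:
        return [getattr(self, c) for c in REPORT_COLUMNS]


def evaluate_predictions(Y, predictions: PredictionSet) -> MetricsReport:
    """Full report for one model's predictions against the truth."""
    ex = example_metrics(Y, predictions.predicted)
    lb = label_metrics(Y, predictions.predicted)
    rl, excluded = rank_loss(Y, predictions.scores, return_excluded=True)
    try:
        auc_value, _, _ = roc_auc(Y, predictions.scores)
    except ValueError:
        auc_value = float("nan")
    return MetricsReport(
        **ex,
        rank_loss=rl,
        rank_loss_excluded=excluded,
        auc=auc_value,
        **lb,
    )


def metrics_table(reports: Mapping[str, MetricsReport], digits: int = 3) -> pd.DataFrame:
    """Reports stacked into the standard thirteen-column layout."""
    frame = pd.DataFrame(
        {name: rep.row() for name, rep in reports.items()},
        index=list(REPORT_COLUMNS),
    ).T
    return frame.round(digits) if digits is not None else frame


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class FoldAssignment:
    """Mutually exclusive, jointly exhaustive folds with sizes within 1."""

    k: int
    fold_of: np.ndarray

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        return np.flatnonzero(self.fold_of != fold), np.flatnonzero(self.fold_of == fold)


def kfold_split(n: int, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle followed by round-robin fold assignment."""
    if n < k:
        raise ValueError(f"cannot split {n} proteins into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % k
    return FoldAssignment(k, fold_of)


#: The eight model variants reported by the CV harness, in table order.
ALL_VARIANTS = (
    "pseaac",
    "pssm",
    "go_binary",
    "go_ppv",
    "pseaac_pssm_go",
    "pssm_go",
    "consensus_pseaac_pssm_go",
    "consensus_pssm_go",
)

#: Feature views each non-consensus variant is trained on (GO fusion and
#: the consensus GO member use the PPV representation).
_VARIANT_VIEWS: dict[str, tuple[str, ...]] = {
    "pseaac": ("pseaac",),
    "pssm": ("pssm",),
    "go_binary": ("go_binary",),
    "go_ppv": ("go_ppv",),
    "pseaac_pssm_go": ("pseaac", "pssm", "go_ppv"),
    "pssm_go": ("pssm", "go_ppv"),
}

_CONSENSUS_MEMBERS: dict[str, tuple[str, ...]] = {
    "consensus_pssm_go": ("pssm", "go_ppv"),
    "consensus_pseaac_pssm_go": ("pseaac", "pssm", "go_ppv"),
}


@dataclass
class CVResult:
    """Pooled held-out predictions, reports and confusion tables."""

    reports: dict[str, MetricsReport]
    confusions: dict[str, pd.DataFrame]
    predictions: dict[str, PredictionSet]
    folds: FoldAssignment
    seed: int

    def table(self, digits: int = 3) -> pd.DataFrame:
        return metrics_table(self.reports, digits)


def cv_run(
    Y: LabelMatrix,
    pseaac: FeatureMatrix | None = None,
    pssm: FeatureMatrix | None = None,
    go_annotations: GOAnnotationSet | None = None,
    variants: Sequence[str] = ALL_VARIANTS,
    k: int = 5,
    seed: int = 0,
    base: str = "rf",
    n_estimators: int = 500,
    go_vocabulary_scope: str = "fold",
) -> CVResult:
    """k-fold cross-validation of the requested model variants.

    Per fold the GO vocabulary is rebuilt from training proteins only
    (``go_vocabulary_scope="global"`` instead builds it once from the
    whole dataset), every view model is fitted on the training part, the
    held-out part is predicted, and consensus variants OR the member
    decisions of that same fold.  Held-out predictions are pooled over
    folds, so every protein is evaluated exactly once.
    """
    unknown = set(variants) - set(ALL_VARIANTS)
    if unknown:
        raise ValueError(f"unknown variants {sorted(unknown)}")
    needed_views: set[str] = set()
    for v in variants:
        needed_views.update(_VARIANT_VIEWS.get(v, ()))
        for member in _CONSENSUS_MEMBERS.get(v, ()):
            needed_views.add(member)
    for view, mat in (("pseaac", pseaac), ("pssm", pssm)):
        if view in needed_views:
            if mat is None:
                raise ValueError(f"variants {list(variants)} require the {view} view")
            if mat.ids != Y.ids:
                raise ValueError(f"{view} view is not row-aligned with the labels")
    if ({"go_binary", "go_ppv"} & needed_views) and go_annotations is None:
        raise ValueError("GO-based variants require go_annotations")
    Y.require_localized()

    folds = kfold_split(Y.n, k=k, seed=seed)
    n, q = Y.n, Y.universe.q
    pooled_pred = {v: np.zeros((n, q), dtype=np.int8) for v in variants}
    pooled_score = {v: np.zeros((n, q)) for v in variants}

    global_vocab = None
    if go_vocabulary_scope == "global" and go_annotations is not None:
        global_vocab = build_go_vocabulary(go_annotations, Y.ids)
    elif go_vocabulary_scope not in ("fold", "global"):
        raise ValueError("go_vocabulary_scope must be 'fold' or 'global'")

    all_subsets = {tuple(map(int, y)) for y in Y.Y}
    for fold in range(k):
        tr, te = folds.train_test(fold)
        Y_tr = Y.subset(tr)
        fold_subsets = {tuple(map(int, y)) for y in Y_tr.Y}
        if fold_subsets != all_subsets:
            logger.info(
                "fold %d: %d label subset(s) absent from the training part",
                fold, len(all_subsets - fold_subsets),
            )

        fold_views: dict[str, tuple[FeatureMatrix, FeatureMatrix]] = {}
        if "pseaac" in needed_views:
            fold_views["pseaac"] = (pseaac.subset(tr), pseaac.subset(te))
        if "pssm" in needed_views:
            fold_views["pssm"] = (pssm.subset(tr), pssm.subset(te))
        if {"go_binary", "go_ppv"} & needed_views:
            vocab = global_vocab or build_go_vocabulary(
                go_annotations, [Y.ids[i] for i in tr]
            )
            for mode in ("binary", "ppv"):
                view = f"go_{mode}"
                if view in needed_views:
                    fold_views[view] = (
                        go_encode(go_annotations, [Y.ids[i] for i in tr], vocab, mode),
                        go_encode(go_annotations, [Y.ids[i] for i in te], vocab, mode),
                    )

        member_predictions: dict[str, PredictionSet] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singleton-class notes are expected in CV
            for view in sorted(needed_views):
                X_tr, X_te = fold_views[view]
                model = lp_fit(X_tr, Y_tr, base=base, seed=seed, n_estimators=n_estimators)
                member_predictions[view] = lp_predict(model, X_te)
            for variant in variants:
                if variant in _CONSENSUS_MEMBERS:
                    continue
                views = _VARIANT_VIEWS[variant]
                if len(views) == 1:
                    pred = member_predictions[views[0]]
                else:
                    fused_tr = feature_fusion([fold_views[v][0] for v in views], variant)
                    fused_te = feature_fusion([fold_views[v][1] for v in views], variant)
                    model = lp_fit(fused_tr, Y_tr, base=base, seed=seed,
                                   n_estimators=n_estimators)
                    pred = lp_predict(model, fused_te)
                pooled_pred[variant][te] = pred.predicted
                pooled_score[variant][te] = pred.scores
        for variant in variants:
            if variant in _CONSENSUS_MEMBERS:
                cons = consensus_or(
                    [member_predictions[m] for m in _CONSENSUS_MEMBERS[variant]],
                    model_id=variant,
                )
                pooled_pred[variant][te] = cons.predicted
                pooled_score[variant][te] = cons.scores

    predictions = {
        v: PredictionSet(list(Y.ids), pooled_pred[v], pooled_score[v], Y.universe, v)
        for v in variants
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reports = {v: evaluate_predictions(Y, p) for v, p in predictions.items()}
    confusions = {
        v: location_confusion(Y, p.predicted, Y.universe) for v, p in predictions.items()
    }
    return CVResult(reports, confusions, predictions, folds, seed)
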