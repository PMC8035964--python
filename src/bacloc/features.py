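"""Fixed-length feature encoders for the three views.

* **PseAAC** — Chou's Type-I pseudo amino acid composition: the 20
  residue frequencies plus lambda sequence-order correlation factors built
  from normalized hydrophobicity, hydrophilicity and side-chain mass,
  combined with weight ``w`` and normalized to sum to one.
* **PSSM-ACC** — auto/cross covariance transform of an L x 20 profile
  into a length ``400 * lg`` vector: for each column the lagged
  autocovariance (AC), and for each ordered column pair the lagged
  cross-covariance (CC), each divided by ``L - lag`` and centred on the
  column's own mean.
* **GO** — membership of a training-derived vocabulary (union of the
  MF/BP/CC terms seen on training proteins), either 0/1 or carrying the
  predictor's PPV confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datatypes import (
    STANDARD_AA,
    FeatureMatrix,
    GOAnnotationSet,
    ProteinRecord,
    PSSMProfile,
)

# ---------------------------------------------------------------------------
# PSSM auto-cross covariance


def _aa_index(i: int | str) -> int:
    if isinstance(i, str):
        idx = STANDARD_AA.find(i)
        if idx < 0:
            raise ValueError(f"unknown amino acid {i!r}")
        return idx
    if not 0 <= i < 20:
        raise ValueError(f"amino-acid index {i} out of range 0..19")
    return int(i)


def column_mean(profile: PSSMProfile, i: int | str) -> float:
    """Mean score of amino-acid column ``i`` over all L positions."""
    return float(profile.scores[:, _aa_index(i)].mean())


def auto_covariance(profile: PSSMProfile, i: int | str, lag: int) -> float:
    """Lagged covariance of one column with itself.

    ``AC(i, lag) = 1/(L-lag) * sum_j (p[j,i] - mean_i)(p[j+lag,i] - mean_i)``
    """
    idx = _aa_index(i)
    L = profile.length
    if lag < 1 or lag >= L:
        raise ValueError(
            f"profile {profile.id}: sequence shorter than lag+1 (L={L}, lag={lag})"
        )
    col = profile.scores[:, idx]
    dev = col - col.mean()
    return float(np.dot(dev[: L - lag], dev[lag:]) / (L - lag))


def cross_covariance(profile: PSSMProfile, i: int | str, j: int | str, lag: int) -> float:
    """Lagged covariance between two distinct columns.

    ``CC(i, j, lag) = 1/(L-lag) * sum_k (p[k,i] - mean_i)(p[k+lag,j] - mean_j)``
    """
    ii, jj = _aa_index(i), _aa_index(j)
    if ii == jj:
        raise ValueError("i and j must differ; use auto_covariance for i == j")
    L = profile.length
    if lag < 1 or lag >= L:
        raise ValueError(
            f"profile {profile.id}: sequence shorter than lag+1 (L={L}, lag={lag})"
        )
    a = profile.scores[:, ii] - profile.scores[:, ii].mean()
    b = profile.scores[:, jj] - profile.scores[:, jj].mean()
    return float(np.dot(a[: L - lag], b[lag:]) / (L - lag))


def acc_feature_names(lg: int) -> tuple[str, ...]:
    """Canonical feature order: AC by (residue, lag), then CC by (i, j, lag)."""
    names = [f"AC_{aa}_{lag}" for aa in STANDARD_AA for lag in range(1, lg + 1)]
    names += [
        f"CC_{a}_{b}_{lag}"
        for a in STANDARD_AA
        for b in STANDARD_AA
        if a != b
        for lag in range(1, lg + 1)
    ]
    return tuple(names)


def acc_transform(profile: PSSMProfile, lg: int = 1) -> np.ndarray:
    """ACC vector of length ``400 * lg`` (AC block then CC block).

    The default ``lg = 1`` keeps the feature count at 400 per protein.
    """
    L = profile.length
    if lg < 1:
        raise ValueError("lg must be >= 1")
    if lg >= L:
        raise ValueError(
            f"profile {profile.id}: sequence shorter than lag+1 (L={L}, lg={lg})"
        )
    dev = profile.scores - profile.scores.mean(axis=0, keepdims=True)
    # cov[lag][i, j] = sum_k dev[k, i] * dev[k+lag, j] / (L - lag)
    cov = [dev[: L - lag].T @ dev[lag:] / (L - lag) for lag in range(1, lg + 1)]
    cov = np.stack(cov, axis=-1)  # 20 x 20 x lg
    ac = cov[np.arange(20), np.arange(20), :].reshape(-1)  # (aa, lag)
    off = ~np.eye(20, dtype=bool)
    cc = cov[off].reshape(-1)  # ordered pairs (i, j), i != j, then lag
    return np.concatenate([ac, cc])


def acc_matrix(
    profiles: Sequence[PSSMProfile], lg: int = 1, view: str = "pssm_acc"
) -> FeatureMatrix:
    X = np.vstack([acc_transform(p, lg) for p in profiles])
    return FeatureMatrix([p.id for p in profiles], view, X, acc_feature_names(lg))


# ---------------------------------------------------------------------------
# Type-I pseudo amino acid composition

#: Hydrophobicity, hydrophilicity and side-chain mass of the 20 residues,
#: in the canonical alphabet order.  The values are the ones used by the
#: classic Type-I PseAAC tools.
PSEAAC_PROPERTIES: dict[str, dict[str, float]] = {
    "hydrophobicity": dict(
        zip(
            STANDARD_AA,
            [0.62, -2.53, -0.78, -0.90, 0.29, -0.85, -0.74, 0.48, -0.40, 1.38,
             1.06, -1.50, 0.64, 1.19, 0.12, -0.18, -0.05, 0.81, 0.26, 1.08],
        )
    ),
    "hydrophilicity": dict(
        zip(
            STANDARD_AA,
            [-0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
             -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5],
        )
    ),
    "side_chain_mass": dict(
        zip(
            STANDARD_AA,
            [15.0, 101.0, 58.0, 59.0, 47.0, 72.0, 73.0, 1.0, 82.0, 57.0,
             57.0, 73.0, 75.0, 91.0, 42.0, 31.0, 45.0, 130.0, 107.0, 43.0],
        )
    ),
}

DEFAULT_PSEAAC_PROPERTY_SET = ("hydrophobicity", "hydrophilicity", "side_chain_mass")


def _normalized_properties(property_set: Sequence[str]) -> np.ndarray:
    """Each property standardized to zero mean / unit SD over the 20 residues."""
    rows = []
    for name in property_set:
        try:
            table = PSEAAC_PROPERTIES[name]
        except KeyError:
            raise ValueError(f"unknown physicochemical property {name!r}") from None
        vals = np.array([table[aa] for aa in STANDARD_AA])
        rows.append((vals - vals.mean()) / vals.std())
    return np.vstack(rows)  # n_props x 20


def pseaac_encode(
    record: ProteinRecord,
    lam: int = 30,
    weight: float = 0.05,
    property_set: Sequence[str] = DEFAULT_PSEAAC_PROPERTY_SET,
) -> np.ndarray:
    """Type-I PseAAC vector of length ``20 + lam`` (components sum to 1).

    With ``lam = 0`` this degenerates to the plain amino-acid composition.
    """
    seq = record.sequence
    L = len(seq)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if L <= lam:
        raise ValueError(
            f"protein {record.id}: sequence length {L} must exceed lambda {lam}"
        )
    if weight <= 0:
        raise ValueError("weight w must be positive")
    props = _normalized_properties(property_set)
    try:
        idx = np.array([STANDARD_AA.index(aa) for aa in seq])
    except ValueError:
        bad = sorted(set(seq) - set(STANDARD_AA))
        raise ValueError(f"protein {record.id}: non-standard residues {bad}") from None

    freqs = np.bincount(idx, minlength=20) / L
    h = props[:, idx]  # n_props x L, property profile along the sequence
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        # mean over positions of the mean squared property difference
        diff = h[:, : L - k] - h[:, k:]
        thetas[k - 1] = float((diff**2).mean(axis=0).mean())
    denom = 1.0 + weight * thetas.sum()
    return np.concatenate([freqs / denom, weight * thetas / denom])


def pseaac_matrix(
    records: Sequence[ProteinRecord],
    lam: int = 30,
    weight: float = 0.05,
    property_set: Sequence[str] = DEFAULT_PSEAAC_PROPERTY_SET,
) -> FeatureMatrix:
    """Batch PseAAC encoding; lambda is capped at ``min(lam, min_L - 1)``
    so the view stays rectangular when short sequences are present."""
    if not records:
        raise ValueError("no records to encode")
    eff_lam = min(lam, min(len(r.sequence) for r in records) - 1)
    X = np.vstack([pseaac_encode(r, eff_lam, weight, property_set) for r in records])
    names = tuple(f"AAC_{aa}" for aa in STANDARD_AA) + tuple(
        f"theta_{k}" for k in range(1, eff_lam + 1)
    )
    return FeatureMatrix([r.id for r in records], "pseaac", X, names)


# ---------------------------------------------------------------------------
# GO-term vectorization


@dataclass(frozen=True)
class GOVocabulary:
    """Ordered union of the GO terms seen on training proteins."""

    terms: tuple[str, ...]
    ontology_counts: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("GO vocabulary contains duplicates")

    def __len__(self) -> int:
        return len(self.terms)


def build_go_vocabulary(
    annotations: GOAnnotationSet, training_ids: Iterable[str]
) -> GOVocabulary:
    """Sorted, de-duplicated union of MF/BP/CC terms on training proteins.

    Built from training proteins only so that, inside cross-validation,
    terms first seen on held-out proteins cannot leak into the encoding.
    """
    terms: set[str] = set()
    per_ontology: dict[str, set[str]] = {"MF": set(), "BP": set(), "CC": set()}
    for pid in training_ids:
        for ann in annotations.for_protein(pid):
            terms.add(ann.go_id)
            per_ontology[ann.ontology].add(ann.go_id)
    return GOVocabulary(
        tuple(sorted(terms)), {k: len(v) for k, v in per_ontology.items()}
    )


def go_encode(
    annotations: GOAnnotationSet,
    ids: Sequence[str],
    vocabulary: GOVocabulary,
    mode: str = "ppv",
) -> FeatureMatrix:
    """Encode proteins over the vocabulary; unknown terms are ignored.

    ``binary`` mode marks presence/absence; ``ppv`` mode carries the
    predictor's confidence.  Unannotated proteins yield zero vectors.
    """
    if mode not in ("binary", "ppv"):
        raise ValueError(f"mode must be 'binary' or 'ppv', got {mode!r}")
    pos = {term: k for k, term in enumerate(vocabulary.terms)}
    X = np.zeros((len(ids), len(vocabulary)))
    for row, pid in enumerate(ids):
        for ann in annotations.for_protein(pid):
            k = pos.get(ann.go_id)
            if k is not None:
                X[row, k] = 1.0 if mode == "binary" else ann.ppv
    return FeatureMatrix(list(ids), f"go_{mode}", X, vocabulary.terms)
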