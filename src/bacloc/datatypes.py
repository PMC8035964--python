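"""Core in-memory containers shared across the pipeline.

The label space is a fixed, ordered universe of single-letter location
codes (e.g. ``C`` = cytoplasm, ``I`` = inner membrane).  A protein's
localization is a binary vector over that universe; multi-site proteins
simply set several bits.  Feature views (PseAAC, PSSM-ACC, GO) are plain
N x d matrices row-aligned with the label matrix by protein id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: PSI-BLAST PSSM column order; used as the canonical amino-acid alphabet.
STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

STANDARD_AA_SET = frozenset(STANDARD_AA)

GO_ONTOLOGIES = ("MF", "BP", "CC")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a dataset-unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")

    @property
    def is_standard(self) -> bool:
        """True if the sequence uses only the 20 standard residues."""
        return set(self.sequence) <= STANDARD_AA_SET


@dataclass(frozen=True)
class LabelUniverse:
    """Ordered set of subcellular location codes defining the label space."""

    codes: tuple[str, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codes) != len(set(self.codes)):
            raise ValueError(f"duplicate location codes: {self.codes}")
        if len(self.codes) < 2:
            raise ValueError("a label universe needs at least 2 locations")
        if len(self.names) != len(self.codes):
            raise ValueError("codes and names must be parallel")

    @property
    def q(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(
                f"unknown location code {code!r}; universe is {'/'.join(self.codes)}"
            ) from None

    def encode(self, locations: str) -> np.ndarray:
        """Binary vector from a slash-joined code string such as ``"C/I"``."""
        if not locations or locations == "-":
            raise ValueError("empty location field")
        row = np.zeros(self.q, dtype=np.int8)
        for code in locations.split("/"):
            row[self.index(code)] = 1
        return row

    def decode(self, row: Sequence[int]) -> str:
        """Slash-joined codes of the set bits; ``"-"`` for an empty set."""
        codes = [c for c, bit in zip(self.codes, row) if bit]
        return "/".join(codes) if codes else "-"


#: Gram-negative bacteria: cytoplasm, inner/outer membrane, periplasm,
#: extracellular space and (gas-vesicle) vacuole.
GRAM_NEGATIVE = LabelUniverse(
    codes=("C", "I", "O", "P", "S", "V"),
    names=(
        "Cytoplasm",
        "Inner membrane",
        "Outer membrane",
        "Periplasm",
        "Extracellular",
        "Vacuole",
    ),
)

#: Gram-positive bacteria lack the outer membrane and periplasm but add
#: the cell wall compartment.
GRAM_POSITIVE = LabelUniverse(
    codes=("C", "I", "S", "W", "V"),
    names=("Cytoplasm", "Inner membrane", "Extracellular", "Cell wall", "Vacuole"),
)

UNIVERSE_PRESETS: Mapping[str, LabelUniverse] = {
    "gram_negative": GRAM_NEGATIVE,
    "gram_positive": GRAM_POSITIVE,
}


@dataclass
class LabelMatrix:
    """Binary N x Q multi-label assignment, row-aligned with ``ids``."""

    ids: list[str]
    Y: np.ndarray
    universe: LabelUniverse

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int8)
        if self.Y.ndim != 2 or self.Y.shape != (len(self.ids), self.universe.q):
            raise ValueError(
                f"label matrix shape {self.Y.shape} does not match "
                f"{len(self.ids)} ids x {self.universe.q} locations"
            )
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("label matrix entries must be 0/1")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate protein ids in label matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    def require_localized(self) -> "LabelMatrix":
        """Assert every row has at least one set bit (benchmark truth)."""
        empty = np.flatnonzero(self.Y.sum(axis=1) == 0)
        if empty.size:
            raise ValueError(
                f"proteins without any location: {[self.ids[i] for i in empty[:5]]}"
            )
        return self

    def subset(self, indices: Sequence[int]) -> "LabelMatrix":
        idx = np.asarray(indices)
        return LabelMatrix([self.ids[i] for i in idx], self.Y[idx], self.universe)


@dataclass(frozen=True)
class GOAnnotation:
    """One predicted GO term with its predictor confidence (PPV)."""

    go_id: str
    ontology: str
    ppv: float

    def __post_init__(self) -> None:
        if self.ontology not in GO_ONTOLOGIES:
            raise ValueError(
                f"ontology must be one of {GO_ONTOLOGIES}, got {self.ontology!r}"
            )
        if not (0.0 <= self.ppv <= 1.0):
            raise ValueError(f"PPV {self.ppv} outside [0, 1] for {self.go_id}")


class GOAnnotationSet:
    """Per-protein GO term lists; a protein may legally have none.

    Duplicate (protein, go_id) pairs are collapsed keeping the maximum
    PPV, mirroring the de-duplication applied when merging redundant
    homology-transferred annotations.
    """

    def __init__(self) -> None:
        self._by_protein: dict[str, dict[str, GOAnnotation]] = {}

    def add(self, protein_id: str, annotation: GOAnnotation) -> None:
        terms = self._by_protein.setdefault(protein_id, {})
        prev = terms.get(annotation.go_id)
        if prev is None or annotation.ppv > prev.ppv:
            terms[annotation.go_id] = annotation

    def for_protein(self, protein_id: str) -> list[GOAnnotation]:
        return list(self._by_protein.get(protein_id, {}).values())

    @property
    def protein_ids(self) -> list[str]:
        return list(self._by_protein)

    def __len__(self) -> int:
        return len(self._by_protein)


@dataclass
class PSSMProfile:
    """L x 20 position-specific scoring matrix for one protein.

    Rows follow the sequence; columns follow ``alphabet`` (by default the
    PSI-BLAST order A R N D C Q E G H I L K M F P S T W Y V).
    """

    id: str
    scores: np.ndarray
    alphabet: str = STANDARD_AA

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.id}: expected L x 20 matrix, got {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM for {self.id}: empty body")
        if len(self.alphabet) != 20:
            raise ValueError("PSSM alphabet must list 20 amino acids")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class FeatureMatrix:
    """One fixed-width feature view, row-aligned with the label matrix."""

    ids: list[str]
    view: str
    X: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape != (len(self.ids), len(self.columns)):
            raise ValueError(
                f"view {self.view}: matrix shape {self.X.shape} does not match "
                f"{len(self.ids)} ids x {len(self.columns)} columns"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return len(self.columns)

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix([self.ids[i] for i in idx], self.view, self.X[idx], self.columns)


@dataclass
class PredictionSet:
    """Hard multi-label predictions plus per-label marginal scores."""

    ids: list[str]
    predicted: np.ndarray
    scores: np.ndarray
    universe: LabelUniverse
    model_id: str

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=np.int8)
        self.scores = np.asarray(self.scores, dtype=float)
        shape = (len(self.ids), self.universe.q)
        if self.predicted.shape != shape or self.scores.shape != shape:
            raise ValueError(
                f"prediction set {self.model_id}: shapes {self.predicted.shape}/"
                f"{self.scores.shape} do not match {shape}"
            )
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("marginal scores must lie in [0, 1]")
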