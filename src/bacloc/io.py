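"""Readers and writers for the pipeline's external artifacts.

Formats handled:

* FASTA protein sequences (via Biopython), with optional filtering of
  sequences containing non-standard residues such as ``X``;
* PSI-BLAST ASCII PSSM files (as written by ``psiblast -out_ascii_pssm``):
  header, one row per residue with 20 log-odds columns followed by 20
  weighted-percentage columns;
* labels TSV: ``protein_id <TAB> locations`` with slash-joined codes
  ("C/I" for a dual-site protein);
* GO annotation TSV: ``protein_id <TAB> ontology <TAB> go_id <TAB> ppv``;
* predictions TSV (same dialect as labels; an empty prediction is "-").

The two TSV dialects are tab-separated with a single header line;
lines starting with ``#`` are comments.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .datatypes import (
    STANDARD_AA,
    STANDARD_AA_SET,
    GOAnnotation,
    GOAnnotationSet,
    LabelMatrix,
    LabelUniverse,
    PredictionSet,
    ProteinRecord,
    PSSMProfile,
)


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path, filter_nonstandard: bool = True
) -> tuple[list[ProteinRecord], list[str]]:
    """Read protein records; return ``(records, dropped_ids)``.

    With ``filter_nonstandard`` on, sequences containing any character
    outside the 20 standard residues (including the ambiguity symbol X)
    are dropped and their ids returned in ``dropped_ids``.  Record ids
    are the first whitespace-delimited token of each header.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: sequence data before any FASTA header"
                )
            break
        handle.seek(0)
        parsed = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]

    seen: set[str] = set()
    records: list[ProteinRecord] = []
    dropped: list[str] = []
    for rec_id, seq in parsed:
        if rec_id in seen:
            raise ParseError(f"{path}: duplicate protein id {rec_id!r}")
        seen.add(rec_id)
        if filter_nonstandard and not set(seq) <= STANDARD_AA_SET:
            dropped.append(rec_id)
            continue
        records.append(ProteinRecord(rec_id, seq))
    return records, dropped


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(
    path: str | Path, block: str = "log_odds", protein_id: str | None = None
) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM into an L x 20 profile.

    ``block`` selects which 20-column block feeds the profile:
    ``"log_odds"`` (the first block, the conventional profile) or
    ``"percent"`` (the second, weighted observed percentages).  Columns
    are reordered to the canonical alphabet declared in the file header.
    """
    if block not in ("log_odds", "percent"):
        raise ValueError(f"block must be 'log_odds' or 'percent', got {block!r}")
    path = Path(path)
    alphabet: list[str] = []
    rows: list[list[float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            if not alphabet:
                # Header line: 20 (or 40) single-letter amino-acid tokens.
                if len(fields) >= 20 and all(
                    len(f) == 1 and f in STANDARD_AA_SET for f in fields[:20]
                ):
                    alphabet = fields[:20]
                continue
            if not fields[0].lstrip("-").isdigit():
                continue  # trailing K/lambda statistics lines
            numeric = fields[2:]
            if len(numeric) < 40:
                raise ParseError(
                    f"{path}: row {len(rows) + 1} (line {lineno}): expected 40 "
                    f"numeric fields, found {len(numeric)}"
                )
            try:
                values = [float(x) for x in numeric[:40]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: row {len(rows) + 1} (line {lineno}): {exc}"
                ) from None
            rows.append(values)
    if not alphabet:
        raise ParseError(f"{path}: no amino-acid header line found")
    if not rows:
        raise ParseError(f"{path}: empty PSSM body")

    matrix = np.asarray(rows, dtype=float)
    matrix = matrix[:, :20] if block == "log_odds" else matrix[:, 20:]
    # Reorder columns from the header's alphabet to the canonical order.
    order = [alphabet.index(aa) for aa in STANDARD_AA]
    matrix = matrix[:, order]
    return PSSMProfile(protein_id or path.stem, matrix)


def write_pssm(
    profile: PSSMProfile,
    path: str | Path,
    percent: np.ndarray | None = None,
    sequence: str | None = None,
) -> None:
    """Write a profile in PSI-BLAST ASCII layout (both 20-column blocks).

    If ``percent`` is not given, a percentage block is derived from the
    scores (softmax per position, rounded to integers) so that files are
    format-realistic and the two blocks differ.
    """
    scores = profile.scores
    if percent is None:
        z = np.exp(scores / 2.0 - (scores / 2.0).max(axis=1, keepdims=True))
        percent = np.round(100.0 * z / z.sum(axis=1, keepdims=True)).astype(int)
    header = (
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts"
    )
    aa_cols = "  ".join(STANDARD_AA)
    with open(path, "w") as out:
        out.write("\n" + header + "\n")
        out.write("            " + aa_cols + "   " + aa_cols + "\n")
        for j in range(profile.length):
            letter = sequence[j] if sequence else "A"
            lo = " ".join(f"{int(round(v)):3d}" for v in scores[j])
            pc = " ".join(f"{int(v):3d}" for v in percent[j])
            out.write(f"{j + 1:5d} {letter}  {lo}  {pc}  0.00 0.00\n")
        out.write("\n")


# ---------------------------------------------------------------------------
# Labels / predictions TSV


def _read_tsv_rows(path: Path, expected_header: Sequence[str]) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header_seen = False
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if not header_seen:
                if [c.strip() for c in row] != list(expected_header):
                    raise ParseError(
                        f"{path}: line {lineno}: expected header "
                        f"{list(expected_header)}, got {row}"
                    )
                header_seen = True
                continue
            rows.append([c.strip() for c in row])
    if not header_seen:
        raise ParseError(f"{path}: missing header line")
    return rows


def read_labels(path: str | Path, universe: LabelUniverse) -> LabelMatrix:
    """Read a labels TSV into a binary label matrix (every row non-empty)."""
    matrix = read_predictions(path, universe)
    return LabelMatrix(matrix.ids, matrix.Y, universe).require_localized()


def read_predictions(path: str | Path, universe: LabelUniverse) -> LabelMatrix:
    """Like :func:`read_labels` but permits empty ("-") rows."""
    path = Path(path)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for fields in _read_tsv_rows(path, ("protein_id", "locations")):
        if len(fields) != 2:
            raise ParseError(f"{path}: malformed row {fields}")
        pid, locs = fields
        if not locs:
            raise ParseError(f"{path}: empty location field for {pid}")
        ids.append(pid)
        if locs == "-":
            rows.append(np.zeros(universe.q, dtype=np.int8))
        else:
            try:
                rows.append(universe.encode(locs))
            except KeyError as exc:
                raise ParseError(f"{path}: protein {pid}: {exc.args[0]}") from None
    Y = np.vstack(rows) if rows else np.zeros((0, universe.q), dtype=np.int8)
    return LabelMatrix(ids, Y, universe)


def write_predictions(
    ids: Sequence[str],
    predicted: np.ndarray | LabelMatrix,
    universe: LabelUniverse,
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write ``id <TAB> slash-joined-codes`` rows; empty rows become "-"."""
    Y = predicted.Y if isinstance(predicted, LabelMatrix) else np.asarray(predicted)
    if Y.shape != (len(ids), universe.q):
        raise ValueError(
            f"prediction matrix shape {Y.shape} does not match "
            f"{len(ids)} ids x {universe.q} locations"
        )
    with open(path, "w") as out:
        for comment in header_comments:
            out.write(f"# {comment}\n")
        out.write("protein_id\tlocations\n")
        for pid, row in zip(ids, Y):
            out.write(f"{pid}\t{universe.decode(row)}\n")


# ---------------------------------------------------------------------------
# GO annotations TSV


def read_go_annotations(path: str | Path) -> GOAnnotationSet:
    """Read predicted GO terms grouped by protein.

    Duplicate (protein, go_id) rows keep the maximum PPV; a PPV outside
    [0, 1] or an unknown sub-ontology is rejected outright.
    """
    path = Path(path)
    annotations = GOAnnotationSet()
    for fields in _read_tsv_rows(path, ("protein_id", "ontology", "go_id", "ppv")):
        if len(fields) != 4:
            raise ParseError(f"{path}: malformed row {fields}")
        pid, ontology, go_id, ppv_str = fields
        try:
            ppv = float(ppv_str)
        except ValueError:
            raise ParseError(f"{path}: protein {pid}: non-numeric PPV {ppv_str!r}") from None
        try:
            annotations.add(pid, GOAnnotation(go_id, ontology, ppv))
        except ValueError as exc:
            raise ParseError(f"{path}: protein {pid}: {exc}") from None
    return annotations


def write_go_annotations(annotations: GOAnnotationSet, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("protein_id\tontology\tgo_id\tppv\n")
        for pid in annotations.protein_ids:
            for ann in sorted(annotations.for_protein(pid), key=lambda a: a.go_id):
                out.write(f"{pid}\t{ann.ontology}\t{ann.go_id}\t{ann.ppv:.3f}\n")
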