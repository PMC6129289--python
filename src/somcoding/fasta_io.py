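"""Reading and writing of transcript sequences, labels and prediction tables.

Transcripts are nucleotide sequences normalized to the DNA alphabet
``{A, C, G, T, N}``: RNA uracil is mapped to thymine at read time so that
all downstream feature code works on a single alphabet (start codon ATG,
stop codons TAA/TAG/TGA).  Ambiguous IUPAC codes other than N are rejected
with a record-level error rather than silently dropped or guessed at.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

CODING = "coding"
NONCODING = "noncoding"
REJECTED = "rejected"
CLASSES = (CODING, NONCODING)

_VALID = set("ACGTN")

# upper-case, U->T; anything else must already be in {A,C,G,T,N}
_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")


class FastaError(ValueError):
    """Raised for malformed FASTA input (missing, empty, duplicate ids,
    characters outside the accepted nucleotide alphabet)."""


@dataclass(frozen=True)
class Transcript:
    """One identified nucleotide sequence with an optional class label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("transcript id must be non-empty")
        if len(self.sequence) < 1:
            raise FastaError(f"transcript {self.id!r}: empty sequence")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(
                f"transcript {self.id!r}: label must be one of {CLASSES}, "
                f"got {self.label!r}"
            )


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Upper-case a raw nucleotide string and map U to T.

    Characters outside ``{A,C,G,T,U,N}`` (either case) raise
    :class:`FastaError` naming the record and the 0-based offending position.
    Normalization is idempotent.
    """
    seq = raw.translate(_NORMALIZE)
    for pos, ch in enumerate(seq):
        if ch not in _VALID:
            raise FastaError(
                f"record {record_id!r}: invalid character {raw[pos]!r} "
                f"at position {pos}"
            )
    return seq


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, label: Optional[str] = None) -> list[Transcript]:
    """Read a (possibly multi-line, mixed-case, RNA-alphabet) FASTA file.

    Parameters
    ----------
    path:
        FASTA file; ``.gz`` suffixed files are transparently decompressed.
    label:
        Optional class (``"coding"`` or ``"noncoding"``) attached to every
        record, for building labeled training sets from per-class files.

    Returns
    -------
    list of :class:`Transcript` in file order, sequences normalized.

    Raises
    ------
    FastaError
        Missing file, empty file, duplicate ids, or invalid characters.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    if label is not None and label not in CLASSES:
        raise ValueError(f"label must be one of {CLASSES}, got {label!r}")

    transcripts: list[Transcript] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            rid = record.id  # first whitespace-delimited token of the header
            if rid in seen:
                raise FastaError(f"duplicate id {rid!r} in {path}")
            seen.add(rid)
            seq = normalize_sequence(str(record.seq), rid)
            if not seq:
                raise FastaError(f"record {rid!r}: empty sequence")
            transcripts.append(Transcript(id=rid, sequence=seq, label=label))
    if not transcripts:
        raise FastaError(f"no FASTA records in {path}")
    return transcripts


def write_fasta(transcripts: list[Transcript], path, width: int = 70) -> None:
    """Write transcripts as FASTA with fixed line wrapping (deterministic)."""
    path = Path(path)
    with open(path, "wt") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")


def labels_to_matrix(labels) -> np.ndarray:
    """One-hot encode class labels: coding -> [1, 0], noncoding -> [0, 1]."""
    out = np.zeros((len(labels), 2), dtype=float)
    for i, lab in enumerate(labels):
        if lab == CODING:
            out[i, 0] = 1.0
        elif lab == NONCODING:
            out[i, 1] = 1.0
        else:
            raise ValueError(f"unknown label {lab!r} at row {i}")
    return out


def write_labels(transcripts: list[Transcript], path) -> None:
    """Write a two-column id/label TSV for a labeled transcript set."""
    rows = []
    for t in transcripts:
        if t.label is None:
            raise ValueError(f"transcript {t.id!r} has no label")
        rows.append((t.id, t.label))
    pd.DataFrame(rows, columns=["id", "label"]).to_csv(path, sep="\t", index=False)


def read_labels(path) -> dict[str, str]:
    """Read an id/label TSV into a dict; labels validated against CLASSES."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["id", "label"]:
        raise ValueError(f"label file {path} must have columns id, label")
    labels = dict(zip(df["id"], df["label"]))
    bad = sorted(set(labels.values()) - set(CLASSES))
    if bad:
        raise ValueError(f"unknown labels in {path}: {bad}")
    return labels


PREDICTION_COLUMNS = [
    "id",
    "output_coding",
    "output_noncoding",
    "predicted_class",
    "bmu_row",
    "bmu_col",
]


def write_predictions(records, path) -> None:
    """Write per-transcript prediction records as a TSV table.

    Columns: id, output_coding, output_noncoding, predicted_class
    (coding | noncoding | rejected), bmu_row, bmu_col.  Row order equals
    input order; float formatting is fixed so identical inputs give
    byte-identical files.
    """
    if not records:
        raise ValueError("no prediction records to write")
    with open(path, "wt") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.id}\t{r.o_coding:.10g}\t{r.o_noncoding:.10g}\t"
                f"{r.decision}\t{r.bmu[0]}\t{r.bmu[1]}\n"
            )


def read_predictions(path) -> pd.DataFrame:
    """Read a prediction TSV back into a DataFrame (round-trips writes)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PREDICTION_COLUMNS:
        raise ValueError(f"{path} is not a prediction table")
    return df
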