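"""Alignment-free feature vector for coding-potential classification.

Each transcript is summarized by a fixed-order numeric vector of length
1365 built from three families:

* **sequence bias** — per-nucleotide frequencies, GC frequency and the
  codon position bias ``X_pos = min(X1, X2, X3) / max(X1, X2, X3)`` where
  ``Xj`` counts base X at positions ``j-1, j+2, j+5, ...`` of the
  transcript;
* **ORF statistics** — coverage and log10-length of the longest open
  reading frame, mean/SD of ORF lengths, coverages and of start/end codon
  relative positions, the frame bias
  ``1 - min_frame(#ORF) / max_frame(#ORF)`` and the ORF frequency
  ``#ORF / #start codons``;
* **k-mer frequencies** for k = 3, 4, 5 in lexicographic order over
  ``{A, C, G, T}``.

ORFs are enumerated on the forward strand only: every ATG occurrence is
paired with its nearest in-frame stop codon (TAA/TAG/TGA) downstream;
nested starts each yield their own ORF sharing that stop.  Windows
containing N never match a start or stop pattern.  Under this
nearest-stop definition the ORF frequency lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

import numpy as np

from .fasta_io import Transcript

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
KMER_SIZES = (3, 4, 5)

#: total feature-vector length: 4 + 1 + 4 + 12 + 64 + 256 + 1024
N_FEATURES = 21 + sum(4**k for k in KMER_SIZES)


def _kmer_names(k: int) -> list[str]:
    return ["kmer%d_%s" % (k, "".join(p)) for p in product(BASES, repeat=k)]


FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"freq_{b}" for b in BASES]
    + ["freq_GC"]
    + [f"codon_pos_bias_{b}" for b in BASES]
    + [
        "longest_orf_coverage",
        "longest_orf_log10_length",
        "orf_length_mean",
        "orf_length_sd",
        "orf_coverage_mean",
        "orf_coverage_sd",
        "orf_start_mean",
        "orf_start_sd",
        "orf_end_mean",
        "orf_end_sd",
        "frame_bias",
        "orf_frequency",
    ]
    + _kmer_names(3)
    + _kmer_names(4)
    + _kmer_names(5)
)

assert len(FEATURE_NAMES) == N_FEATURES

#: bump when the layout above changes; stored in model archives so that a
#: model trained under one layout refuses features from another.
FEATURE_LAYOUT_VERSION = "somcoding-features-1"

FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}


@dataclass(frozen=True)
class Orf:
    """One open reading frame: [start, end) spans ATG through stop codon."""

    frame: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OrfSet:
    """All forward-strand ORFs of a transcript plus the raw ATG count."""

    orfs: tuple[Orf, ...]
    n_start_codons: int


def nucleotide_and_gc_frequencies(sequence: str) -> np.ndarray:
    """Frequencies of A, C, G, T and the GC frequency.

    Denominators use the number of non-N positions; an all-N sequence
    yields five zeros.
    """
    counts = np.array([sequence.count(b) for b in BASES], dtype=float)
    l_eff = counts.sum()
    if l_eff == 0:
        return np.zeros(5)
    freqs = counts / l_eff
    return np.append(freqs, freqs[2] + freqs[1])  # GC = f_G + f_C


def codon_position_bias(sequence: str) -> np.ndarray:
    """min/max ratio of per-base counts over the three codon positions.

    For base X, ``X1`` counts X at positions 0, 3, 6, ..., ``X2`` at
    1, 4, 7, ... and ``X3`` at 2, 5, 8, ...; the bias is
    ``min(X1,X2,X3)/max(X1,X2,X3)``, 0 by convention when the base is
    absent.  A value of 1 means the base is positionally uniform; near 0
    means it is restricted to a subset of codon positions.
    """
    counts = np.zeros((4, 3))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for pos, ch in enumerate(sequence):
        i = base_idx.get(ch)
        if i is not None:
            counts[i, pos % 3] += 1
    maxima = counts.max(axis=1)
    minima = counts.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = np.where(maxima > 0, minima / np.maximum(maxima, 1e-300), 0.0)
    return bias


def find_orfs(sequence: str) -> OrfSet:
    """Enumerate all forward-strand ORFs (nearest-stop definition).

    Every ATG is paired with the first downstream in-frame stop codon;
    unclosed starts contribute to ``n_start_codons`` but yield no ORF.
    Codon windows containing N never match.
    """
    n = len(sequence)
    starts = [i for i in range(n - 2) if sequence[i : i + 3] == "ATG"]
    stops_by_frame: list[list[int]] = [[], [], []]
    for i in range(n - 2):
        if sequence[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    orfs = []
    for s in starts:
        frame = s % 3
        # first in-frame stop at position >= s + 3
        stop = next((q for q in stops_by_frame[frame] if q >= s + 3), None)
        if stop is not None:
            orfs.append(Orf(frame=frame, start=s, end=stop + 3))
    return OrfSet(orfs=tuple(orfs), n_start_codons=len(starts))


def orf_statistics(orfset: OrfSet, seq_length: int) -> np.ndarray:
    """Twelve ORF-derived features (see module docstring for the layout).

    All statistics are 0 for a transcript with no ORF; SDs are population
    SDs (defined for a single ORF); start/end positions are divided by the
    transcript length so all statistics are scale-free.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    orfs = orfset.orfs
    if not orfs:
        return np.zeros(12)
    lengths = np.array([o.length for o in orfs], dtype=float)
    coverages = lengths / seq_length
    starts = np.array([o.start for o in orfs], dtype=float) / seq_length
    ends = np.array([o.end for o in orfs], dtype=float) / seq_length
    frame_counts = np.bincount([o.frame for o in orfs], minlength=3)
    frame_bias = 1.0 - frame_counts.min() / frame_counts.max()
    orf_frequency = (
        len(orfs) / orfset.n_start_codons if orfset.n_start_codons else 0.0
    )
    longest = lengths.max()
    return np.array(
        [
            longest / seq_length,
            np.log10(longest),
            lengths.mean(),
            lengths.std(),
            coverages.mean(),
            coverages.std(),
            starts.mean(),
            starts.std(),
            ends.mean(),
            ends.std(),
            frame_bias,
            orf_frequency,
        ]
    )


_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


def _encode(sequence: str) -> np.ndarray:
    """Map a normalized sequence to codes A=0 C=1 G=2 T=3, N=-1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_frequencies(sequence: str, k: int) -> np.ndarray:
    """Frequencies of all 4**k words of length k, lexicographic order.

    Windows containing N are skipped; the denominator is the number of
    counted windows, so a block sums to 1 whenever at least one valid
    window exists, and is all zeros otherwise.
    """
    if k not in KMER_SIZES:
        raise ValueError(f"k must be one of {KMER_SIZES}")
    codes = _encode(sequence)
    n_windows = len(codes) - k + 1
    out = np.zeros(4**k)
    if n_windows <= 0:
        return out
    idx = np.zeros(n_windows, dtype=np.int64)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_windows]
        valid &= c >= 0
        idx = idx * 4 + np.where(c >= 0, c, 0)
    if not valid.any():
        return out
    counts = np.bincount(idx[valid], minlength=4**k).astype(float)
    return counts / counts.sum()


def featurize(transcript: Transcript) -> np.ndarray:
    """Full fixed-order feature vector (length 1365) of one transcript."""
    seq = transcript.sequence
    orfset = find_orfs(seq)
    parts = [
        nucleotide_and_gc_frequencies(seq),
        codon_position_bias(seq),
        orf_statistics(orfset, len(seq)),
    ]
    parts.extend(kmer_frequencies(seq, k) for k in KMER_SIZES)
    vec = np.concatenate(parts)
    assert vec.shape == (N_FEATURES,)
    return vec


def feature_matrix(transcripts: Iterable[Transcript]) -> np.ndarray:
    """Stack feature vectors for a list of transcripts (n x 1365)."""
    return np.vstack([featurize(t) for t in transcripts])


def feature_table(transcripts: list[Transcript]):
    """Feature matrix as a pandas DataFrame with canonical column names."""
    import pandas as pd

    X = feature_matrix(transcripts)
    return pd.DataFrame(X, index=[t.id for t in transcripts], columns=list(FEATURE_NAMES))
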