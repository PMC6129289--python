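"""Synthetic labeled transcript generator.

Produces FASTA-ready datasets with the coding / non-coding contrasts the
classifier relies on, so the whole pipeline (training, prediction,
rejection, visualization) is exercisable without any database download:

* **coding-like** transcripts carry one long open reading frame covering
  a target fraction of the length, built from a codon distribution with a
  positional skew (so the codon position bias is informative), flanked by
  UTR-like uniform sequence;
* **non-coding-like** transcripts are uniform (or first-order Markov)
  random sequence, which leaves stop codons unpruned — many short
  scattered ORFs, a high ORF frequency and a low longest-ORF coverage;
* an optional **ambiguous** regime embeds a mid-coverage (~0.5) unbiased
  ORF in otherwise random sequence, mimicking boundary transcripts that
  sit between the two classes and should attract rejections.

The generator is deterministic under a fixed seed and emits plain
:class:`~somcoding.fasta_io.Transcript` records.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np

from .fasta_io import CODING, NONCODING, Transcript

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in _STOPS]


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give a cleanly separable two-class dataset of 500 + 500
    transcripts with lengths 300-1500 nt, coding ORFs covering about 85%
    of the transcript with a strong positional codon skew, and no
    ambiguous regime.  ``ambiguity_fraction`` > 0 replaces that fraction
    of each class with boundary-profile sequences (ORF coverage ~0.5,
    high ORF frequency) that keep their class label.
    """

    n_coding: int = 500
    n_noncoding: int = 500
    length_range: tuple[int, int] = (300, 1500)
    orf_coverage: float = 0.85
    codon_bias_strength: float = 0.75
    noncoding_model: str = "uniform"  # or "markov"
    ambiguity_fraction: float = 0.0
    ambiguous_coverage: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length range must satisfy 30 <= lo <= hi")
        for name in ("orf_coverage", "codon_bias_strength",
                     "ambiguity_fraction", "ambiguous_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.orf_coverage * lo < 9:
            raise ValueError(
                "orf_coverage too small for the shortest length: the "
                "embedded ORF needs at least 3 codons"
            )
        if self.noncoding_model not in ("uniform", "markov"):
            raise ValueError("noncoding_model must be 'uniform' or 'markov'")


def _biased_codon_probs(strength: float) -> np.ndarray:
    """Codon distribution over the 61 sense codons with positional skew.

    At strength 0 all sense codons are equiprobable; at strength 1 codons
    are drawn from strongly skewed independent per-position base weights
    (position 1 favors G/A, position 2 favors C, position 3 favors G/C),
    giving coding-like sequences a pronounced codon position bias.
    """
    skew = np.array(
        [
            [0.35, 0.10, 0.35, 0.20],  # position 1: A C G T
            [0.15, 0.55, 0.15, 0.15],  # position 2
            [0.10, 0.40, 0.40, 0.10],  # position 3
        ]
    )
    uniform = np.full((3, 4), 0.25)
    pos = uniform + strength * (skew - uniform)
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.array(
        [pos[0, idx[c[0]]] * pos[1, idx[c[1]]] * pos[2, idx[c[2]]] for c in _SENSE_CODONS]
    )
    return probs / probs.sum()


def _random_seq(rng: np.random.Generator, length: int, model: str) -> str:
    if model == "uniform" or length < 2:
        return "".join(rng.choice(_BASES, size=length))
    # simple first-order Markov chain with mild GC persistence
    P = np.array(
        [
            [0.35, 0.20, 0.20, 0.25],
            [0.25, 0.30, 0.25, 0.20],
            [0.20, 0.25, 0.30, 0.25],
            [0.25, 0.20, 0.20, 0.35],
        ]
    )
    states = np.empty(length, dtype=int)
    states[0] = rng.integers(4)
    for i in range(1, length):
        states[i] = rng.choice(4, p=P[states[i - 1]])
    return "".join(_BASES[states])


def _embedded_orf_seq(
    rng: np.random.Generator,
    length: int,
    coverage: float,
    codon_probs: Optional[np.ndarray],
) -> str:
    """Sequence of ``length`` nt with one ATG..stop ORF covering ~coverage.

    The ORF body is drawn from ``codon_probs`` over sense codons (uniform
    sense codons when None), so it contains no in-frame stop and the
    embedded ORF is exactly ATG .. first in-frame stop.
    """
    orf_len = int(round(coverage * length / 3.0)) * 3
    orf_len = max(9, min(orf_len, length // 3 * 3))
    n_body = orf_len // 3 - 2  # codons between ATG and the stop
    if codon_probs is None:
        body_idx = rng.integers(len(_SENSE_CODONS), size=n_body)
    else:
        body_idx = rng.choice(len(_SENSE_CODONS), size=n_body, p=codon_probs)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    orf = "ATG" + "".join(_SENSE_CODONS[i] for i in body_idx) + stop
    flank = length - orf_len
    left = int(rng.integers(flank + 1))
    return (
        _random_seq(rng, left, "uniform")
        + orf
        + _random_seq(rng, flank - left, "uniform")
    )


def generate(config: GeneratorConfig) -> list[Transcript]:
    """Generate the labeled synthetic dataset described by ``config``.

    Returns coding-like records first (ids ``coding_0000`` ...), then
    non-coding-like ones; within each class the configured ambiguity
    fraction of records (the last ones) come from the boundary regime.
    Byte-identical output for identical config and seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    codon_probs = _biased_codon_probs(config.codon_bias_strength)
    out: list[Transcript] = []

    for label, n in ((CODING, config.n_coding), (NONCODING, config.n_noncoding)):
        n_ambig = int(round(config.ambiguity_fraction * n))
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            ambiguous = i >= n - n_ambig
            if ambiguous:
                seq = _embedded_orf_seq(
                    rng, length, config.ambiguous_coverage, codon_probs=None
                )
            elif label == CODING:
                seq = _embedded_orf_seq(
                    rng, length, config.orf_coverage, codon_probs=codon_probs
                )
            else:
                seq = _random_seq(rng, length, config.noncoding_model)
            out.append(
                Transcript(id=f"{label}_{i:04d}", sequence=seq, label=label)
            )
    return out
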