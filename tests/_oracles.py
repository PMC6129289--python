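"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written as plainly as possible (explicit loops,
no shared code with the package) so agreement with the vectorized
implementation is meaningful.
"""

from itertools import product

STOPS = ("TAA", "TAG", "TGA")


def orfs_bruteforce(seq):
    """All (start, end) ORFs by enumerating every (ATG, in-frame stop) pair
    and keeping the nearest stop per start; plus the total ATG count."""
    atgs = [i for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG"]
    orfs = []
    for i in atgs:
        candidates = [
            q
            for q in range(len(seq) - 2)
            if q % 3 == i % 3 and q >= i + 3 and seq[q : q + 3] in STOPS
        ]
        if candidates:
            orfs.append((i, min(candidates) + 3))
    return orfs, len(atgs)


def codon_position_bias_bruteforce(seq):
    """Per-base min/max positional-count ratio via explicit slicing."""
    out = []
    for base in "ACGT":
        counts = [seq[j::3].count(base) for j in range(3)]
        out.append(min(counts) / max(counts) if max(counts) > 0 else 0.0)
    return out


def frame_bias_bruteforce(seq):
    orfs, _ = orfs_bruteforce(seq)
    if not orfs:
        return 0.0
    per_frame = [sum(1 for s, _ in orfs if s % 3 == f) for f in range(3)]
    return 1.0 - min(per_frame) / max(per_frame)


def orf_frequency_bruteforce(seq):
    orfs, n_atg = orfs_bruteforce(seq)
    return len(orfs) / n_atg if n_atg else 0.0


def kmer_frequencies_bruteforce(seq, k):
    """Dict-count every N-free window, then normalize; lexicographic order."""
    counts = {"".join(p): 0 for p in product("ACGT", repeat=k)}
    n_valid = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if w in counts:
            counts[w] += 1
            n_valid += 1
    if n_valid == 0:
        return [0.0] * (4**k)
    return [counts[w] / n_valid for w in sorted(counts)]


def confusion_bruteforce(decisions, truths):
    """Confusion counts over non-rejected items, positive = noncoding."""
    tp = tn = fp = fn = rej = 0
    for d, t in zip(decisions, truths):
        if d == "rejected":
            rej += 1
        elif t == "noncoding" and d == "noncoding":
            tp += 1
        elif t == "coding" and d == "coding":
            tn += 1
        elif t == "coding" and d == "noncoding":
            fp += 1
        elif t == "noncoding" and d == "coding":
            fn += 1
    return tp, tn, fp, fn, rej


def random_sequence(rng, length, n_prob=0.0):
    bases = "ACGTN" if n_prob > 0 else "ACGT"
    p = [
        (1 - n_prob) / 4,
        (1 - n_prob) / 4,
        (1 - n_prob) / 4,
        (1 - n_prob) / 4,
        n_prob,
    ][: len(bases)]
    return "".join(rng.choice(list(bases), size=length, p=p))
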