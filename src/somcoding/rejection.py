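"""Ambiguity rejection and evaluation metrics.

A prediction is *rejected* when the two perceptron outputs are too close
to call: ``|o_coding - o_noncoding| < beta`` (strict) for a rejection
threshold ``beta`` in [0, 1].  Otherwise the class is the argmax, with
ties resolved to non-coding.  Metrics are computed on the non-rejected
records only; the positive class is the non-coding class, so sensitivity
is the recall of non-coding RNAs and specificity the recall of coding
RNAs.  A metric whose denominator is zero is reported as missing (NaN),
never silently as 0, so an all-rejected evaluation is distinguishable
from a failing one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fasta_io import CODING, NONCODING, REJECTED


@dataclass(frozen=True)
class PredictionRecord:
    """Per-transcript outputs, decision and best-matching-unit coordinates."""

    id: str
    o_coding: float
    o_noncoding: float
    decision: str
    bmu: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and metrics over the non-rejected predictions.

    ``accuracy = (TP+TN)/(TP+FP+FN+TN)``, ``sensitivity = TP/(TP+FN)``,
    ``specificity = TN/(TN+FP)`` with non-coding as the positive class.
    Metrics with a zero denominator are ``None``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    n_rejected: int
    n_total: int
    beta: float

    @property
    def accuracy(self) -> Optional[float]:
        d = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / d if d else None

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def reject_rate(self) -> float:
        return self.n_rejected / self.n_total if self.n_total else 0.0

    def as_dict(self) -> dict:
        return {
            "beta": self.beta,
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "reject_rate": self.reject_rate,
        }


def classify(o_coding: float, o_noncoding: float) -> str:
    """Argmax class with the tie resolved to non-coding."""
    return CODING if o_coding > o_noncoding else NONCODING


def apply_rejection(outputs: np.ndarray, beta: float) -> list[str]:
    """Decide coding / noncoding / rejected for each output pair.

    Rejection is strict: ``|o0 - o1| < beta``; equality is not rejected.
    With beta = 0 nothing is rejected; with beta = 1 everything is (the
    sigmoid outputs lie in the open interval (0, 1), so their difference
    is strictly below 1).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    decisions = []
    for o0, o1 in outputs:
        if abs(o0 - o1) < beta:
            decisions.append(REJECTED)
        else:
            decisions.append(classify(o0, o1))
    return decisions


def make_records(
    ids: Sequence[str],
    outputs: np.ndarray,
    beta: float,
    bmus: Optional[np.ndarray] = None,
) -> list[PredictionRecord]:
    """Bundle prediction outputs into records with rejection applied."""
    decisions = apply_rejection(outputs, beta)
    if bmus is None:
        bmus = np.zeros((len(ids), 2), dtype=int)
    return [
        PredictionRecord(
            id=i,
            o_coding=float(o[0]),
            o_noncoding=float(o[1]),
            decision=d,
            bmu=(int(b[0]), int(b[1])),
        )
        for i, o, d, b in zip(ids, np.atleast_2d(outputs), decisions, bmus)
    ]


def evaluate(
    records: Sequence[PredictionRecord], truth: dict[str, str], beta: float | None = None
) -> EvaluationReport:
    """Confusion counts and metrics on the non-rejected records.

    ``truth`` maps record id to its true label; every record id must be
    present.  ``beta`` is recorded in the report for provenance (taken
    from the records' rejection pattern when omitted — purely a label).
    """
    tp = tn = fp = fn = rejected = 0
    for r in records:
        if r.id not in truth:
            raise KeyError(f"no truth label for record {r.id!r}")
        if r.decision == REJECTED:
            rejected += 1
            continue
        actual, predicted = truth[r.id], r.decision
        if actual == NONCODING and predicted == NONCODING:
            tp += 1
        elif actual == CODING and predicted == CODING:
            tn += 1
        elif actual == CODING and predicted == NONCODING:
            fp += 1
        else:
            fn += 1
    return EvaluationReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        n_rejected=rejected,
        n_total=len(records),
        beta=float(beta) if beta is not None else float("nan"),
    )


def threshold_sweep(
    ids: Sequence[str],
    outputs: np.ndarray,
    truth: dict[str, str],
    betas: Sequence[float],
) -> pd.DataFrame:
    """Evaluate the same outputs across a sorted ascending grid of betas.

    Returns one row per beta with the confusion counts and metrics
    (missing metrics as NaN).  The reject rate is checked to be
    non-decreasing in beta, which the strict-inequality rule guarantees.
    """
    betas = list(betas)
    if betas != sorted(betas):
        raise ValueError("betas must be sorted ascending")
    rows = []
    prev_rate = -1.0
    for beta in betas:
        records = make_records(ids, outputs, beta)
        rep = evaluate(records, truth, beta=beta)
        assert rep.reject_rate >= prev_rate, "reject rate must be non-decreasing"
        prev_rate = rep.reject_rate
        rows.append(rep.as_dict())
    df = pd.DataFrame(rows)
    return df.astype({"TP": int, "TN": int, "FP": int, "FN": int})
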