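"""Prediction metrics: accuracy, top-fraction curves, O/E propensities.

Because the predictor only emits positive calls (a pair is either
predicted to be in a bin or not predicted at all), there are no true or
false negatives, and accuracy — correct predictions over all
predictions, as a percentage — coincides with the positive predictive
value. Top-fraction curves report that accuracy for the best-scoring
floor(f·L) predictions at a set of fractions f of the chain length.

Residue-type propensities ask whether correctly predicted pairs of a
bin are biased toward particular amino-acid combinations: per structure,
E is the fraction of the bin's true pairs of type {A,B}, O the fraction
of the correctly predicted pairs of that type, and the reported quantity
is log2 of O/E averaged over structures where the type occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constraints import PairPrediction
from .msa import AMINO_ACIDS

_AA_INDEX = {a: k for k, a in enumerate(AMINO_ACIDS)}


@dataclass
class AccuracyReport:
    bin: str
    n_predictions: int
    n_correct: int

    @property
    def empty(self) -> bool:
        return self.n_predictions == 0

    @property
    def accuracy_percent(self) -> float:
        if self.empty:
            raise ValueError(f"no predictions for bin {self.bin}; accuracy undefined")
        return 100.0 * self.n_correct / self.n_predictions


def accuracy(
    preds: list[PairPrediction],
    truth: dict[tuple[int, int], str | None],
    bin_name: str | None = None,
) -> AccuracyReport:
    """Percentage of predictions whose pair truly lies in the predicted bin.

    Pairs whose truth label is ``"unknown"`` (e.g. unresolved residues)
    are excluded before counting. With no negative predictions this
    equals the positive predictive value.
    """
    if bin_name is None:
        bins = {p.bin for p in preds}
        bin_name = bins.pop() if len(bins) == 1 else "all"
    n = 0
    correct = 0
    for p in preds:
        label = truth.get((p.i, p.j))
        if label == "unknown":
            continue
        n += 1
        if label == p.bin:
            correct += 1
    return AccuracyReport(bin=bin_name, n_predictions=n, n_correct=correct)


def positive_predictive_value(
    preds: list[PairPrediction],
    truth: dict[tuple[int, int], str | None],
) -> float:
    """TP / (TP + FP) computed via an explicit confusion count."""
    tp = fp = 0
    for p in preds:
        label = truth.get((p.i, p.j))
        if label == "unknown":
            continue
        if label == p.bin:
            tp += 1
        else:
            fp += 1
    if tp + fp == 0:
        raise ValueError("no scored predictions; PPV undefined")
    return tp / (tp + fp)


def rank_predictions(preds: list[PairPrediction]) -> list[PairPrediction]:
    """Score descending, ties by (i, j) ascending."""
    return sorted(preds, key=lambda p: (-p.score, p.i, p.j))


@dataclass
class TopkPoint:
    fraction: float
    k: int
    report: AccuracyReport
    truncated: bool


def topk_curve(
    preds: list[PairPrediction],
    truth: dict[tuple[int, int], str | None],
    L: int,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 1.5),
) -> list[TopkPoint]:
    """Accuracy of the top floor(f·L) predictions at each fraction f."""
    ranked = rank_predictions(preds)
    points = []
    for f in sorted(fractions):
        k = math.floor(f * L)
        truncated = k > len(ranked)
        subset = ranked[:k]
        points.append(
            TopkPoint(
                fraction=f,
                k=min(k, len(ranked)),
                report=accuracy(subset, truth),
                truncated=truncated,
            )
        )
    return points


def _type_key(a: str, b: str) -> tuple[int, int]:
    ia, ib = _AA_INDEX[a], _AA_INDEX[b]
    return (ia, ib) if ia <= ib else (ib, ia)


@dataclass
class StructureEvaluation:
    """One structure's truth and scored predictions for propensity analysis."""

    sequence: str
    truth: dict[tuple[int, int], str | None]
    predictions: list[PairPrediction]


@dataclass
class PropensityTable:
    """<O/E> residue-type propensities and per-pair-type precision."""

    bin: str
    oe_mean: np.ndarray          # 20 x 20, nan where no structure contributes
    n_structures: np.ndarray     # 20 x 20 contributing-structure counts
    precision: np.ndarray        # 20 x 20 pooled per-type precision
    skipped_structures: list[int] = field(default_factory=list)

    @property
    def log2_oe(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(self.oe_mean)


def _pair_type_fractions(
    pairs: list[tuple[int, int]], sequence: str
) -> dict[tuple[int, int], float]:
    counts: dict[tuple[int, int], int] = {}
    for i, j in pairs:
        key = _type_key(sequence[i - 1], sequence[j - 1])
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def propensity(
    structures: list[StructureEvaluation],
    bin_name: str,
    threshold: float = 0.7,
    pooled: bool = False,
) -> PropensityTable:
    """O/E propensity of residue-type pairs among correct predictions.

    Per structure: E is the type distribution of all true pairs of the
    bin, O the type distribution of correctly predicted pairs with score
    >= ``threshold`` (Σ O = Σ E = 1 within each structure). O/E is
    averaged over structures where the type occurs in the truth (E > 0);
    structures with no correct prediction in the bin are skipped. With
    ``pooled`` the counts are pooled over structures before the ratio is
    taken (comparison variant). Per-type precision is always pooled:
    correct predictions of the type over all predictions of the type.
    """
    oe_sum = np.zeros((20, 20))
    oe_n = np.zeros((20, 20), dtype=int)
    pooled_truth: dict[tuple[int, int], int] = {}
    pooled_correct: dict[tuple[int, int], int] = {}
    predicted_counts = np.zeros((20, 20))
    correct_counts = np.zeros((20, 20))
    skipped = []

    for s_idx, s in enumerate(structures):
        truth_pairs = [pair for pair, lab in s.truth.items() if lab == bin_name]
        scored = [
            p for p in s.predictions if p.bin == bin_name and p.score >= threshold
        ]
        correct = [p for p in scored if s.truth.get((p.i, p.j)) == bin_name]
        for p in scored:
            a, b = _type_key(s.sequence[p.i - 1], s.sequence[p.j - 1])
            predicted_counts[a, b] += 1
        for p in correct:
            a, b = _type_key(s.sequence[p.i - 1], s.sequence[p.j - 1])
            correct_counts[a, b] += 1
        if not truth_pairs:
            continue
        if not correct:
            skipped.append(s_idx)
            continue
        E = _pair_type_fractions(truth_pairs, s.sequence)
        O = _pair_type_fractions([(p.i, p.j) for p in correct], s.sequence)
        for key, e in E.items():
            if pooled:
                continue
            o = O.get(key, 0.0)
            oe_sum[key] += o / e
            oe_n[key] += 1
        if pooled:
            for (i, j) in truth_pairs:
                key = _type_key(s.sequence[i - 1], s.sequence[j - 1])
                pooled_truth[key] = pooled_truth.get(key, 0) + 1
            for p in correct:
                key = _type_key(s.sequence[p.i - 1], s.sequence[p.j - 1])
                pooled_correct[key] = pooled_correct.get(key, 0) + 1

    if pooled:
        oe = np.full((20, 20), np.nan)
        total_truth = sum(pooled_truth.values())
        total_correct = sum(pooled_correct.values())
        for key, nt in pooled_truth.items():
            e = nt / total_truth
            o = pooled_correct.get(key, 0) / total_correct if total_correct else 0.0
            oe[key] = o / e
            oe_n[key] = 1
    else:
        with np.errstate(invalid="ignore"):
            oe = np.where(oe_n > 0, oe_sum / np.maximum(oe_n, 1), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(predicted_counts > 0, correct_counts / np.maximum(predicted_counts, 1), np.nan)

    # mirror the upper triangle so tables are symmetric in type exchange
    oe = _symmetrise(oe)
    prec = _symmetrise(prec)
    n_sym = np.maximum(oe_n, oe_n.T)
    return PropensityTable(
        bin=bin_name, oe_mean=oe, n_structures=n_sym, precision=prec,
        skipped_structures=skipped,
    )


def _symmetrise(mat: np.ndarray) -> np.ndarray:
    out = mat.copy()
    lower = np.tril_indices(20, k=-1)
    out[lower] = mat.T[lower]
    return out
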