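"""Significance-threshold derivation by a dual-reference F1-score scan.

Given per-protein mean log2 knockdown ratios and two disjoint reference
proteomes — organellar (expected depleted) and non-organellar (expected
unaffected) — the scan evaluates, on a regular ratio grid, how well a
candidate threshold theta separates the two sets:

* depleted side (organellar reference): a protein is "called" when its mean
  log2 ratio is <= theta; TP/FP/FN are counted within the union of the two
  reference sets and F1 = harmonic mean of precision TP/(TP+FP) and
  sensitivity TP/(TP+FN).
* unaffected side (non-organellar reference): the mirror image, a protein
  is "called" when its ratio is > theta.

The argmax-F1 grid values are t2 (organellar curve) and t1 (non-organellar
curve); the adopted significance threshold is the more stringent (more
negative) of the two, min(t1, t2).

Grid values are carried in integer hundredths of a log2 unit so that the
0.01 increments are exact decimals; ratio comparisons against grid values
use a small epsilon to absorb binary-float drift in computed means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from importomics.quant_io import ReferenceSet
from importomics.replicate_stats import ProteinStatistics

#: absolute slack when comparing a mean ratio against an exact-decimal grid value
GRID_EPS = 1e-9

Side = Literal["depleted", "unaffected"]


@dataclass(frozen=True)
class F1Point:
    """Confusion counts and F1 score of one candidate threshold."""

    threshold: float
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    f1: float


@dataclass
class ThresholdScanResult:
    grid_step: float
    curve_positive_ref: list[F1Point]
    curve_negative_ref: list[F1Point]
    t2: float  # argmax F1, positive (organellar) reference curve
    t1: float  # argmax F1, negative (non-organellar) reference curve
    chosen_threshold: float

    @property
    def max_f1_positive(self) -> float:
        return max(p.f1 for p in self.curve_positive_ref)

    @property
    def max_f1_negative(self) -> float:
        return max(p.f1 for p in self.curve_negative_ref)


def _f1_from_counts(tp: int, fp: int, fn: int, threshold: float) -> F1Point:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return F1Point(threshold, tp, fp, fn, precision, sensitivity, f1)


def _quantified_means(
    stats: Iterable[ProteinStatistics], ids: frozenset[str]
) -> np.ndarray:
    return np.array(
        [
            s.mean_log2
            for s in stats
            if s.passed_filter and not math.isnan(s.mean_log2) and s.protein_id in ids
        ]
    )


def _check_disjoint(reference: ReferenceSet, opposite: ReferenceSet) -> None:
    shared = reference.ids & opposite.ids
    if shared:
        raise ValueError(
            f"reference sets {reference.name!r} and {opposite.name!r} overlap: "
            f"{sorted(shared)[:10]}"
        )


def confusion_at_threshold(
    theta: float,
    stats: Sequence[ProteinStatistics],
    reference: ReferenceSet,
    opposite: ReferenceSet,
    side: Side = "depleted",
) -> F1Point:
    """Confusion counts of threshold ``theta`` against one reference set.

    Only filter-passing proteins with a defined mean that belong to one of
    the two reference sets enter the counts; the unlabeled pool being
    classified is ignored.
    """
    _check_disjoint(reference, opposite)
    ref_means = _quantified_means(stats, reference.ids)
    opp_means = _quantified_means(stats, opposite.ids)
    cut = theta + GRID_EPS
    if side == "depleted":
        tp = int(np.sum(ref_means <= cut))
        fp = int(np.sum(opp_means <= cut))
        fn = ref_means.size - tp
    elif side == "unaffected":
        tp = int(np.sum(ref_means > cut))
        fp = int(np.sum(opp_means > cut))
        fn = ref_means.size - tp
    else:
        raise ValueError(f"unknown side {side!r}")
    return _f1_from_counts(tp, fp, fn, theta)


def _scan_curve(
    ref_means: np.ndarray,
    opp_means: np.ndarray,
    side: Side,
    step_c: int,
    start_rule: str,
) -> list[F1Point]:
    """Vectorized F1 curve over the exact-decimal grid (centi-log2 units)."""
    all_means = np.concatenate([ref_means, opp_means])
    hi_c = math.ceil(round(all_means.max() / 0.01, 6))
    if start_rule == "literal" and side == "depleted":
        # lowest ratio at which >=1 TP and >=1 FP exist
        start = max(ref_means.min(), opp_means.min())
    else:
        start = all_means.min()
    lo_c = math.floor(round(start / 0.01, 6))
    grid_c = np.arange(lo_c, hi_c + 1, step_c)
    thetas = grid_c / 100.0

    ref_sorted = np.sort(ref_means)
    opp_sorted = np.sort(opp_means)
    n_ref_le = np.searchsorted(ref_sorted, thetas + GRID_EPS, side="right")
    n_opp_le = np.searchsorted(opp_sorted, thetas + GRID_EPS, side="right")
    if side == "depleted":
        tp, fp = n_ref_le, n_opp_le
    else:
        tp = ref_sorted.size - n_ref_le
        fp = opp_sorted.size - n_opp_le
    fn = ref_sorted.size - tp
    return [
        _f1_from_counts(int(t), int(f), int(n), float(th))
        for th, t, f, n in zip(thetas, tp, fp, fn)
    ]


def _argmax_most_negative(curve: Sequence[F1Point]) -> float:
    """Grid value maximizing F1; ties go to the most negative threshold."""
    best = max(p.f1 for p in curve)
    return min(p.threshold for p in curve if p.f1 == best)


def scan_f1(
    stats: Sequence[ProteinStatistics],
    positive_ref: ReferenceSet,
    negative_ref: ReferenceSet,
    grid_step: float = 0.01,
    start_rule: Literal["literal", "full"] = "literal",
    candidates: Literal["grid", "observed"] = "grid",
) -> ThresholdScanResult:
    """Scan the ratio grid for the F1-optimal thresholds t2 and t1.

    ``start_rule="literal"`` starts the depleted-side curve at the lowest
    ratio at which at least one TP and one FP are present; ``"full"``
    evaluates the whole observed range (useful when a perfectly separating
    threshold exists below the first FP).  ``candidates="observed"``
    replaces the regular grid with the set of observed mean ratios.
    """
    _check_disjoint(positive_ref, negative_ref)
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    step_c = round(grid_step / 0.01)
    if step_c < 1 or abs(step_c * 0.01 - grid_step) > 1e-9:
        raise ValueError("grid_step must be a positive multiple of 0.01")

    pos_means = _quantified_means(stats, positive_ref.ids)
    neg_means = _quantified_means(stats, negative_ref.ids)
    if pos_means.size == 0:
        raise ValueError(
            f"reference set {positive_ref.name!r} has no quantified members"
        )
    if neg_means.size == 0:
        raise ValueError(
            f"reference set {negative_ref.name!r} has no quantified members"
        )

    if candidates == "observed":
        curve_pos = _observed_curve(pos_means, neg_means, "depleted", start_rule)
        curve_neg = _observed_curve(neg_means, pos_means, "unaffected", start_rule)
    else:
        curve_pos = _scan_curve(pos_means, neg_means, "depleted", step_c, start_rule)
        curve_neg = _scan_curve(neg_means, pos_means, "unaffected", step_c, start_rule)

    t2 = _argmax_most_negative(curve_pos)
    t1 = _argmax_most_negative(curve_neg)
    return ThresholdScanResult(
        grid_step=step_c * 0.01,
        curve_positive_ref=curve_pos,
        curve_negative_ref=curve_neg,
        t2=t2,
        t1=t1,
        chosen_threshold=choose_threshold(t1, t2),
    )


def _observed_curve(
    ref_means: np.ndarray, opp_means: np.ndarray, side: Side, start_rule: str
) -> list[F1Point]:
    """F1 at every observed mean ratio instead of the regular grid."""
    all_means = np.concatenate([ref_means, opp_means])
    if start_rule == "literal" and side == "depleted":
        start = max(ref_means.min(), opp_means.min())
    else:
        start = all_means.min()
    thetas = np.unique(all_means)
    thetas = thetas[thetas >= start - GRID_EPS]
    ref_sorted = np.sort(ref_means)
    opp_sorted = np.sort(opp_means)
    n_ref_le = np.searchsorted(ref_sorted, thetas + GRID_EPS, side="right")
    n_opp_le = np.searchsorted(opp_sorted, thetas + GRID_EPS, side="right")
    if side == "depleted":
        tp, fp = n_ref_le, n_opp_le
    else:
        tp = ref_sorted.size - n_ref_le
        fp = opp_sorted.size - n_opp_le
    fn = ref_sorted.size - tp
    return [
        _f1_from_counts(int(t), int(f), int(n), float(th))
        for th, t, f, n in zip(thetas, tp, fp, fn)
    ]


def choose_threshold(t1: float, t2: float) -> float:
    """The adopted significance threshold: the more stringent of t1 and t2."""
    return min(t1, t2)


def curve_to_rows(curve: Sequence[F1Point]) -> list[dict]:
    """Serialize an F1 curve for TSV export."""
    return [
        {
            "threshold": p.threshold,
            "tp": p.tp,
            "fp": p.fp,
            "fn": p.fn,
            "precision": p.precision,
            "sensitivity": p.sensitivity,
            "f1": p.f1,
        }
        for p in curve
    ]
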