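"""Importome calling, new-candidate identification and overlap accounting.

A filter-passing protein is called *imported* (organellar, import-dependent)
when its mean log2 (+Tet/-Tet) ratio is at or below the significance
threshold and its t-test p-value is below alpha; the ratio gate is inclusive
(<=), the p gate strict (<).  Proteins that fail the identification filter
or lack the statistics are *unquantifiable*; everything else is
*unaffected*.  A fixed fold-change mode replaces the derived threshold with
a symmetric log2 fold cut and reports a direction (down/up/none), as used
for whole-cell (1.5-fold) and disulfide-relay knockdown (2-fold) datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from importomics.quant_io import ReferenceSet
from importomics.replicate_stats import ProteinStatistics
from importomics.threshold_f1 import GRID_EPS

CALL_IMPORTED = "imported"
CALL_UNAFFECTED = "unaffected"
CALL_UNQUANTIFIABLE = "unquantifiable"


@dataclass
class ImportomeCall:
    protein_id: str
    mean_log2: float
    p_value: float
    call: str  # imported | unaffected | unquantifiable
    direction: str = "none"  # down | up | none (fixed-fold mode)
    is_new_candidate: bool = False


def _base_call(stat: ProteinStatistics) -> str | None:
    """Return the unquantifiable call if the protein cannot be classified."""
    if (
        not stat.passed_filter
        or math.isnan(stat.mean_log2)
        or math.isnan(stat.p_value)
    ):
        return CALL_UNQUANTIFIABLE
    return None


def call_importome(
    stats: Sequence[ProteinStatistics],
    threshold: float,
    alpha: float = 0.05,
) -> list[ImportomeCall]:
    """Classify every protein against a derived depletion threshold."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    calls: list[ImportomeCall] = []
    for stat in stats:
        call = _base_call(stat)
        if call is None:
            imported = (
                stat.mean_log2 <= threshold + GRID_EPS and stat.p_value < alpha
            )
            call = CALL_IMPORTED if imported else CALL_UNAFFECTED
        calls.append(
            ImportomeCall(
                protein_id=stat.protein_id,
                mean_log2=stat.mean_log2,
                p_value=stat.p_value,
                call=call,
                direction="down" if call == CALL_IMPORTED else "none",
            )
        )
    return calls


def call_fixed_fold(
    stats: Sequence[ProteinStatistics],
    fold: float,
    alpha: float = 0.05,
) -> list[ImportomeCall]:
    """Classify by a symmetric fixed fold change (e.g. 1.5x or 2x) and alpha."""
    if fold <= 1:
        raise ValueError(f"fold must exceed 1, got {fold}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    cut = math.log2(fold)
    calls: list[ImportomeCall] = []
    for stat in stats:
        call = _base_call(stat)
        direction = "none"
        if call is None:
            if stat.p_value < alpha and stat.mean_log2 <= -cut + GRID_EPS:
                direction = "down"
            elif stat.p_value < alpha and stat.mean_log2 >= cut - GRID_EPS:
                direction = "up"
            call = CALL_IMPORTED if direction == "down" else CALL_UNAFFECTED
        calls.append(
            ImportomeCall(
                protein_id=stat.protein_id,
                mean_log2=stat.mean_log2,
                p_value=stat.p_value,
                call=call,
                direction=direction,
            )
        )
    return calls


def identify_new_candidates(
    calls: Iterable[ImportomeCall], known_ref: ReferenceSet
) -> set[str]:
    """Imported proteins absent from the known reference set; flags the calls."""
    new: set[str] = set()
    for call in calls:
        call.is_new_candidate = (
            call.call == CALL_IMPORTED and call.protein_id not in known_ref
        )
        if call.is_new_candidate:
            new.add(call.protein_id)
    return new


@dataclass(frozen=True)
class OverlapSummary:
    """How much of each reference set was quantified and called imported."""

    positive_quantified: int
    positive_imported: int
    positive_imported_pct: float  # one decimal
    negative_quantified: int
    negative_imported: int
    negative_imported_pct: float


def reference_overlap_summary(
    calls: Sequence[ImportomeCall],
    positive_ref: ReferenceSet,
    negative_ref: ReferenceSet,
) -> OverlapSummary:
    """Tabulate importome membership of both reference sets.

    Denominators are reference members present among classifiable
    (filter-passing, quantified) proteins.
    """
    shared = positive_ref.ids & negative_ref.ids
    if shared:
        raise ValueError(f"reference sets overlap: {sorted(shared)[:10]}")

    def count(ref: ReferenceSet) -> tuple[int, int]:
        quantified = imported = 0
        for call in calls:
            if call.protein_id in ref and call.call != CALL_UNQUANTIFIABLE:
                quantified += 1
                if call.call == CALL_IMPORTED:
                    imported += 1
        return quantified, imported

    pos_q, pos_i = count(positive_ref)
    neg_q, neg_i = count(negative_ref)
    return OverlapSummary(
        positive_quantified=pos_q,
        positive_imported=pos_i,
        positive_imported_pct=round(100.0 * pos_i / pos_q, 1) if pos_q else 0.0,
        negative_quantified=neg_q,
        negative_imported=neg_i,
        negative_imported_pct=round(100.0 * neg_i / neg_q, 1) if neg_q else 0.0,
    )


def volcano_table(
    stats: Sequence[ProteinStatistics],
    calls: Sequence[ImportomeCall],
    positive_ref: ReferenceSet | None = None,
    negative_ref: ReferenceSet | None = None,
) -> pd.DataFrame:
    """Export one volcano-plot row per filter-passing protein.

    Columns: protein_id, mean_log2, neg_log10_p, call, is_new_candidate,
    reference_membership (positive/negative/other).
    """
    if len(stats) != len(calls) or any(
        s.protein_id != c.protein_id for s, c in zip(stats, calls)
    ):
        raise ValueError("stats and calls are not aligned by protein id")

    rows = []
    for stat, call in zip(stats, calls):
        if not stat.passed_filter:
            continue
        membership = "other"
        if positive_ref is not None and stat.protein_id in positive_ref:
            membership = "positive"
        elif negative_ref is not None and stat.protein_id in negative_ref:
            membership = "negative"
        rows.append(
            {
                "protein_id": stat.protein_id,
                "mean_log2": stat.mean_log2,
                "neg_log10_p": -math.log10(stat.p_value)
                if not math.isnan(stat.p_value) and stat.p_value > 0
                else (math.inf if stat.p_value == 0 else np.nan),
                "call": call.call,
                "is_new_candidate": call.is_new_candidate,
                "reference_membership": membership,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "mean_log2",
            "neg_log10_p",
            "call",
            "is_new_candidate",
            "reference_membership",
        ],
    )
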