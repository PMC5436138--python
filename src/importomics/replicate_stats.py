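"""Identification/quantification filtering and per-protein ratio statistics.

A protein enters downstream analysis only if it was identified with enough
peptides (at least one unique) and quantified in enough biological
replicates.  An optional rescue clause admits single-unique-peptide proteins
that were quantified in every replicate with fragment-spectrum (MS/MS)
evidence in a minimum number of them, as used for gradient-purified
organelle datasets.

For each protein the mean of the oriented log2 (+Tet/-Tet) ratios across
replicates is tested against zero with a one-sample two-sided Student
t-test; the (mean, p) pair is the coordinate of the protein on the volcano
plot and the input to threshold derivation and importome calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from importomics.quant_io import EVIDENCE_MSMS, ProteinQuantRecord


@dataclass(frozen=True)
class FilterPolicy:
    """Identification/quantification filter, including the rescue clause.

    Defaults implement the general rule (>=2 peptides, >=1 unique,
    quantified in >=2 replicates) with the rescue path disabled.
    """

    min_peptides: int = 2
    min_unique_peptides: int = 1
    min_quantified_replicates: int = 2
    single_peptide_rescue: bool = False
    rescue_requires_all_replicates: bool = True
    rescue_min_msms_replicates: int = 2

    def __post_init__(self) -> None:
        if self.min_unique_peptides > self.min_peptides:
            raise ValueError("min_unique_peptides must not exceed min_peptides")
        if min(self.min_peptides, self.min_unique_peptides,
               self.min_quantified_replicates, self.rescue_min_msms_replicates) < 0:
            raise ValueError("filter counts must be non-negative")


#: Policy for gradient-purified organelle datasets: the general rule plus
#: the single-unique-peptide rescue (quantified in all replicates, MS/MS
#: evidence in at least two).
GRADIENT_ORGANELLE_POLICY = FilterPolicy(single_peptide_rescue=True)


@dataclass
class ProteinStatistics:
    """Per-protein ratio summary: mean log2 ratio, t-test p-value, filter flag."""

    protein_id: str
    ratios: np.ndarray
    n_quantified: int
    mean_log2: float  # nan when nothing was quantified
    p_value: float  # nan when fewer than two replicates quantified
    passed_filter: bool


def summarize_protein(ratios: Sequence[float] | np.ndarray) -> tuple[float, float, int]:
    """Mean log2 ratio and two-sided one-sample t-test p-value against zero.

    Missing replicates (nan) are dropped.  Returns ``(mean, p, n_quantified)``
    with nan for statistics that are undefined: the mean needs one value, the
    test two.  Degenerate zero-variance samples use the limit of the t
    statistic: p=1 when the mean is also zero, p=0 otherwise.
    """
    values = np.asarray(ratios, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n == 0:
        return math.nan, math.nan, 0
    mean = float(np.mean(values))
    if n == 1:
        return mean, math.nan, 1
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return mean, (1.0 if mean == 0.0 else 0.0), n
    p = float(sps.ttest_1samp(values, popmean=0.0).pvalue)
    return mean, p, n


def _passes(record: ProteinQuantRecord, policy: FilterPolicy, n_quantified: int) -> bool:
    main = (
        record.n_peptides >= policy.min_peptides
        and record.n_unique_peptides >= policy.min_unique_peptides
        and n_quantified >= policy.min_quantified_replicates
    )
    if main:
        return True
    if not policy.single_peptide_rescue or record.n_unique_peptides < 1:
        return False
    n_replicates = len(record.log2_ratios)
    quantified_enough = (
        n_quantified == n_replicates
        if policy.rescue_requires_all_replicates
        else n_quantified >= policy.min_quantified_replicates
    )
    n_msms = sum(1 for ev in record.evidence if ev == EVIDENCE_MSMS)
    return quantified_enough and n_msms >= policy.rescue_min_msms_replicates


def apply_identification_filter(
    records: Iterable[ProteinQuantRecord],
    policy: FilterPolicy = FilterPolicy(),
) -> list[ProteinStatistics]:
    """Compute statistics for every record and set its filter flag.

    Failing records are retained with ``passed_filter=False`` so that
    exports and audits can account for every input protein; filtering never
    raises on data content.
    """
    out: list[ProteinStatistics] = []
    for record in records:
        mean, p, n = summarize_protein(record.log2_ratios)
        out.append(
            ProteinStatistics(
                protein_id=record.protein_id,
                ratios=np.array(record.log2_ratios, dtype=float),
                n_quantified=n,
                mean_log2=mean,
                p_value=p,
                passed_filter=_passes(record, policy, n),
            )
        )
    return out
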