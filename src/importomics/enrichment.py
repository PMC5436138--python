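"""Fisher exact enrichment tests with Benjamini-Hochberg FDR control.

Overrepresentation of a property (a predicted-substrate list, a functional
term) inside a hit set is tested against the background of all quantified,
filter-passing proteins of the same experiment — never against the whole
genome — with the two-sided Fisher exact test.  Across a family of term
tests, raw p-values are adjusted by the Benjamini-Hochberg step-up
procedure, which controls the false discovery rate.

Term annotations are generic protein->term maps; a term hierarchy can be
collapsed onto a slim vocabulary by ancestor closure before testing.  Each
term is tested independently (classic per-term Fisher); no hierarchical
decorrelation of nested terms is performed, so closely related terms share
signal and their p-values are not independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = in hit set / not, columns = has property / not."""

    a: int  # hit, with property
    b: int  # hit, without
    c: int  # non-hit, with property
    d: int  # non-hit, without

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table is empty")


@dataclass
class EnrichmentRecord:
    term_id: str
    hits_with_term: int
    hits_total: int
    background_with_term: int
    background_total: int
    odds_ratio: float  # may be inf; nan when undefined (two zero cells)
    p_raw: float
    p_adjusted: float


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: total probability of tables (same margins)
    no more likely than the observed one under the hypergeometric null."""
    p = sps.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    ).pvalue
    return float(min(p, 1.0))


def sample_odds_ratio(table: ContingencyTable2x2) -> float:
    """Unconditional cross-product ratio ad/bc; inf on a zero denominator
    with a non-zero numerator, nan when both vanish."""
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min over j >= i of p_(j) * m / j, capped at 1, where
    p_(1) <= ... <= p_(m) are the sorted raw values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted.tolist()


def test_substrate_enrichment(
    hit_set: set[str],
    predicted_set: set[str],
    background: set[str],
    term_id: str = "predicted_substrate",
) -> EnrichmentRecord:
    """Is the predicted set overrepresented among the hits?

    The predicted set is intersected with the background before counting;
    the hit set must be contained in the background.
    """
    stray = hit_set - background
    if stray:
        raise ValueError(
            f"hit set contains {len(stray)} accession(s) outside the background, "
            f"e.g. {sorted(stray)[:5]}"
        )
    predicted = predicted_set & background
    a = len(hit_set & predicted)
    b = len(hit_set) - a
    c = len(predicted) - a
    d = len(background) - len(hit_set) - c
    table = ContingencyTable2x2(a, b, c, d)
    p = fisher_exact_two_sided(table)
    return EnrichmentRecord(
        term_id=term_id,
        hits_with_term=a,
        hits_total=len(hit_set),
        background_with_term=len(predicted),
        background_total=len(background),
        odds_ratio=sample_odds_ratio(table),
        p_raw=p,
        p_adjusted=p,  # single-test family
    )


def _close_ancestors(ancestor_map: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Transitive closure of a term->parents map (memoized DFS)."""
    closed: dict[str, set[str]] = {}

    def visit(term: str, trail: tuple[str, ...] = ()) -> set[str]:
        if term in closed:
            return closed[term]
        if term in trail:
            raise ValueError(f"cycle in ancestor map at term {term!r}")
        result: set[str] = set()
        for parent in ancestor_map.get(term, ()):  # leaves have no entry
            result.add(parent)
            result |= visit(parent, trail + (term,))
        closed[term] = result
        return result

    for term in ancestor_map:
        visit(term)
    return closed


def reduce_to_slim(
    term_assignments: Mapping[str, set[str]],
    ancestor_map: Mapping[str, set[str]],
    slim_terms: set[str],
) -> dict[str, set[str]]:
    """Collapse each protein's terms onto a slim vocabulary.

    Each term is replaced by ({term} | ancestors(term)) & slim_terms with
    the ancestor map closed transitively first; proteins whose terms have
    no slim representative map to the empty set.  Terms absent from the
    ancestor map pass through only if they are themselves slim (a warning
    is logged once per unknown term).
    """
    closed = _close_ancestors(ancestor_map)
    warned: set[str] = set()
    reduced: dict[str, set[str]] = {}
    for protein, terms in term_assignments.items():
        slim_hits: set[str] = set()
        for term in terms:
            if term not in closed and term not in warned:
                log.warning("term %s missing from the ancestor map", term)
                warned.add(term)
            expanded = {term} | closed.get(term, set())
            slim_hits |= expanded & slim_terms
        reduced[protein] = slim_hits
    return reduced


def term_enrichment(
    hit_set: set[str],
    slim_assignments: Mapping[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """One Fisher test per term with at least one hit-set member, BH-adjusted.

    Terms private to non-hit proteins are not tested (they cannot be
    enriched in the hits and would only dilute the BH family); the count of
    untested terms is logged.  Records are sorted by adjusted then raw p.
    """
    if not background:
        raise ValueError("background is empty")
    stray = hit_set - background
    if stray:
        raise ValueError(
            f"hit set contains accession(s) outside the background: {sorted(stray)[:5]}"
        )

    term_to_proteins: dict[str, set[str]] = {}
    for protein in background:
        for term in slim_assignments.get(protein, ()):
            term_to_proteins.setdefault(term, set()).add(protein)

    tested: list[tuple[str, ContingencyTable2x2]] = []
    n_untested = 0
    for term, proteins in sorted(term_to_proteins.items()):
        a = len(proteins & hit_set)
        if a == 0:
            n_untested += 1
            continue
        b = len(hit_set) - a
        c = len(proteins) - a
        d = len(background) - len(hit_set) - c
        tested.append((term, ContingencyTable2x2(a, b, c, d)))
    if n_untested:
        log.info("%d term(s) with no hit-set member were not tested", n_untested)
    if not tested:
        return []

    p_raw = [fisher_exact_two_sided(t) for _, t in tested]
    p_adj = bh_adjust(p_raw)
    records = [
        EnrichmentRecord(
            term_id=term,
            hits_with_term=t.a,
            hits_total=len(hit_set),
            background_with_term=t.a + t.c,
            background_total=len(background),
            odds_ratio=sample_odds_ratio(t),
            p_raw=praw,
            p_adjusted=padj,
        )
        for (term, t), praw, padj in zip(tested, p_raw, p_adj)
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
    return records


# ---------------------------------------------------------------------------
# annotation file readers (TSV pairs and plain term lists)

def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """TSV with two columns protein_id<TAB>term_id, one pair per row."""
    assignments: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected two tab-separated fields, got {line!r}")
        assignments.setdefault(parts[0], set()).add(parts[1])
    return assignments


def read_ancestor_map(path: str | Path) -> dict[str, set[str]]:
    """TSV with two columns term_id<TAB>parent_id; closed transitively on use."""
    return read_annotation_map(path)


def read_term_list(path: str | Path) -> set[str]:
    """One term per line, "#" comments allowed."""
    terms = {
        line.split("#", 1)[0].strip()
        for line in Path(path).read_text().splitlines()
    }
    terms.discard("")
    return terms
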