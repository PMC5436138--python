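"""Fisher exact tests, BH adjustment, slim reduction and term enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from importomics import (
    ContingencyTable2x2,
    bh_adjust,
    fisher_exact_two_sided,
    reduce_to_slim,
    term_enrichment,
)
from importomics.enrichment import (
    test_substrate_enrichment as substrate_enrichment,
)


def fisher_by_enumeration(a, b, c, d):
    """Oracle: sum hypergeometric probabilities of all same-margin tables
    no more probable than the observed one."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: hypergeom.pmf(x, n, col1, row1) for x in range(lo, hi + 1)}
    observed = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= observed * (1 + 1e-9)))


class TestFisherExact:
    def test_balanced_table_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_enumerated_moderate_table(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_enumerated_extreme_table(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(10, 0, 0, 10))
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_matches_enumeration_on_small_margin_sample(self):
        for a, b, c, d in [(0, 3, 2, 5), (4, 1, 0, 7), (2, 2, 2, 2), (6, 0, 5, 1)]:
            assert fisher_exact_two_sided(
                ContingencyTable2x2(a, b, c, d)
            ) == pytest.approx(fisher_by_enumeration(a, b, c, d), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 1)


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.random(50)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(list(expected), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_inflation_order_invariance_idempotence(self, p_values):
        adjusted = bh_adjust(p_values)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, p_values))
        assert all(0 <= a <= 1 for a in adjusted)
        # permutation of inputs permutes outputs identically
        order = sorted(range(len(p_values)), key=lambda i: p_values[i])
        permuted = bh_adjust([p_values[i] for i in order])
        assert permuted == pytest.approx([adjusted[i] for i in order], abs=1e-12)
        # re-adjusting never shrinks any value
        readjusted = bh_adjust(adjusted)
        assert all(r >= a - 1e-12 for r, a in zip(readjusted, adjusted))


class TestSubstrateEnrichment:
    def test_extreme_table_minimal_p(self):
        hits = {f"H{i}" for i in range(10)}
        background = hits | {f"B{i}" for i in range(40)}
        record = substrate_enrichment(hits, set(hits), background)
        assert record.p_raw == pytest.approx(
            fisher_by_enumeration(10, 0, 0, 40), rel=1e-9
        )
        assert record.odds_ratio == math.inf

    def test_null_behaviour_large_p(self):
        rng = np.random.default_rng(5)
        background = {f"P{i}" for i in range(200)}
        predicted = set(rng.choice(sorted(background), 50, replace=False))
        p_values = []
        for _ in range(30):
            hits = set(rng.choice(sorted(background), 30, replace=False))
            p_values.append(
                substrate_enrichment(hits, predicted, background).p_raw
            )
        assert np.mean(p_values) > 0.3

    def test_hit_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside the background"):
            substrate_enrichment({"X"}, set(), {"A", "B"})


class TestReduceToSlim:
    def test_slim_term_maps_to_itself(self):
        reduced = reduce_to_slim({"P1": {"S"}}, {}, {"S"})
        assert reduced == {"P1": {"S"}}

    def test_child_collapses_through_closure(self):
        # grandchild -> child -> S, only S is slim
        ancestors = {"grandchild": {"child"}, "child": {"S"}}
        reduced = reduce_to_slim({"P1": {"grandchild"}}, ancestors, {"S"})
        assert reduced == {"P1": {"S"}}

    def test_term_without_slim_ancestor_drops(self):
        reduced = reduce_to_slim({"P1": {"t"}}, {"t": {"u"}}, {"S"})
        assert reduced == {"P1": set()}

    def test_unknown_term_warns_and_passes_if_slim(self, caplog):
        with caplog.at_level("WARNING"):
            reduced = reduce_to_slim({"P1": {"S", "mystery"}}, {"S": set()}, {"S"})
        assert reduced == {"P1": {"S"}}
        assert any("mystery" in r.message for r in caplog.records)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            reduce_to_slim({"P1": {"a"}}, {"a": {"b"}, "b": {"a"}}, {"a"})


class TestTermEnrichment:
    def test_hit_set_equal_background_all_p_one(self):
        background = {f"P{i}" for i in range(10)}
        assignments = {p: {"T1"} for p in background}
        records = term_enrichment(set(background), assignments, background)
        assert all(r.p_raw == 1.0 for r in records)

    def test_private_term_is_significant(self):
        hits = {f"H{i}" for i in range(10)}
        others = {f"O{i}" for i in range(10)}
        background = hits | others
        assignments = {p: {"private"} for p in hits}
        assignments.update({p: {"shared"} for p in others})
        for p in hits:
            assignments[p].add("shared")
        records = term_enrichment(hits, assignments, background)
        by_term = {r.term_id: r for r in records}
        assert by_term["private"].p_adjusted < 0.05
        assert by_term["private"].p_raw == pytest.approx(
            fisher_by_enumeration(10, 0, 0, 10), rel=1e-9
        )

    def test_terms_without_hit_members_not_tested(self):
        background = {"A", "B", "C", "D"}
        assignments = {"A": {"T1"}, "B": {"T2"}, "C": {"T2"}, "D": {"T2"}}
        records = term_enrichment({"A"}, assignments, background)
        assert [r.term_id for r in records] == ["T1"]

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(set(), {}, set())

    def test_null_fdr_controlled(self):
        """Uniform random hit sets: adjusted-significant fraction <= alpha."""
        rng = np.random.default_rng(17)
        background = [f"P{i}" for i in range(400)]
        n_terms = 40
        assignments = {
            p: {f"T{t}" for t in rng.choice(n_terms, 4, replace=False)}
            for p in background
        }
        false_discoveries = total_terms = 0
        for _ in range(25):
            hits = set(rng.choice(background, 60, replace=False))
            records = term_enrichment(hits, assignments, set(background))
            total_terms += len(records)
            false_discoveries += sum(r.p_adjusted < 0.05 for r in records)
        assert false_discoveries / total_terms <= 0.05 + 3 * math.sqrt(
            0.05 * 0.95 / total_terms
        )
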