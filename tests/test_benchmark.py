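"""Agreement statistics, the IR index, and rarefaction."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from preyassign.benchmark import (
    DEFAULT_RANK_WEIGHTS,
    agreement_from_counts,
    agreement_with_consensus,
    compare_ir,
    ir_from_scores,
    ir_index,
    ir_scores,
    pairwise_agreement,
    rarefaction_curve,
    rarefaction_expected,
)
from preyassign.consensus import ConsensusAssignment
from preyassign.similarity_assign import Assignment


def cons(taxon, seq, ds="d1"):
    if taxon is None:
        return ConsensusAssignment(seq, ds, None)
    return ConsensusAssignment(seq, ds, taxon, "species", ("SAP", "MAP"))


class TestAgreement:
    def test_percent_at_two_decimals(self):
        assert agreement_from_counts(137, 138) == 99.28
        assert agreement_from_counts(125, 138) == 90.58
        assert agreement_from_counts(62, 138) == 44.93
        assert agreement_from_counts(48, 138) == 34.78

    def test_zero_matches(self):
        consensus = [cons("a", "s1"), cons("b", "s2")]
        k, pct = agreement_with_consensus({"s1": "x", "s2": None}, consensus)
        assert (k, pct) == (0, 0.0)

    def test_empty_consensus_is_na(self):
        assert agreement_with_consensus({"s1": "a"}, [cons(None, "s1")]) == (0, None)

    def test_only_consensus_sequences_enter_denominator(self):
        consensus = [cons("a", "s1"), cons(None, "s2"), cons("b", "s3")]
        calls = {"s1": "a", "s2": "a", "s3": "z"}
        k, pct = agreement_with_consensus(calls, consensus)
        assert (k, pct) == (1, 50.0)

    def test_matches_join_oracle(self, rng):
        taxa = ["a", "b", "c", None]
        seqs = [f"s{i}" for i in range(60)]
        consensus = [cons(taxa[int(rng.integers(3))], s) for s in seqs[:40]]
        consensus += [cons(None, s) for s in seqs[40:]]
        calls = {s: taxa[int(rng.integers(4))] for s in seqs}
        k, pct = agreement_with_consensus(calls, consensus)
        expected = sum(
            1 for c in consensus if c.assigned and calls[c.sequence_id] == c.taxon_id
        )
        assert k == expected
        denom = sum(1 for c in consensus if c.assigned)
        assert pct == pytest.approx(100.0 * expected / denom, abs=0.005)


class TestPairwiseAgreement:
    def test_method_against_itself_with_complete_calls_is_100(self):
        calls = {"s1": "a", "s2": "b"}
        got = pairwise_agreement({"m1": calls}, ["s1", "s2"])
        assert got[("m1", "m1")] == 100

    def test_disjoint_assignments_give_zero(self):
        got = pairwise_agreement(
            {"m1": {"s1": "a"}, "m2": {"s2": "b"}}, ["s1", "s2"]
        )
        assert got[("m1", "m2")] == 0

    def test_absent_assignment_counts_as_disagreement(self):
        # m1 covers both; m2 covers one: 1 agreement of 2 sequences
        got = pairwise_agreement(
            {"m1": {"s1": "a", "s2": "b"}, "m2": {"s1": "a"}}, ["s1", "s2"]
        )
        assert got[("m1", "m2")] == 50

    def test_symmetric_and_matches_brute_force(self, rng):
        taxa = ["a", "b", None]
        seqs = [f"s{i}" for i in range(30)]
        methods = {
            m: {s: taxa[int(rng.integers(3))] for s in seqs} for m in ("m1", "m2", "m3")
        }
        got = pairwise_agreement(methods, seqs)
        for m1, m2 in itertools.combinations(methods, 2):
            assert got[(m1, m2)] == got[(m2, m1)]
            brute = sum(
                1
                for s in seqs
                if methods[m1][s] is not None and methods[m1][s] == methods[m2][s]
            )
            assert got[(m1, m2)] == pytest.approx(round(100 * brute / 30))


class TestIRIndex:
    def test_all_species_mean_five_se_zero(self, mini_taxonomy):
        assignments = [
            Assignment(f"s{i}", "MAP", "c_bergi", rank="species") for i in range(10)
        ]
        got = ir_index(assignments, mini_taxonomy)
        assert got.mean == 5.0 and got.se == 0.0

    def test_two_items_arithmetic(self):
        got = ir_from_scores([5.0, 3.0])
        assert got.mean == 4.0
        assert got.sd == pytest.approx(math.sqrt(2))
        assert got.se == pytest.approx(1.0)

    def test_study_rank_totals_reproduce_consensus_ir(self):
        """The published consensus rank profile (47 species, 6 genus, 28
        family, 6 superfamily, 47 order, 2 class, 2 phylum) under the
        default weights gives a mean IR of 3.30."""
        totals = {
            "species": 47, "genus": 6, "family": 28, "superfamily": 6,
            "order": 47, "class": 2, "phylum": 2,
        }
        scores = [
            DEFAULT_RANK_WEIGHTS[r] for r, n in totals.items() for _ in range(n)
        ]
        got = ir_from_scores(scores)
        assert got.mean == pytest.approx(3.30, abs=0.01)

    def test_unranked_taxon_takes_nearest_canonical_weight(self, mini_taxonomy):
        assignments = [Assignment("s1", "LCA", "laniatores", rank="no rank")]
        assert ir_scores(assignments, mini_taxonomy) == [DEFAULT_RANK_WEIGHTS["order"]]

    def test_taxon_without_canonical_ancestor_raises(self, mini_taxonomy):
        assignments = [Assignment("s1", "LCA", "metazoa", rank="no rank")]
        with pytest.raises(ValueError, match="no weighted rank"):
            ir_scores(assignments, mini_taxonomy)

    def test_unassigned_items_excluded(self, mini_taxonomy):
        assignments = [
            Assignment("s1", "LCA", "c_bergi", rank="species"),
            Assignment("s2", "LCA", None),
        ]
        assert len(ir_scores(assignments, mini_taxonomy)) == 1

    def test_mean_bounded_by_weights_and_permutation_invariant(self, rng):
        w = list(DEFAULT_RANK_WEIGHTS.values())
        scores = [w[int(i)] for i in rng.integers(len(w), size=30)]
        got = ir_from_scores(scores)
        assert min(w) <= got.mean <= max(w)
        assert ir_from_scores(scores[::-1]).mean == got.mean

    def test_non_decreasing_weights_rejected(self, mini_taxonomy):
        bad = dict(DEFAULT_RANK_WEIGHTS, genus=5.0)
        with pytest.raises(ValueError, match="decrease"):
            ir_scores(
                [Assignment("s1", "LCA", "c_bergi", rank="species")],
                mini_taxonomy,
                bad,
            )


class TestCompareIR:
    def test_identical_vectors_p_near_one(self):
        _, p = compare_ir([3.0, 4.0, 5.0] * 5, [3.0, 4.0, 5.0] * 5)
        assert p > 0.9

    def test_separated_vectors_extreme_u(self):
        u, p = compare_ir([1.0] * 8, [9.0] * 8)
        assert u in (0.0, 64.0)
        assert p < 0.01

    def test_matches_reference_routine(self, rng):
        a = list(rng.normal(3, 1, size=20))
        b = list(rng.normal(4, 1, size=25))
        u, p = compare_ir(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided")
        assert (u, p) == (ref.statistic, ref.pvalue)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            compare_ir([], [1.0])


def exhaustive_expected_richness(labels, n):
    """Oracle: average distinct labels over every size-n subset."""
    subsets = list(itertools.combinations(range(len(labels)), n))
    return sum(len({labels[i] for i in s}) for s in subsets) / len(subsets)


class TestRarefaction:
    def test_single_order_curve_is_flat_one(self):
        labels = ["ord1"] * 12
        curve = rarefaction_curve(labels, range(1, 13))
        assert all(e == pytest.approx(1.0) for _, e in curve)

    def test_full_sample_returns_observed_richness(self):
        labels = ["a"] * 3 + ["b"] * 2 + ["c"] * 5
        assert rarefaction_expected(Counter(labels).values(), 10) == pytest.approx(3.0)

    def test_first_individual_is_one_category(self):
        assert rarefaction_expected([4, 3, 1], 1) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "labels",
        [
            ["a", "a", "b", "c", "c", "c"],
            ["a", "b", "c", "d", "e", "f", "g", "h"],
            ["a"] * 7 + ["b"],
            ["a", "a", "b", "b", "c", "c", "d", "d"],
        ],
    )
    def test_matches_exhaustive_subset_enumeration(self, labels):
        counts = list(Counter(labels).values())
        for n in range(1, len(labels) + 1):
            assert rarefaction_expected(counts, n) == pytest.approx(
                exhaustive_expected_richness(labels, n)
            )

    def test_curve_non_decreasing_and_concave(self, rng):
        labels = [f"o{int(i)}" for i in rng.integers(6, size=40)]
        curve = [e for _, e in rarefaction_curve(labels, range(1, 41))]
        diffs = [b - a for a, b in zip(curve, curve[1:])]
        assert all(d >= -1e-9 for d in diffs)
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(diffs, diffs[1:]))

    def test_extrapolation_is_seeded_and_plausible(self):
        labels = ["a"] * 5 + ["b"] * 4 + ["c"]
        c1 = rarefaction_curve(labels, [15, 20], seed=7)
        c2 = rarefaction_curve(labels, [15, 20], seed=7)
        assert c1 == c2
        observed = 3
        for _, e in c1:
            assert observed - 0.3 <= e <= observed

    def test_subsample_larger_than_sample_needs_extrapolation(self):
        with pytest.raises(ValueError):
            rarefaction_expected([2, 2], 5)
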