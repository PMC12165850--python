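"""Shared-motif counting, ranking construction and Kendall tau statistics."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ippoint.chain_io import GenomicInterval
from ippoint.simulate import simulate_motif_pairs
from ippoint.tfbs import (
    KendallResult,
    MotifHit,
    RankingError,
    RankingSet,
    cohens_d,
    count_shared_motifs,
    dedupe_same_motif_hits,
    filter_cross_motif_overlaps,
    kendall_pipeline,
    normalized_kendall_min,
    prepare_ranking,
)


def _hit(motif, start, end, score, chrom="cre"):
    return MotifHit(motif, GenomicInterval(chrom, start, end), score)


def _ranking_from_order(order):
    """RankingSet from an explicit motif order (no recurrences)."""
    return RankingSet((tuple(order),))


def brute_kendall_min(order_a, order_b):
    """Independent K_d: count discordant pairs directly, min over orientations."""
    n = len(order_a)
    denom = n * (n - 1) / 2

    def disc(a, b):
        pos = {m: i for i, m in enumerate(b)}
        return sum(
            1
            for i, j in itertools.combinations(range(n), 2)
            if pos[a[i]] > pos[a[j]]
        )

    return min(disc(order_a, order_b), disc(order_a, order_b[::-1])) / denom


class TestDedupe:
    def test_overlapping_same_motif_keeps_higher_score(self):
        hits = [_hit("GATA", 10, 20, 8.1), _hit("GATA", 15, 25, 6.5)]
        kept = dedupe_same_motif_hits(hits)
        assert [h.score for h in kept] == [8.1]

    def test_non_overlapping_same_motif_both_kept(self):
        hits = [_hit("GATA", 10, 20, 8.1), _hit("GATA", 30, 40, 6.5)]
        assert len(dedupe_same_motif_hits(hits)) == 2

    def test_chain_of_three_keeps_only_top(self):
        # mutually overlapping chain: greedy keeps only the score-7 hit
        hits = [_hit("A", 0, 12, 5.0), _hit("A", 8, 20, 6.0), _hit("A", 10, 22, 7.0)]
        kept = dedupe_same_motif_hits(hits)
        assert [h.score for h in kept] == [7.0]

    def test_different_motifs_untouched(self):
        hits = [_hit("A", 10, 20, 5.0), _hit("B", 12, 22, 9.0)]
        assert len(dedupe_same_motif_hits(hits)) == 2


class TestSharedMotifs:
    def test_identical_lists(self):
        hits = [_hit("A", 0, 10, 5), _hit("B", 20, 30, 5)]
        _, n = count_shared_motifs(hits, hits)
        assert n == 2

    def test_disjoint_sets(self):
        _, n = count_shared_motifs([_hit("A", 0, 10, 5)], [_hit("B", 0, 10, 5)])
        assert n == 0

    def test_per_motif_min_rule(self):
        a = [_hit("GATA", 0, 10, 5), _hit("GATA", 20, 30, 5), _hit("TEAD", 40, 50, 5)]
        b = [_hit("GATA", 0, 10, 5), _hit("MEF2", 20, 30, 5)]
        shared, n = count_shared_motifs(a, b)
        assert dict(shared) == {"GATA": 1} and n == 1

    def test_bounded_by_smaller_list(self):
        a = [_hit("A", i * 20, i * 20 + 10, 5) for i in range(5)]
        b = [_hit("A", 0, 10, 5)]
        _, n = count_shared_motifs(a, b)
        assert n <= min(len(a), len(b))


class TestPrepareRanking:
    def test_noncontiguous_recurrence_expands_rows(self):
        # order A,B,C,A,D -> rows {A,B,C,D} and {B,C,A,D}
        hits = [
            _hit("A", 0, 10, 5), _hit("B", 20, 30, 5), _hit("C", 40, 50, 5),
            _hit("A", 60, 70, 5), _hit("D", 80, 90, 5),
        ]
        ranking = prepare_ranking(hits)
        assert set(ranking.rows) == {("A", "B", "C", "D"), ("B", "C", "A", "D")}

    def test_contiguous_run_collapses(self):
        hits = [_hit("A", 0, 10, 5), _hit("A", 20, 30, 5), _hit("B", 40, 50, 5)]
        ranking = prepare_ranking(hits)
        assert ranking.rows == (("A", "B"),)

    def test_cross_motif_overlap_resolved_by_score(self):
        # 9 bp overlap >= the 8 bp minimum: only the 7.0 hit enters
        hits = [_hit("A", 0, 12, 4.0), _hit("B", 3, 15, 7.0), _hit("C", 30, 40, 5.0)]
        ranking = prepare_ranking(hits)
        assert ranking.rows == (("B", "C"),)

    def test_overlap_below_8bp_tolerated(self):
        hits = [_hit("A", 0, 12, 4.0), _hit("B", 5, 17, 7.0)]
        kept = filter_cross_motif_overlaps(hits)
        assert len(kept) == 2

    def test_filter_is_idempotent(self):
        hits = [
            _hit("A", 0, 12, 4.0), _hit("B", 3, 15, 7.0), _hit("C", 10, 22, 6.0),
            _hit("D", 40, 52, 5.0),
        ]
        once = filter_cross_motif_overlaps(hits)
        assert filter_cross_motif_overlaps(once) == once

    def test_fewer_than_two_motifs_rejected(self):
        with pytest.raises(RankingError):
            prepare_ranking([_hit("A", 0, 10, 5)])


class TestKendall:
    def test_identity_is_zero(self):
        r = _ranking_from_order("ABC")
        assert normalized_kendall_min(r, r).k_d == 0

    def test_full_reversal_is_zero_via_reverse_orientation(self):
        a = _ranking_from_order("ABCD")
        b = _ranking_from_order("DCBA")
        res = normalized_kendall_min(a, b)
        assert res.k_d == 0 and res.orientation == "reverse"

    def test_single_swap(self):
        a = _ranking_from_order("ABC")
        b = _ranking_from_order("BAC")
        res = normalized_kendall_min(a, b)
        assert res.k_d == pytest.approx(1 / 3)
        assert res.orientation == "forward"

    def test_mismatched_motif_sets_error(self):
        with pytest.raises(ValueError, match="different motif sets"):
            normalized_kendall_min(_ranking_from_order("ABC"),
                                   _ranking_from_order("ABD"))

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_brute_force_equivalence_all_permutations(self, n):
        letters = "ABCDEF"[:n]
        identity = _ranking_from_order(letters)
        for perm in itertools.permutations(letters):
            res = normalized_kendall_min(identity, _ranking_from_order(perm))
            assert res.k_d == pytest.approx(brute_kendall_min(tuple(letters), perm))

    def test_min_over_rank_matrix_rows(self):
        # second list recurs A noncontiguously; the min over its two rows
        # must be <= the K_d of each row alone
        a = _ranking_from_order("ABCD")
        b = RankingSet((("A", "B", "C", "D"), ("B", "C", "A", "D")))
        res = normalized_kendall_min(a, b)
        per_row = [
            normalized_kendall_min(a, RankingSet((row,))).k_d for row in b.rows
        ]
        assert res.k_d == min(per_row) == 0

    @settings(max_examples=200, derandomize=True)
    @given(st.permutations(list("ABCDE")))
    def test_min_never_exceeds_either_orientation(self, perm):
        a = tuple("ABCDE")
        res = normalized_kendall_min(_ranking_from_order(a),
                                     _ranking_from_order(perm))
        n = 5
        denom = n * (n - 1) / 2

        def disc(order):
            pos = {m: i for i, m in enumerate(order)}
            return sum(1 for i, j in itertools.combinations(range(n), 2)
                       if pos[a[i]] > pos[a[j]]) / denom

        assert res.k_d <= disc(perm)
        assert res.k_d <= disc(perm[::-1])


class TestCohensD:
    def test_identical_samples(self):
        d, label = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0 and label == "small"

    def test_closed_form_example(self):
        d, _ = cohens_d([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "shift,expected", [(0.15, "small"), (0.2, "medium"), (0.35, "medium"),
                           (0.5, "medium"), (0.8, "large")]
    )
    def test_magnitude_labels(self, shift, expected):
        # x has sample SD exactly 5; shifting by 5*shift gives |d| == shift
        x = [0, 5, 10]
        y = [v + 5 * shift for v in x]
        d, label = cohens_d(x, y)
        assert abs(d) == pytest.approx(shift)
        assert label == expected

    def test_zero_pooled_sd_unequal_means_errors(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestPipeline:
    def _pairs_from_sim(self, cls_t):
        pairs = []
        for cls, t, seed in cls_t:
            for sim_pair in simulate_motif_pairs(2, n_motifs=6,
                                                 t_transpositions=t, seed=seed):
                pairs.append((f"{cls}_{seed}_{sim_pair.pair_id}", cls,
                              list(sim_pair.hits_a), list(sim_pair.hits_b)))
        return pairs

    def test_shuffled_pairs_score_higher(self):
        pairs = self._pairs_from_sim([("DC", 0, 1), ("NC", 3, 2)])
        results, summary = kendall_pipeline(pairs, min_shared=6)
        med = summary.set_index("class")["median_k_d"]
        assert med["DC"] < med["NC"]

    def test_below_min_shared_excluded(self):
        pairs = self._pairs_from_sim([("DC", 0, 3)])
        # 6 motifs < min_shared=7 -> all dropped
        results, _ = kendall_pipeline(pairs, min_shared=7)
        assert len(results) == 0 and results.attrs["n_dropped"] == 2

    def test_identical_lists_all_zero(self):
        hits = [_hit(m, i * 30, i * 30 + 10, 5.0)
                for i, m in enumerate("ABCDEF")]
        pairs = [("p1", "DC", hits, hits), ("p2", "IC", hits, hits)]
        results, summary = kendall_pipeline(pairs, min_shared=6)
        assert (results["k_d"] == 0).all()

    def test_empty_class_reported_not_crash(self):
        pairs = self._pairs_from_sim([("DC", 0, 4)])
        _, summary = kendall_pipeline(pairs, min_shared=6)
        row = summary.set_index("class").loc["NC"]
        assert row["n"] == 0 and math.isnan(row["median_k_d"])


class TestTranspositionRecovery:
    @pytest.mark.parametrize("t", [0, 1, 2, 3])
    def test_forward_kd_equals_t_over_denominator(self, t):
        n = 6
        for pair in simulate_motif_pairs(5, n_motifs=n, t_transpositions=t,
                                         seed=100 + t):
            order_a = [h.motif_id for h in pair.hits_a]
            order_b = [h.motif_id for h in pair.hits_b]
            pos = {m: i for i, m in enumerate(order_b)}
            disc = sum(1 for i, j in itertools.combinations(range(n), 2)
                       if pos[order_a[i]] > pos[order_a[j]])
            assert disc == t

    def test_flip_with_zero_transpositions_scores_zero(self):
        for pair in simulate_motif_pairs(5, n_motifs=6, t_transpositions=0,
                                         orientation_flip_prob=1.0, seed=9):
            assert pair.flipped
            ra = prepare_ranking(list(pair.hits_a))
            rb = prepare_ranking(list(pair.hits_b))
            assert normalized_kendall_min(ra, rb).k_d == 0
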