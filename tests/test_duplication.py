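"""Homology, collinear-block chaining (against a brute-force oracle), the
MCScanX-style duplicate classifier, and interspecies synteny."""

from __future__ import annotations


import numpy as np
import pytest

from abcsurvey import duplication as dup
from abcsurvey.duplication import (
    Anchor,
    HomologPair,
    classify_duplicates,
    detect_collinear_blocks,
    interspecies_synteny,
    pairwise_homology,
    pairs_to_anchors,
)
from abcsurvey.genome import Genome, GeneModel


def _gene(gid, chrom, rank):
    start = 1000 * rank + 100
    return GeneModel(
        gene_id=gid, chromosome=chrom, strand="+", start=start, end=start + 500,
        exons=((start, start + 500),), cds_segments=((start, start + 500),),
    )


def _linear_genome(n, chrom="chr1", prefix="g"):
    return Genome({f"{prefix}{i}": _gene(f"{prefix}{i}", chrom, i) for i in range(n)})


def _diag_anchors(pairs):
    return [
        Anchor(f"a{ra}", f"b{rb}", "c1", "c2", ra, rb) for ra, rb in pairs
    ]


class TestHomology:
    def test_identical_pair_scores_full_identity_rank_one(self):
        pairs = pairwise_homology({"a": "MKVLAWGKEV" * 8, "b": "MKVLAWGKEV" * 8})
        assert len(pairs) == 1
        assert pairs[0].identity_pct == pytest.approx(100.0)
        assert pairs[0].rank == 1

    def test_three_member_family_links_all_members(self):
        seq = "MKVLAWGKEVHAPSTNDQRC" * 6
        pairs = pairwise_homology({"a": seq, "b": seq, "c": seq})
        assert len(pairs) == 3  # every unordered pair

    def test_planted_families_never_pair_with_background(
        self, sim_genome, survey_candidates, duplication_run
    ):
        planted = set(sim_genome.truth["gene_id"])
        for p in duplication_run["pairs"]:
            assert p.gene_a in planted and p.gene_b in planted


class TestBlockChaining:
    def test_perfect_diagonal_of_five_is_one_block(self):
        anchors = _diag_anchors([(i, i) for i in range(1, 6)])
        blocks = detect_collinear_blocks(anchors, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].score == 5
        assert blocks[0].orientation == "same"

    def test_four_anchors_stay_below_threshold(self):
        anchors = _diag_anchors([(i, i) for i in range(1, 5)])
        assert detect_collinear_blocks(anchors, min_anchors=5) == []

    def test_inverted_diagonal_detected_with_inverted_orientation(self):
        anchors = _diag_anchors([(i, 10 - i) for i in range(1, 7)])
        blocks = detect_collinear_blocks(anchors, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_gap_constraint_breaks_distant_anchors_apart(self):
        anchors = _diag_anchors(
            [(i, i) for i in range(1, 6)] + [(i, i) for i in range(100, 105)]
        )
        blocks = detect_collinear_blocks(anchors, min_anchors=5, max_gap=25)
        assert len(blocks) == 2

    @staticmethod
    def _brute_force_best_chain(anchors, max_gap):
        """Exhaustive DFS over all monotone chains (both orientations)."""
        best = 0
        n = len(anchors)

        def extend(last_idx, length, direction):
            nonlocal best
            best = max(best, length)
            la = anchors[last_idx]
            for k in range(n):
                a = anchors[k]
                gap_a = a.rank_a - la.rank_a
                gap_b = direction * (a.rank_b - la.rank_b)
                if 0 < gap_a <= max_gap and 0 < gap_b <= max_gap:
                    extend(k, length + 1, direction)

        for direction in (+1, -1):
            for start in range(n):
                extend(start, 1, direction)
        return best

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_chain_length_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(3000 + seed)
        ranks_a = rng.permutation(14)
        ranks_b = rng.permutation(14)
        anchors = _diag_anchors(list(zip(ranks_a.tolist(), ranks_b.tolist())))
        expected = self._brute_force_best_chain(anchors, max_gap=6)
        got_same = len(dup._best_chain(anchors, 6, +1))
        got_inv = len(dup._best_chain(anchors, 6, -1))
        assert max(got_same, got_inv) == expected

    def test_dp_on_30_anchor_permutations_matches_memoized_recursion(self):
        rng = np.random.default_rng(5150)
        from functools import lru_cache

        for _ in range(5):
            perm = rng.permutation(30)
            anchors = _diag_anchors([(i, int(perm[i])) for i in range(30)])

            def best_from(idx, direction, anchors=anchors):
                @lru_cache(maxsize=None)
                def rec(i):
                    out = 1
                    ai = anchors[i]
                    for j in range(len(anchors)):
                        aj = anchors[j]
                        ga = aj.rank_a - ai.rank_a
                        gb = direction * (aj.rank_b - ai.rank_b)
                        if 0 < ga <= 25 and 0 < gb <= 25:
                            out = max(out, 1 + rec(j))
                    return out

                return rec(idx)

            expected = max(
                best_from(i, d) for i in range(30) for d in (+1, -1)
            )
            got = max(
                len(dup._best_chain(anchors, 25, +1)),
                len(dup._best_chain(anchors, 25, -1)),
            )
            assert got == expected


class TestClassification:
    def _pair(self, a, b):
        return HomologPair(min(a, b), max(a, b), 100.0, 95.0, 1)

    def test_adjacent_homologs_outside_blocks_are_tandem(self):
        genome = _linear_genome(10)
        pairs = [self._pair("g3", "g4")]
        calls, counts = classify_duplicates(genome.genes, genome, pairs, [])
        by = {c.gene_id: c.dup_type for c in calls}
        assert by["g3"] == by["g4"] == "tandem"
        assert counts["tandem"] == 2

    def test_homologs_eight_ranks_apart_are_proximal(self):
        genome = _linear_genome(12)
        pairs = [self._pair("g1", "g9")]
        calls, _ = classify_duplicates(
            genome.genes, genome, pairs, [], proximal_window=10
        )
        by = {c.gene_id: c.dup_type for c in calls}
        assert by["g1"] == by["g9"] == "proximal"

    def test_cross_chromosome_homolog_without_block_is_dispersed(self):
        genes = {
            "a": _gene("a", "chr1", 0),
            "b": _gene("b", "chr2", 0),
        }
        genome = Genome(genes)
        calls, _ = classify_duplicates(
            genome.genes, genome, [self._pair("a", "b")], []
        )
        assert all(c.dup_type == "dispersed" for c in calls)

    def test_block_membership_takes_precedence_over_adjacency(self):
        genome = _linear_genome(20)
        pairs = [self._pair(f"g{i}", f"g{i+10}") for i in range(5)]
        anchors = pairs_to_anchors(pairs, genome)
        blocks = detect_collinear_blocks(anchors, min_anchors=5)
        assert blocks, "expected a same-chromosome collinear block"
        calls, counts = classify_duplicates(genome.genes, genome, pairs, blocks)
        by = {c.gene_id: c.dup_type for c in calls}
        for i in range(5):
            assert by[f"g{i}"] == by[f"g{i+10}"] == "wgd_segmental"
        assert counts["wgd_segmental"] == 10

    def test_gene_without_homolog_is_singleton(self):
        genome = _linear_genome(3)
        calls, counts = classify_duplicates(genome.genes, genome, [], [])
        assert counts["singleton"] == 3

    def test_types_partition_the_gene_set(self, sim_genome, survey_candidates, duplication_run):
        counts = duplication_run["counts"]
        assert sum(counts.values()) == len(survey_candidates["candidates"])

    def test_planted_mix_recovered_exactly(self, sim_genome, duplication_run):
        """Ground-truth closure: every planted duplication type is recovered
        with 100% accuracy on the noise-free synthetic genome."""
        truth = dict(zip(sim_genome.truth["gene_id"], sim_genome.truth["true_type"]))
        for call in duplication_run["calls"]:
            if call.gene_id in truth:
                assert call.dup_type == truth[call.gene_id], call
        expected_counts = sim_genome.truth["true_type"].value_counts().to_dict()
        got = {k: v for k, v in duplication_run["counts"].items() if v}
        assert got == expected_counts

    def test_classification_invariant_to_pair_order_and_swap(self):
        genome = _linear_genome(12)
        pairs = [self._pair("g1", "g2"), self._pair("g4", "g9")]
        calls_fwd, _ = classify_duplicates(genome.genes, genome, pairs, [])
        calls_rev, _ = classify_duplicates(genome.genes, genome, pairs[::-1], [])
        assert calls_fwd == calls_rev

    def test_unknown_gene_in_pair_raises(self):
        genome = _linear_genome(3)
        with pytest.raises(ValueError, match="ghost"):
            classify_duplicates(genome.genes, genome, [self._pair("g1", "ghost")], [])


class TestInterspeciesSynteny:
    def _two_genomes(self, shuffle_b=False, drop_second_copy=False):
        rng = np.random.default_rng(8)
        seqs = {}
        alphabet = list("ACDEGHKMNPQRSTWY")
        for i in range(8):
            seqs[i] = "".join(rng.choice(alphabet, size=120))
        order_a = list(range(8))
        order_b = list(range(8))
        if shuffle_b:
            order_b = [5, 2, 7, 0, 3, 6, 1, 4]
        genome_a = Genome(
            {f"a{i}": _gene(f"a{i}", "chr1", r) for r, i in enumerate(order_a)}
        )
        genome_b = Genome(
            {f"b{i}": _gene(f"b{i}", "chrX", r) for r, i in enumerate(order_b)}
        )
        prot_a = {f"a{i}": seqs[i] for i in range(8)}
        prot_b = {f"b{i}": seqs[i] for i in range(8)}
        return genome_a, genome_b, prot_a, prot_b

    def test_identical_genomes_give_one_to_one_family_pairs(self):
        ga, gb, pa, pb = self._two_genomes()
        result = interspecies_synteny(
            ga, gb, pa, pb, family_a=set(pa), family_b=set(pb)
        )
        assert result["blocks"]
        card = result["cardinality"]
        assert len(card) == 8
        assert set(card["cardinality"]) == {"one_to_one"}

    def test_shuffled_gene_order_destroys_collinearity(self):
        ga, gb, pa, pb = self._two_genomes(shuffle_b=True)
        result = interspecies_synteny(
            ga, gb, pa, pb, family_a=set(pa), family_b=set(pb)
        )
        assert result["blocks"] == []

    def test_duplicated_region_in_one_genome_yields_many_to_one(self):
        """Genome A carries the syntenic region twice (a WGD remnant), so
        each genome-B gene anchors two blocks: every pair is many-to-one."""
        ga, gb, pa, pb = self._two_genomes()
        genes = {g.gene_id: g for g in ga.genes.values()}
        pa = dict(pa)
        for i in range(8):
            genes[f"c{i}"] = _gene(f"c{i}", "chr1", 20 + i)
            pa[f"c{i}"] = pa[f"a{i}"]
        ga = Genome(genes)
        result = interspecies_synteny(
            ga, gb, pa, pb, family_a=set(pa), family_b=set(pb)
        )
        assert len(result["blocks"]) == 2
        card = result["cardinality"]
        assert set(card["cardinality"]) == {"many_to_one"}
        assert len(card) == 16
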