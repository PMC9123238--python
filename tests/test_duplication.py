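"""Collinear-block chaining, duplicate classification and the chi-squared test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from hsfkit.duplication import (
    DUP_CLASSES,
    CollinearBlock,
    GenePosition,
    HomologPair,
    chain_collinear_blocks,
    class_count_table,
    classify_duplicates,
    type_enrichment_chi2,
)


def diagonal_pairs(n, start_a=1, start_b=11, chrom_a="c1", chrom_b="c2", prefix=""):
    pos, pairs = [], []
    for i in range(n):
        ga, gb = f"{prefix}a{i}", f"{prefix}b{i}"
        pos.append(GenePosition(ga, chrom_a, start_a + i))
        pos.append(GenePosition(gb, chrom_b, start_b + i))
        pairs.append(HomologPair(ga, gb))
    return pairs, pos


def pad_positions(pos, chrom, upto):
    have = {p.rank for p in pos if p.chrom == chrom}
    out = list(pos)
    for r in range(1, upto + 1):
        if r not in have:
            out.append(GenePosition(f"fill_{chrom}_{r}", chrom, r))
    return out


def brute_force_max_chain(anchors, max_gap):
    """Largest valid monotone chain over <= 2^n anchor subsets (oracle)."""
    best: tuple = ()
    for r in range(len(anchors), 0, -1):
        for subset in itertools.combinations(sorted(anchors), r):
            for sign in (1, -1):
                ok = all(
                    0 < b[0] - a[0] <= max_gap
                    and 0 < sign * (b[1] - a[1]) <= max_gap
                    for a, b in zip(subset, subset[1:])
                )
                if ok and len(subset) > len(best):
                    best = subset
        if best:
            break
    return best


class TestChainCollinearBlocks:
    def test_perfect_diagonal_one_block(self):
        pairs, pos = diagonal_pairs(5)
        pos = pad_positions(pos, "c1", 5)
        pos = pad_positions(pos, "c2", 15)
        blocks = chain_collinear_blocks(pairs, pos)
        assert len(blocks) == 1
        assert len(blocks[0]) == 5
        assert blocks[0].orientation == "same"

    def test_below_min_pairs_no_block(self):
        pairs, pos = diagonal_pairs(4)
        pos = pad_positions(pos, "c1", 4)
        pos = pad_positions(pos, "c2", 14)
        assert chain_collinear_blocks(pairs, pos, min_pairs=5) == []

    def test_outlier_excluded_matches_brute_force(self):
        # 7 anchors: 6 on a diagonal plus one off-diagonal outlier
        ranks = [(1, 11), (2, 12), (3, 13), (4, 40), (5, 14), (6, 15), (7, 16)]
        pos, pairs, anchors = [], [], []
        for i, (ra, rb) in enumerate(ranks):
            ga, gb = f"a{i}", f"b{i}"
            pos.append(GenePosition(ga, "c1", ra))
            pos.append(GenePosition(gb, "c2", rb))
            pairs.append(HomologPair(ga, gb))
            anchors.append((ra, rb))
        pos = pad_positions(pos, "c1", 7)
        pos = pad_positions(pos, "c2", 40)
        blocks = chain_collinear_blocks(pairs, pos, min_pairs=5, max_rank_gap=25)
        assert len(blocks) == 1
        got = {(int(a[1:]), int(b[1:])) for a, b in blocks[0].anchors}
        oracle = brute_force_max_chain(anchors, 25)
        assert len(blocks[0]) == len(oracle) == 6
        assert {ranks.index(a) for a in oracle} == {
            i for i, r in enumerate(ranks) if r != (4, 40)
        }
        assert got == {(i, i) for i, r in enumerate(ranks) if r != (4, 40)}

    def test_inverted_block_detected(self):
        pos, pairs = [], []
        for i in range(5):
            ga, gb = f"a{i}", f"b{i}"
            pos.append(GenePosition(ga, "c1", 1 + i))
            pos.append(GenePosition(gb, "c2", 10 - i))
            pairs.append(HomologPair(ga, gb))
        pos = pad_positions(pos, "c1", 5)
        pos = pad_positions(pos, "c2", 10)
        blocks = chain_collinear_blocks(pairs, pos)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_gap_cap_splits_chain(self):
        pairs, pos = diagonal_pairs(5)
        pairs2, pos2 = diagonal_pairs(5, start_a=100, start_b=200, prefix="q")
        allpos = pad_positions(pos + pos2, "c1", 104)
        allpos = pad_positions(allpos, "c2", 204)
        blocks = chain_collinear_blocks(pairs + pairs2, allpos, max_rank_gap=25)
        assert sorted(len(b) for b in blocks) == [5, 5]

    def test_permutation_invariance(self, rng):
        pairs, pos = diagonal_pairs(7)
        pos = pad_positions(pos, "c1", 7)
        pos = pad_positions(pos, "c2", 17)
        base = chain_collinear_blocks(pairs, pos)
        for _ in range(10):
            shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
            assert chain_collinear_blocks(shuffled, pos) == base

    def test_missing_position_is_hard_error(self):
        with pytest.raises(KeyError, match="no position"):
            chain_collinear_blocks(
                [HomologPair("a", "b")], [GenePosition("a", "c1", 1)]
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_brute_force(self, seed):
        """Seeded random <=7-anchor instances against subset enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        ra = sorted(rng.choice(np.arange(1, 60), n, replace=False).tolist())
        rb = rng.choice(np.arange(1, 60), n, replace=False).tolist()
        anchors = list(zip(ra, rb))
        pos, pairs = [], []
        for i, (x, y) in enumerate(anchors):
            pos.append(GenePosition(f"a{i}", "c1", int(x)))
            pos.append(GenePosition(f"b{i}", "c2", int(y)))
            pairs.append(HomologPair(f"a{i}", f"b{i}"))
        pos = pad_positions(pos, "c1", 60)
        pos = pad_positions(pos, "c2", 60)
        blocks = chain_collinear_blocks(pairs, pos, min_pairs=2, max_rank_gap=10)
        oracle = brute_force_max_chain(anchors, 10)
        got_first = len(blocks[0]) if blocks else 0
        assert got_first == (len(oracle) if len(oracle) >= 2 else 0)


class TestClassifyDuplicates:
    def simple_pos(self):
        return [GenePosition(f"g{r}", "c1", r) for r in range(1, 21)]

    def test_no_homolog_is_singleton(self):
        classes = classify_duplicates({"g1"}, [], self.simple_pos(), [])
        assert classes == {"g1": "singleton"}

    def test_adjacent_homologs_both_tandem(self):
        classes = classify_duplicates(
            {"g7", "g8"}, [HomologPair("g7", "g8")], self.simple_pos(), []
        )
        assert classes == {"g7": "tandem", "g8": "tandem"}

    def test_proximal_within_gap(self):
        classes = classify_duplicates(
            {"g3", "g9"}, [HomologPair("g3", "g9")], self.simple_pos(), []
        )
        assert classes == {"g3": "proximal", "g9": "proximal"}

    def test_distant_same_chrom_dispersed(self):
        classes = classify_duplicates(
            {"g1", "g20"}, [HomologPair("g1", "g20")], self.simple_pos(), [],
            proximal_max_gap=10,
        )
        assert classes == {"g1": "dispersed", "g20": "dispersed"}

    def test_block_anchor_precedence_over_tandem(self):
        # g7 anchors a block AND is tandem-adjacent to g8; applying the
        # precedence list by hand: wgd_segmental wins
        block = CollinearBlock("c1", "c2", "same", [("g7", "x1")])
        classes = classify_duplicates(
            {"g7", "g8"},
            [HomologPair("g7", "g8")],
            self.simple_pos(),
            [block],
        )
        assert classes["g7"] == "wgd_segmental"
        assert classes["g8"] == "tandem"

    def test_classes_partition_members(self, rng):
        from hsfkit.simulate import simulate_genome_with_duplicates

        g = simulate_genome_with_duplicates(rng, n_genes=600, n_tandem=3,
                                            n_proximal=3, n_segmental_blocks=1,
                                            n_dispersed=3)
        blocks = chain_collinear_blocks(g.pairs, g.positions)
        classes = classify_duplicates(
            set(g.true_classes), g.pairs, g.positions, blocks
        )
        counts = class_count_table(classes)
        assert counts.sum() == len(g.true_classes)
        assert set(counts.index) == set(DUP_CLASSES)


class TestTypeEnrichmentChi2:
    def test_textbook_formula_oracle(self):
        # 2x2 table (8,2 / 100,900): chi2 from sum (O-E)^2/E by hand
        fam = {"wgd_segmental": 8, "dispersed": 2}
        gen = {"wgd_segmental": 100, "dispersed": 900}
        chi2, p, _ = type_enrichment_chi2(fam, gen, "wgd_segmental")
        obs = np.array([[8, 2], [100, 900]])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = ((obs - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(by_hand)
        assert p == pytest.approx(stats.chi2.sf(by_hand, 1))

    def test_identical_proportions_null(self):
        fam = {"wgd_segmental": 10, "dispersed": 90}
        gen = {"wgd_segmental": 100, "dispersed": 900}
        chi2, p, sig = type_enrichment_chi2(fam, gen, "wgd_segmental")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_wgd_share_vs_genome_proportion_significant(self):
        # family WGD share 14/25 = 56.00 % against a genome share of
        # 10.27 %: overwhelmingly significant at p < .01
        fam = {"wgd_segmental": 14, "dispersed": 11}
        chi2, p, sig = type_enrichment_chi2(
            fam, {"wgd_segmental": 0.1027}, "wgd_segmental",
            genome_is_proportions=True,
        )
        assert sig and p < 0.01

    def test_zero_expected_cell_is_hard_error(self):
        with pytest.raises(ValueError, match="exact"):
            type_enrichment_chi2(
                {"tandem": 5, "dispersed": 5},
                {"tandem": 1.0},
                "tandem",
                genome_is_proportions=True,
            )
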