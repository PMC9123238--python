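"""LCA reconciliation: worked cases, exhaustive-search optimality, aggregation."""

import itertools

import pytest

from hsfkit import reconcile
from hsfkit.reconcile import (
    aggregate_reconciliations,
    gene_tree_from_newick,
    lca_reconcile,
    species_tree_from_newick,
)

# ---------------------------------------------------------------------------
# independent oracle: enumerate every valid node mapping and take the
# minimum duplication + loss cost


def _enumerate_cost(gtree, stree, gene_species):
    """Minimum dup+loss over all reconciliations (exhaustive search)."""
    parent, depth, leaf_of = reconcile._species_index(stree)
    snodes = list(stree.preorder_node_iter())

    def ancestors_or_self(n):
        out = []
        while n is not None:
            out.append(n)
            n = parent[n]
        return out

    def dist(a, b):  # edges from ancestor a down to b
        d = 0
        while b is not a:
            b = parent[b]
            d += 1
        return d

    gnodes = list(gtree.postorder_node_iter())
    internal = [n for n in gnodes if not n.is_leaf()]
    leaf_map = {
        n: leaf_of[gene_species[n.taxon.label]] for n in gnodes if n.is_leaf()
    }
    best = [None]

    def rec(i, assign):
        if i == len(internal):
            cost = 0
            for v in internal:
                c1, c2 = v.child_nodes()
                m_v = assign[v]
                m1 = assign.get(c1, leaf_map.get(c1))
                m2 = assign.get(c2, leaf_map.get(c2))
                lca = reconcile._lca(m1, m2, parent, depth)
                dup = not (
                    m_v is lca
                    and m1 is not m_v
                    and m2 is not m_v
                )
                if dup:
                    cost += 1
                for m_c in (m1, m2):
                    d = dist(m_v, m_c)
                    cost += d if dup else max(0, d - 1)
            if best[0] is None or cost < best[0]:
                best[0] = cost
            return
        v = internal[i]
        c1, c2 = v.child_nodes()
        m1 = assign.get(c1, leaf_map.get(c1))
        m2 = assign.get(c2, leaf_map.get(c2))
        lca = reconcile._lca(m1, m2, parent, depth)
        for cand in ancestors_or_self(lca):
            assign[v] = cand
            rec(i + 1, assign)
        del assign[v]
        return

    # enumerate children before parents so child assignments exist
    internal.sort(key=lambda n: -depth_of(n))
    rec(0, {})
    return best[0]


def depth_of(node):
    d = 0
    while node.parent_node is not None:
        node = node.parent_node
        d += 1
    return d


def all_binary_topologies(leaves):
    """All rooted binary tree shapes over the given (labeled) leaf list."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(1, len(rest) + 1):
        for left_rest in itertools.combinations(rest, k - 1):
            left = [first, *left_rest]
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in all_binary_topologies(left):
                for rt in all_binary_topologies(right):
                    yield (lt, rt)


def to_newick(shape):
    if isinstance(shape, str):
        return shape
    return f"({to_newick(shape[0])},{to_newick(shape[1])})"


class TestWorkedCases:
    def test_congruent_trees_no_events(self, stree_abcd):
        gt = gene_tree_from_newick("((a,b),(c,d));")
        s = lca_reconcile(gt, stree_abcd, {"a": "A", "b": "B", "c": "C", "d": "D"})
        assert s.total_duplications == 0 and s.total_losses == 0

    def test_root_duplication_no_losses(self, stree_ab):
        gt = gene_tree_from_newick("((a1,b1),(a2,b2));")
        s = lca_reconcile(gt, stree_ab, {"a1": "A", "b1": "B", "a2": "A", "b2": "B"})
        assert s.duplications == {"node_A|B": 1}
        assert s.total_losses == 0

    def test_duplication_with_loss_on_sibling_branch(self, stree_ab):
        gt = gene_tree_from_newick("(a1,(a2,b1));")
        s = lca_reconcile(gt, stree_ab, {"a1": "A", "a2": "A", "b1": "B"})
        assert s.duplications == {"node_A|B": 1}
        assert s.losses == {"B": 1}

    def test_event_count_equals_internal_nodes(self, stree_abcd):
        gt = gene_tree_from_newick("((a,(b,c)),(c2,d));")
        s = lca_reconcile(
            gt, stree_abcd,
            {"a": "A", "b": "B", "c": "C", "c2": "C", "d": "D"},
        )
        assert len(s.events) == 4

    def test_unmappable_leaf_is_hard_error(self, stree_ab):
        gt = gene_tree_from_newick("(a1,b1);")
        with pytest.raises(KeyError):
            lca_reconcile(gt, stree_ab, {"a1": "A"})
        with pytest.raises(ValueError, match="not in species tree"):
            lca_reconcile(gt, stree_ab, {"a1": "A", "b1": "Z"})

    def test_multifurcating_gene_tree_rejected(self, stree_abc):
        with pytest.raises(ValueError, match="binary"):
            gene_tree_from_newick("(a,b,c);")

    def test_multifurcating_species_tree_accepted(self):
        st = species_tree_from_newick("(A,B,C);")
        gt = gene_tree_from_newick("(a,(b,c));")
        s = lca_reconcile(gt, st, {"a": "A", "b": "B", "c": "C"})
        assert s.total_duplications + s.total_losses >= 0  # runs cleanly


class TestParsimonyOptimality:
    @pytest.mark.parametrize("snewick", ["(A,B);", "((A,B),C);", "(A,(B,C));"])
    def test_exhaustive_minimum_small_trees(self, snewick):
        """LCA cost equals brute-force minimum for ALL gene trees with
        <= 4 leaves over every species assignment."""
        stree = species_tree_from_newick(snewick)
        species = sorted(lf.taxon.label for lf in stree.leaf_node_iter())
        for n_leaves in (2, 3, 4):
            leaf_names = [f"x{i}" for i in range(n_leaves)]
            for shape in all_binary_topologies(leaf_names):
                nwk = to_newick(shape) + ";"
                for assignment in itertools.product(species, repeat=n_leaves):
                    mapping = dict(zip(leaf_names, assignment))
                    gt = gene_tree_from_newick(nwk)
                    s = lca_reconcile(gt, stree, mapping)
                    lca_cost = s.total_duplications + s.total_losses
                    gt2 = gene_tree_from_newick(nwk)
                    assert lca_cost == _enumerate_cost(gt2, stree, mapping), (
                        snewick, nwk, mapping,
                    )

    def test_exhaustive_minimum_sampled_larger_trees(self, rng, stree_abcd):
        """Seeded sample of 5-6 leaf gene trees over a 4-species tree."""
        species = ["A", "B", "C", "D"]
        for _ in range(60):
            n_leaves = int(rng.integers(5, 7))
            leaf_names = [f"x{i}" for i in range(n_leaves)]
            shapes = list(all_binary_topologies(leaf_names))
            shape = shapes[int(rng.integers(len(shapes)))]
            mapping = {
                x: species[int(rng.integers(4))] for x in leaf_names
            }
            nwk = to_newick(shape) + ";"
            s = lca_reconcile(gene_tree_from_newick(nwk), stree_abcd, mapping)
            oracle = _enumerate_cost(
                gene_tree_from_newick(nwk), stree_abcd, mapping
            )
            assert s.total_duplications + s.total_losses == oracle

    def test_mapping_monotonicity(self, rng, stree_abcd):
        """M(parent) is ancestor-or-equal of M(child) on random gene trees."""
        from hsfkit import simulate

        res = simulate.simulate_family_evolution(
            stree_abcd, birth_rate=1.0, death_rate=0.3, rng=rng, n_families=30
        )
        for r in res:
            if r.gene_tree is None or len(r.gene_species) < 2:
                continue
            s = lca_reconcile(r.gene_tree, stree_abcd, r.gene_species)
            # ancestry is encoded in branch ids: an ancestor's leaf set
            # contains the descendant's
            def leafset(bid):
                return set(bid.split("_")[-1].split("|")) if "|" in bid else {bid}
            for key, (_ev, bid) in s.events.items():
                for other, (_e2, bid2) in s.events.items():
                    if set(other) < set(key):
                        assert leafset(bid2) <= leafset(bid)


class TestAggregate:
    def test_identity_and_addition(self, stree_ab):
        gt = gene_tree_from_newick("(a1,(a2,b1));")
        m = {"a1": "A", "a2": "A", "b1": "B"}
        s = lca_reconcile(gt, stree_ab, m)
        one = aggregate_reconciliations([s], stree_ab)
        assert one.duplications == s.duplications and one.losses == s.losses
        two = aggregate_reconciliations([s, s], stree_ab)
        assert two.duplications == {"node_A|B": 2}
        assert two.losses == {"B": 2}

    def test_sum_matches_independent_accumulation(self, rng, stree_abcd):
        from hsfkit import simulate

        res = simulate.simulate_family_evolution(
            stree_abcd, birth_rate=0.8, death_rate=0.2, rng=rng, n_families=10
        )
        summaries = [
            lca_reconcile(r.gene_tree, stree_abcd, r.gene_species)
            for r in res
            if r.gene_tree is not None and len(r.gene_species) >= 2
        ]
        agg = aggregate_reconciliations(summaries, stree_abcd)
        # independent accumulation in reversed order with plain dict math
        dups: dict = {}
        for s in reversed(summaries):
            for b, n in s.duplications.items():
                dups[b] = dups.get(b, 0) + n
        assert agg.duplications == dups

    def test_mismatched_species_tree_is_error(self, stree_ab, stree_abc):
        gt = gene_tree_from_newick("(a1,b1);")
        s = lca_reconcile(gt, stree_ab, {"a1": "A", "b1": "B"})
        with pytest.raises(ValueError, match="different species tree"):
            aggregate_reconciliations([s], stree_abc)
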