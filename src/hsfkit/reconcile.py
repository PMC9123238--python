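"""LCA-mapping reconciliation of rooted gene trees with a species tree.

Each gene-tree node v is mapped to M(v), the lowest common ancestor in the
species tree of the species below v. A node is a duplication when it maps
to the same species-tree node as one of its children; otherwise it is a
speciation. Losses are counted per gene-tree edge (u -> v) from the number
of species-tree edges d on the path M(u) -> M(v):

    losses = d - 1   if u is a speciation (the first edge is the
                     speciation itself),
    losses = d       if u is a duplication (the duplicate starts at M(u)
                     and must survive every subsequent speciation).

Each unit loss is attributed to the off-path sibling branch of the species
node the lineage passes through — e.g. with species tree (A,B) and gene
tree (a1,(a2,b1)), the copy ancestral to a1 is lost on the branch to B.
This is the most-parsimonious (minimum duplication + loss) reconciliation;
the test suite checks optimality against exhaustive search over all valid
mappings on small trees.

Species trees may be multifurcating; gene trees must be rooted and binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import pandas as pd

__all__ = [
    "ReconciliationSummary",
    "lca_reconcile",
    "aggregate_reconciliations",
    "species_tree_from_newick",
    "gene_tree_from_newick",
]


def species_tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("species tree leaf labels must be unique")
    if len(labels) < 2:
        raise ValueError("species tree needs >= 2 leaves")
    return tree


def gene_tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            raise ValueError(
                "gene tree must be strictly binary; found a node with "
                f"{len(node.child_nodes())} children"
            )
    return tree


def branch_id(node: dendropy.Node) -> str:
    """Identify the branch above ``node`` by its child-node label."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "node_" + "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


@dataclass
class ReconciliationSummary:
    """Per species-tree branch duplication and loss counts plus node events.

    ``events`` maps each internal gene-tree node (keyed by the sorted tuple
    of its leaf gene ids) to ("speciation"|"duplication", species branch).
    """

    duplications: dict[str, int] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)
    events: dict[tuple[str, ...], tuple[str, str]] = field(default_factory=dict)
    species_tree_signature: str = ""

    @property
    def total_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())

    def to_frame(self) -> pd.DataFrame:
        branches = sorted(set(self.duplications) | set(self.losses))
        return pd.DataFrame(
            {
                "branch": branches,
                "duplications": [self.duplications.get(b, 0) for b in branches],
                "losses": [self.losses.get(b, 0) for b in branches],
                "annotation": [
                    f"+{self.duplications.get(b, 0)}/-{self.losses.get(b, 0)}"
                    for b in branches
                ],
            }
        )


def _species_index(stree: dendropy.Tree):
    """Parent map, depth map and leaf lookup for LCA arithmetic."""
    parent: dict[dendropy.Node, dendropy.Node | None] = {}
    depth: dict[dendropy.Node, int] = {}
    for node in stree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
    leaf_of = {lf.taxon.label: lf for lf in stree.leaf_node_iter()}
    return parent, depth, leaf_of


def _lca(a, b, parent, depth):
    while depth[a] > depth[b]:
        a = parent[a]
    while depth[b] > depth[a]:
        b = parent[b]
    while a is not b:
        a, b = parent[a], parent[b]
    return a


def _tree_signature(stree: dendropy.Tree) -> str:
    return stree.as_string(schema="newick", suppress_rooting=True).strip()


def lca_reconcile(
    gtree: dendropy.Tree,
    stree: dendropy.Tree,
    gene_species: Mapping[str, str],
) -> ReconciliationSummary:
    """Most-parsimonious reconciliation of a rooted binary gene tree.

    ``gene_species`` maps gene-tree leaf labels to species-tree leaf labels.
    Raises ``KeyError``/``ValueError`` for unmappable leaves or non-binary
    gene trees.
    """
    for node in gtree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            raise ValueError("gene tree must be binary for loss counting")
    parent, depth, leaf_of = _species_index(stree)

    mapping: dict[dendropy.Node, dendropy.Node] = {}
    for node in gtree.postorder_node_iter():
        if node.is_leaf():
            gid = node.taxon.label
            try:
                sp = gene_species[gid]
            except KeyError:
                raise KeyError(f"gene leaf {gid!r} has no species mapping") from None
            if sp not in leaf_of:
                raise ValueError(f"species {sp!r} of gene {gid!r} not in species tree")
            mapping[node] = leaf_of[sp]
        else:
            c1, c2 = node.child_nodes()
            mapping[node] = _lca(mapping[c1], mapping[c2], parent, depth)

    summary = ReconciliationSummary(species_tree_signature=_tree_signature(stree))
    is_dup: dict[dendropy.Node, bool] = {}
    for node in gtree.preorder_internal_node_iter():
        dup = any(mapping[c] is mapping[node] for c in node.child_nodes())
        is_dup[node] = dup
        key = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
        b = branch_id(mapping[node])
        summary.events[key] = ("duplication" if dup else "speciation", b)
        if dup:
            summary.duplications[b] = summary.duplications.get(b, 0) + 1

    for node in gtree.preorder_node_iter():
        u = node.parent_node
        if u is None:
            continue
        # walk up from M(v) to M(u); each intermediate species node passed
        # implies the lineage failed to survive in its off-path children
        path_child = mapping[node]
        passed: list[dendropy.Node] = []
        while path_child is not mapping[u]:
            passed.append(path_child)
            path_child = parent[path_child]
            if path_child is None:
                raise RuntimeError("mapping monotonicity violated")
        # passed = nodes strictly below M(u) on the path, nearest-first;
        # losses happen where the lineage enters a node's subtree but the
        # sibling subtrees never see it: for a speciation parent the entry
        # into the topmost passed node IS the speciation (no loss there)
        loss_nodes = passed if is_dup.get(u, False) else passed[:-1]
        for n in loss_nodes:
            parent_node = parent[n]
            sibs = [c for c in parent_node.child_nodes() if c is not n]
            sib = sorted(sibs, key=branch_id)[0]
            summary.losses[branch_id(sib)] = summary.losses.get(branch_id(sib), 0) + 1
    return summary


def aggregate_reconciliations(
    summaries: list[ReconciliationSummary], stree: dendropy.Tree
) -> ReconciliationSummary:
    """Element-wise sum of per-branch counts over gene trees of one species tree."""
    sig = _tree_signature(stree)
    total = ReconciliationSummary(species_tree_signature=sig)
    for s in summaries:
        if s.species_tree_signature != sig:
            raise ValueError("summaries refer to a different species tree")
        for b, n in s.duplications.items():
            total.duplications[b] = total.duplications.get(b, 0) + n
        for b, n in s.losses.items():
            total.losses[b] = total.losses.get(b, 0) + n
    return total
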