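"""Synthetic inputs with known ground truth for every pipeline stage.

These generators are pure test instruments: the statistical structure each
one emulates (gene birth–death along a species tree, planted duplicate
architectures, block-correlated FPKM expression over a 38 °C heat series,
promoters with planted heat-shock elements, scored regulatory edges) is
the structure the corresponding analysis assumes, so recovery can be
checked exactly against the emitted truth logs. Every generator is driven
by a numpy Generator seeded explicitly — identical seed and configuration
give identical output.

Default expression designs follow the study layout this toolkit targets:
a five-sample heat series (control plus 1, 4, 8 and 12 h at 38 °C) and a
six-tissue panel (root, stem, leaf, flower, silique, callus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .duplication import GenePosition, HomologPair
from .network import RegulatoryEdge
from .promoter import HSE_CONSENSUS, HSEHit, PromoterRecord
from .reconcile import branch_id

__all__ = [
    "HEAT_CONDITIONS",
    "TISSUES",
    "simulate_family_evolution",
    "simulate_genome_with_duplicates",
    "simulate_expression",
    "simulate_promoters",
    "simulate_regulatory_edges",
]

HEAT_CONDITIONS = ("control", "T1", "T4", "T8", "T12")
TISSUES = ("root", "stem", "leaf", "flower", "silique", "callus")


# ---------------------------------------------------------------------------
# gene family birth-death evolution


@dataclass
class FamilyEvolutionResult:
    gene_tree: dendropy.Tree | None  # None when the family went extinct
    gene_species: dict[str, str]
    duplications_per_branch: dict[str, int]
    losses_per_branch: dict[str, int]

    @property
    def total_duplications(self) -> int:
        return sum(self.duplications_per_branch.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses_per_branch.values())


class _GNode:
    __slots__ = ("children", "label")

    def __init__(self):
        self.children: list[_GNode] = []
        self.label: str | None = None


def _scale_to_unit_depth(tree: dendropy.Tree) -> None:
    tree.seed_node.edge.length = 0.0  # no events above the root
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None and e.length is None:
            e.length = 1.0
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    if depth <= 0:
        raise ValueError("species tree has zero depth")
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = e.length / depth


def simulate_family_evolution(
    species_tree: dendropy.Tree,
    birth_rate: float = 0.5,
    death_rate: float = 0.2,
    rng: np.random.Generator | None = None,
    n_families: int = 1,
) -> list[FamilyEvolutionResult]:
    """Evolve gene families along a species tree by a birth-death process.

    One ancestral gene enters the root; along each species branch every
    lineage duplicates (birth, rate ``birth_rate``) or dies (death, rate
    ``death_rate``) with exponential waiting times, and surviving lineages
    split with each speciation. The species tree is clock-scaled to unit
    root-to-tip depth so rates read as expected events per gene per total
    tree height. The event log records the true species-tree branch of
    every birth and death; extinct families return ``gene_tree=None`` with
    the log intact.
    """
    if birth_rate < 0 or death_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = rng or np.random.default_rng()
    stree = species_tree.clone(depth=1)
    _scale_to_unit_depth(stree)

    results: list[FamilyEvolutionResult] = []
    for _ in range(n_families):
        dup_log: dict[str, int] = {}
        loss_log: dict[str, int] = {}
        counter = {"n": 0}
        gene_species: dict[str, str] = {}

        def at_species_node(gnode: _GNode, snode: dendropy.Node) -> None:
            if snode.is_leaf():
                counter["n"] += 1
                gid = f"{snode.taxon.label}_g{counter['n']}"
                gnode.label = gid
                gene_species[gid] = snode.taxon.label
                return
            for child in snode.child_nodes():
                sub = _GNode()
                gnode.children.append(sub)
                evolve_branch(sub, child, child.edge.length)

        def evolve_branch(gnode: _GNode, snode: dendropy.Node, t_left: float) -> None:
            rate = birth_rate + death_rate
            while True:
                dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                if dt >= t_left:
                    at_species_node(gnode, snode)
                    return
                t_left -= dt
                b = branch_id(snode)
                if rng.random() < birth_rate / rate:
                    dup_log[b] = dup_log.get(b, 0) + 1
                    left, right = _GNode(), _GNode()
                    gnode.children = [left, right]
                    evolve_branch(left, snode, t_left)
                    evolve_branch(right, snode, t_left)
                    return
                loss_log[b] = loss_log.get(b, 0) + 1
                return  # lineage dies; node stays childless and unlabeled

        root = _GNode()
        at_species_node(root, stree.seed_node)
        tree = _to_dendropy(root)
        results.append(
            FamilyEvolutionResult(
                gene_tree=tree,
                gene_species={
                    g: s for g, s in gene_species.items() if tree is not None
                },
                duplications_per_branch=dup_log,
                losses_per_branch=loss_log,
            )
        )
    return results


def _prune(node: _GNode) -> _GNode | None:
    """Drop extinct subtrees and suppress single-child nodes."""
    if node.label is not None:
        return node
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


def _to_dendropy(root: _GNode) -> dendropy.Tree | None:
    pruned = _prune(root)
    if pruned is None:
        return None
    tree = dendropy.Tree()
    tree.is_rooted = True

    def build(gnode: _GNode, dnode: dendropy.Node) -> None:
        if gnode.label is not None:
            dnode.taxon = tree.taxon_namespace.new_taxon(label=gnode.label)
            return
        for c in gnode.children:
            build(c, dnode.new_child())

    build(pruned, tree.seed_node)
    return tree


# ---------------------------------------------------------------------------
# gene-order genome with planted duplicate architectures


@dataclass
class PlantedGenome:
    positions: list[GenePosition]
    pairs: list[HomologPair]
    true_classes: dict[str, str]


def simulate_genome_with_duplicates(
    rng: np.random.Generator,
    n_tandem: int = 5,
    n_proximal: int = 5,
    n_segmental_blocks: int = 2,
    segment_length: int = 6,
    n_dispersed: int = 5,
    proximal_max_gap: int = 10,
    spacing: int = 26,
    n_genes: int = 1000,
) -> PlantedGenome:
    """Gene-order genome with planted tandem / proximal / segmental /
    dispersed duplicates and singleton filler.

    Planted features are spaced ``spacing`` ranks apart (one more than the
    default block-chaining gap cap) so no two features can chain or fall
    within each other's proximal window: the emitted class labels are then
    exact ground truth for the classifier. Sources live on chromosome c1,
    segmental copies on c2 and dispersed partners on c3. Raises when the
    requested features do not fit in ``n_genes``.
    """
    feat_c1 = (
        n_tandem * 2
        + n_proximal * (proximal_max_gap + 1)
        + n_segmental_blocks * segment_length
        + n_dispersed
    )
    n_feat = n_tandem + n_proximal + n_segmental_blocks + n_dispersed
    need_c1 = feat_c1 + (n_feat + 1) * spacing
    need_c2 = n_segmental_blocks * (segment_length + spacing) + spacing
    need_c3 = n_dispersed * (1 + spacing) + spacing
    if need_c1 + need_c2 + need_c3 > n_genes:
        raise ValueError(
            f"planted events need {need_c1 + need_c2 + need_c3} genes, "
            f"genome capacity is {n_genes}"
        )
    size_c1 = need_c1 + (n_genes - need_c1 - need_c2 - need_c3)
    sizes = {"c1": size_c1, "c2": need_c2, "c3": need_c3}

    gid = {}
    positions: list[GenePosition] = []
    i = 0
    for chrom in ("c1", "c2", "c3"):
        for rank in range(1, sizes[chrom] + 1):
            i += 1
            g = f"g{i:05d}"
            gid[(chrom, rank)] = g
            positions.append(GenePosition(g, chrom, rank))

    pairs: list[HomologPair] = []
    truth: dict[str, str] = {p.gene_id: "singleton" for p in positions}

    cursor1 = spacing + 1
    for _ in range(n_tandem):
        a, b = gid[("c1", cursor1)], gid[("c1", cursor1 + 1)]
        pairs.append(HomologPair(a, b))
        truth[a] = truth[b] = "tandem"
        cursor1 += 2 + spacing
    for _ in range(n_proximal):
        gap = int(rng.integers(2, proximal_max_gap + 1))
        a, b = gid[("c1", cursor1)], gid[("c1", cursor1 + gap)]
        pairs.append(HomologPair(a, b))
        truth[a] = truth[b] = "proximal"
        cursor1 += proximal_max_gap + 1 + spacing
    cursor2 = spacing + 1
    for _ in range(n_segmental_blocks):
        for k in range(segment_length):
            a = gid[("c1", cursor1 + k)]
            b = gid[("c2", cursor2 + k)]
            pairs.append(HomologPair(a, b))
            truth[a] = truth[b] = "wgd_segmental"
        cursor1 += segment_length + spacing
        cursor2 += segment_length + spacing
    cursor3 = spacing + 1
    for _ in range(n_dispersed):
        a, b = gid[("c1", cursor1)], gid[("c3", cursor3)]
        pairs.append(HomologPair(a, b))
        truth[a] = truth[b] = "dispersed"
        cursor1 += 1 + spacing
        cursor3 += 1 + spacing
    return PlantedGenome(positions=positions, pairs=pairs, true_classes=truth)


# ---------------------------------------------------------------------------
# block-correlated expression


@dataclass
class ExpressionSim:
    fpkm: pd.DataFrame  # genes x samples, non-negative
    true_pairs: set[frozenset]
    gene_block: dict[str, int]


def simulate_expression(
    rng: np.random.Generator,
    n_blocks: int = 4,
    block_size: int = 5,
    noise_sigma: float = 0.3,
    conditions: Sequence[str] = HEAT_CONDITIONS,
    include_tissues: bool = False,
    gene_prefix: str = "gene",
) -> ExpressionSim:
    """FPKM-like expression with block-correlated condition responses.

    Genes within a block share one latent per-condition response profile
    (standard normal on the log scale); a gene's value is
    ``exp(alpha_g + z_c + sigma * eps)`` — a per-gene multiplicative
    abundance offset on the shared profile — so at ``noise_sigma = 0``
    within-block Pearson correlations equal 1 exactly while cross-block
    profiles are independent. Truth is the set of within-block pairs;
    so that the truth stays exact with few samples, latent profiles are
    redrawn until no cross-block pair correlates above 0.9 (chance
    collisions over a 5-sample design would otherwise create cross-block
    edges the truth log does not list).
    """
    cond = list(conditions) + (list(TISSUES) if include_tissues else [])
    if len(cond) < 3:
        raise ValueError("need at least 3 conditions")
    genes, blocks = [], {}
    for b in range(n_blocks):
        for k in range(block_size):
            g = f"{gene_prefix}{b:02d}_{k:02d}"
            genes.append(g)
            blocks[g] = b
    for _attempt in range(1000):
        z = rng.standard_normal((n_blocks, len(cond)))
        if n_blocks == 1:
            break
        # the bound must hold on the FPKM scale: at sigma=0 a gene's
        # profile is exp(alpha_g) * exp(z), so cross-block gene PCCs
        # equal the correlations of the exponentiated latent profiles
        lat = np.corrcoef(np.exp(z))
        if np.abs(lat[np.triu_indices(n_blocks, 1)]).max() <= 0.9:
            break
    else:
        raise ValueError(
            "could not draw block profiles with cross-block |PCC| <= 0.9; "
            "use more conditions or fewer blocks"
        )
    alpha = rng.normal(2.0, 1.0, size=len(genes))
    rows = []
    for gi, g in enumerate(genes):
        eps = rng.standard_normal(len(cond))
        rows.append(np.exp(alpha[gi] + z[blocks[g]] + noise_sigma * eps))
    fpkm = pd.DataFrame(rows, index=genes, columns=cond)
    true_pairs = {
        frozenset((a, b))
        for i, a in enumerate(genes)
        for b in genes[i + 1 :]
        if blocks[a] == blocks[b]
    }
    return ExpressionSim(fpkm=fpkm, true_pairs=true_pairs, gene_block=blocks)


# ---------------------------------------------------------------------------
# promoters with planted heat-shock elements


@dataclass
class PromoterSim:
    promoters: list[PromoterRecord]
    planted: list[HSEHit]  # truth: gene, offset, strand, element sequence


def _instantiate_hse(rng: np.random.Generator, disrupt: bool) -> str:
    bases = "ACGT"
    elem = [
        c if c != "n" else bases[rng.integers(4)] for c in HSE_CONSENSUS
    ]
    if disrupt:
        elem[0] = "C"  # break the invariant G at pattern position 1
    return "".join(elem)


def simulate_promoters(
    rng: np.random.Generator,
    n_promoters: int = 100,
    length: int = 2000,
    elements_per_promoter: int = 1,
    disrupt: bool = False,
    both_strands: bool = True,
    gene_prefix: str = "prom",
) -> PromoterSim:
    """Uniform-background promoters with planted HSE instances.

    Elements are planted at non-overlapping offsets, on a random strand
    when ``both_strands``; ``disrupt`` introduces one fixed disrupting
    substitution (G->C at consensus position 1) per instance so the scan
    must reject it. Planting beyond sequence bounds is an error.
    """
    if elements_per_promoter * 13 > length:
        raise ValueError("planted elements do not fit in the promoter length")
    bases = np.array(list("ACGT"))
    promoters: list[PromoterRecord] = []
    planted: list[HSEHit] = []
    for i in range(n_promoters):
        gid = f"{gene_prefix}{i:04d}"
        seq = bases[rng.integers(4, size=length)]
        offsets: list[int] = []
        while len(offsets) < elements_per_promoter:
            o = int(rng.integers(0, length - 12))
            if all(abs(o - p) >= 13 for p in offsets):
                offsets.append(o)
        for o in sorted(offsets):
            strand = "+" if (not both_strands or rng.random() < 0.5) else "-"
            elem = _instantiate_hse(rng, disrupt)
            ins = elem if strand == "+" else _revcomp(elem)
            seq[o : o + 13] = list(ins)
            planted.append(HSEHit(gid, o, strand, elem))
        promoters.append(PromoterRecord(gid, "".join(seq)))
    return PromoterSim(promoters=promoters, planted=planted)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# scored regulatory edges


@dataclass
class RegulatorySim:
    edges: list[RegulatoryEdge]
    family_ids: set[str]
    true_downstream: set[str]
    true_upstream: set[str]
    true_feedback: set[str]


def simulate_regulatory_edges(
    rng: np.random.Generator,
    n_family: int = 5,
    n_downstream: int = 40,
    n_upstream: int = 10,
    n_feedback: int = 3,
    n_below_threshold: int = 20,
    score_min: float = 0.60,
) -> RegulatorySim:
    """Directed scored edges around a gene family, with planted structure.

    Downstream targets and upstream regulators get scores >= ``score_min``;
    feedback genes are wired both ways; ``n_below_threshold`` extra edges
    to decoy genes score strictly below the threshold and must be filtered
    out by network assembly.
    """
    fam = [f"HSF{i:02d}" for i in range(n_family)]
    down = [f"tgt{i:03d}" for i in range(n_downstream)]
    up = [f"reg{i:03d}" for i in range(n_upstream)]
    fb = [f"fbk{i:02d}" for i in range(n_feedback)]
    edges: list[RegulatoryEdge] = []

    def hi() -> float:
        return float(score_min + (1 - score_min) * rng.random())

    def lo() -> float:
        return float(score_min * rng.random() * 0.99)

    for i, t in enumerate(down):
        edges.append(RegulatoryEdge(fam[i % n_family], t, hi()))
    for i, r in enumerate(up):
        edges.append(RegulatoryEdge(r, fam[i % n_family], hi()))
    for i, g in enumerate(fb):
        edges.append(RegulatoryEdge(fam[i % n_family], g, hi()))
        edges.append(RegulatoryEdge(g, fam[(i + 1) % n_family], hi()))
    for i in range(n_below_threshold):
        edges.append(RegulatoryEdge(fam[i % n_family], f"decoy{i:03d}", lo()))
    order = rng.permutation(len(edges))
    edges = [edges[int(k)] for k in order]
    return RegulatorySim(
        edges=edges,
        family_ids=set(fam),
        true_downstream=set(down) | set(fb),
        true_upstream=set(up) | set(fb),
        true_feedback=set(fb),
    )
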