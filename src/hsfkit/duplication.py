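"""Duplicate-gene classification from gene order and homolog pairs.

Mirrors the MCScanX-style scheme: genes are classified into singleton /
dispersed / proximal / tandem / WGD-segmental using gene-rank coordinates
(order index along each chromosome, not base pairs) and collinear blocks
chained from homolog-pair anchors by dynamic programming. Precedence when
a gene qualifies for several classes is

    wgd_segmental > tandem > proximal > dispersed > singleton.

Defaults (min_pairs=5, max_rank_gap=25, proximal_max_gap=10) follow the
MCScanX defaults. A chi-squared test compares one class's share in the
family against the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenePosition",
    "HomologPair",
    "CollinearBlock",
    "chain_collinear_blocks",
    "classify_duplicates",
    "type_enrichment_chi2",
    "DUP_CLASSES",
]

DUP_CLASSES = ("singleton", "dispersed", "proximal", "tandem", "wgd_segmental")


@dataclass(frozen=True)
class GenePosition:
    gene_id: str
    chrom: str
    rank: int  # 1-based order index along the chromosome
    bp_start: int | None = None


@dataclass(frozen=True)
class HomologPair:
    """Unordered homolog pair, stored with gene_a < gene_b."""

    gene_a: str
    gene_b: str
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self pair {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)


@dataclass
class CollinearBlock:
    """A chained run of anchors between two chromosomal regions."""

    chrom_a: str
    chrom_b: str
    orientation: str  # same | inverted
    anchors: list[tuple[str, str]]  # (gene on chrom_a, gene on chrom_b)

    def __len__(self) -> int:
        return len(self.anchors)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.anchors:
            out.add(a)
            out.add(b)
        return out


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _position_index(pos: Sequence[GenePosition]) -> dict[str, GenePosition]:
    idx = {p.gene_id: p for p in pos}
    for chrom, grp in pd.DataFrame(
        {"chrom": [p.chrom for p in pos], "rank": [p.rank for p in pos]}
    ).groupby("chrom"):
        ranks = sorted(grp["rank"])
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"ranks on {chrom} are not contiguous 1..n")
    return idx


def _best_chain(anchors, orientation, max_gap):
    """Longest strictly-monotone chain under the rank-gap cap.

    ``anchors`` are (ra, rb, key) sorted ascending; returns the chain as a
    list of keys. Ties break toward the chain with the smallest starting
    (ra, rb).
    """
    n = len(anchors)
    dp = [1] * n
    pred = [-1] * n
    start = [(anchors[i][0], anchors[i][1]) for i in range(n)]
    for j in range(n):
        for i in range(j):
            ra_i, rb_i, _ = anchors[i]
            ra_j, rb_j, _ = anchors[j]
            if not (0 < ra_j - ra_i <= max_gap):
                continue
            if orientation == "same":
                ok = 0 < rb_j - rb_i <= max_gap
            else:
                ok = 0 < rb_i - rb_j <= max_gap
            if not ok:
                continue
            cand = dp[i] + 1
            if cand > dp[j] or (cand == dp[j] and start[i] < start[j]):
                dp[j] = cand
                pred[j] = i
                start[j] = start[i]
    if n == 0:
        return []
    best = max(range(n), key=lambda j: (dp[j], tuple(-x for x in start[j])))
    chain = []
    while best != -1:
        chain.append(anchors[best][2])
        best = pred[best]
    return chain[::-1]


def chain_collinear_blocks(
    pairs: Iterable[HomologPair],
    pos: Sequence[GenePosition],
    min_pairs: int = 5,
    max_rank_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain homolog-pair anchors into collinear (syntenic) blocks.

    Anchors on each chromosome pair are chained greedily: the longest chain
    whose consecutive anchors are strictly monotone on both chromosomes
    (increasing, or increasing/decreasing for inverted blocks) with rank
    gaps <= ``max_rank_gap`` is extracted, its anchors retired, and the
    search repeats until no chain reaches ``min_pairs``. The result is
    invariant to the input order of ``pairs``.
    """
    idx = _position_index(pos)
    by_cpair: dict[tuple[str, str], list[tuple[int, int, tuple[str, str]]]] = {}
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        key = _canonical_pair(p.gene_a, p.gene_b)
        if key in seen:
            continue
        seen.add(key)
        for g in key:
            if g not in idx:
                raise KeyError(f"homolog pair member {g!r} has no position")
        pa, pb = idx[key[0]], idx[key[1]]
        # orient the anchor so chrom_a <= chrom_b (rank order for same-chrom)
        if (pa.chrom, pa.rank) <= (pb.chrom, pb.rank):
            first, second = pa, pb
        else:
            first, second = pb, pa
        by_cpair.setdefault((first.chrom, second.chrom), []).append(
            (first.rank, second.rank, (first.gene_id, second.gene_id))
        )

    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(by_cpair.items()):
        remaining = sorted(anchors)
        while True:
            candidates = []
            for orientation in ("same", "inverted"):
                chain = _best_chain(remaining, orientation, max_rank_gap)
                if len(chain) >= min_pairs:
                    anchor_lookup = {k: (ra, rb) for ra, rb, k in remaining}
                    candidates.append(
                        (len(chain), orientation == "inverted",
                         anchor_lookup[chain[0]], orientation, chain)
                    )
            if not candidates:
                break
            candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
            _, _, _, orientation, chain = candidates[0]
            blocks.append(CollinearBlock(ca, cb, orientation, list(chain)))
            used = set(chain)
            remaining = [a for a in remaining if a[2] not in used]
    return blocks


def classify_duplicates(
    members: set[str],
    pairs: Iterable[HomologPair],
    pos: Sequence[GenePosition],
    blocks: Sequence[CollinearBlock],
    proximal_max_gap: int = 10,
) -> dict[str, str]:
    """Assign each member gene exactly one duplication class.

    Precedence: block anchor -> wgd_segmental; homolog at rank distance 1
    on the same chromosome -> tandem; within ``proximal_max_gap`` ranks ->
    proximal; any homolog at all -> dispersed; none -> singleton.
    """
    idx = {p.gene_id: p for p in pos}
    partners: dict[str, set[str]] = {g: set() for g in members}
    for p in pairs:
        if p.gene_a in partners:
            partners[p.gene_a].add(p.gene_b)
        if p.gene_b in partners:
            partners[p.gene_b].add(p.gene_a)
    anchor_genes: set[str] = set()
    for b in blocks:
        anchor_genes |= b.genes()

    out: dict[str, str] = {}
    for g in sorted(members):
        if g in anchor_genes:
            out[g] = "wgd_segmental"
            continue
        if not partners[g]:
            out[g] = "singleton"
            continue
        pg = idx.get(g)
        min_gap = None
        if pg is not None:
            for h in partners[g]:
                ph = idx.get(h)
                if ph is not None and ph.chrom == pg.chrom:
                    gap = abs(ph.rank - pg.rank)
                    min_gap = gap if min_gap is None else min(min_gap, gap)
        if min_gap == 1:
            out[g] = "tandem"
        elif min_gap is not None and min_gap <= proximal_max_gap:
            out[g] = "proximal"
        else:
            out[g] = "dispersed"
    return out


def type_enrichment_chi2(
    family_class_counts: Mapping[str, int],
    genome_class_counts: Mapping[str, int] | Mapping[str, float],
    focal: str,
    alpha: float = 0.01,
    genome_is_proportions: bool = False,
) -> tuple[float, float, bool]:
    """2x2 chi-squared test of one class's family share against the genome.

    With genome counts the test is a 2x2 contingency chi-squared (focal vs
    rest x family vs genome) without continuity correction. When only the
    genome's focal-class proportion is known (``genome_is_proportions``),
    a one-sample goodness-of-fit chi-squared(1) against expected counts
    n*p and n*(1-p) is used instead. Returns (chi2, p, significant at
    ``alpha``). Raises on a zero expected cell.
    """
    fam_focal = int(family_class_counts.get(focal, 0))
    fam_rest = int(sum(family_class_counts.values()) - fam_focal)
    n = fam_focal + fam_rest
    if n == 0:
        raise ValueError("empty family class counts")

    if genome_is_proportions:
        p0 = float(genome_class_counts[focal])
        expected = np.array([n * p0, n * (1 - p0)])
        if (expected == 0).any():
            raise ValueError(
                "zero expected cell; use an exact (binomial) test instead"
            )
        observed = np.array([fam_focal, fam_rest])
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        pval = float(stats.chi2.sf(chi2, df=1))
    else:
        gen_focal = int(genome_class_counts.get(focal, 0))
        gen_rest = int(sum(genome_class_counts.values()) - gen_focal)
        table = np.array([[fam_focal, fam_rest], [gen_focal, gen_rest]])
        if (stats.contingency.expected_freq(table) == 0).any():
            raise ValueError("zero expected cell; use Fisher's exact test instead")
        res = stats.chi2_contingency(table, correction=False)
        chi2, pval = float(res.statistic), float(res.pvalue)
    return chi2, pval, bool(pval < alpha)


def class_count_table(classes: Mapping[str, str]) -> pd.Series:
    """Counts per duplication class in fixed class order."""
    counts = pd.Series(classes).value_counts()
    return counts.reindex(DUP_CLASSES, fill_value=0).astype(int)
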