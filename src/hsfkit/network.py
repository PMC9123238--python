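"""Regulatory-target and co-expression networks with term enrichment.

Two network layers:

* the directed regulatory network around a gene family (edges from a
  gene-regulatory-network resource, kept at score >= 0.60), summarised as
  downstream targets, upstream regulators and the feedback set appearing
  in both; and
* the undirected Pearson-correlation co-expression network between family
  genes (e.g. Hsf vs the Hsp chaperone families) across expression samples,
  with strict |PCC| thresholds (> .95 positive, < -.95 negative).

Enrichment of functional terms among network targets uses the upper-tail
hypergeometric test with Bonferroni correction; a term is significant at
q < .05 with fold change > 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegulatoryEdge",
    "NetworkSummary",
    "CoexpressionEdge",
    "build_target_network",
    "pcc_network",
    "hub_ranking",
    "term_enrichment",
    "venn_partition",
]


@dataclass(frozen=True)
class RegulatoryEdge:
    regulator: str
    target: str
    score: float


@dataclass
class NetworkSummary:
    downstream: dict[str, list[str]]  # family gene -> targets it regulates
    upstream: dict[str, list[str]]  # family gene -> its regulators
    feedback: list[str]  # genes that are both downstream and upstream

    @property
    def downstream_genes(self) -> set[str]:
        return {t for v in self.downstream.values() for t in v}

    @property
    def upstream_genes(self) -> set[str]:
        return {r for v in self.upstream.values() for r in v}

    def counts(self) -> pd.DataFrame:
        genes = sorted(set(self.downstream) | set(self.upstream))
        return pd.DataFrame(
            {
                "gene": genes,
                "downstream_count": [len(self.downstream.get(g, [])) for g in genes],
                "upstream_count": [len(self.upstream.get(g, [])) for g in genes],
            }
        ).set_index("gene")


@dataclass(frozen=True)
class CoexpressionEdge:
    """Undirected co-expression edge; gene_a < gene_b canonically."""

    gene_a: str
    gene_b: str
    pcc: float
    sign: str  # positive | negative
    family_a: str = ""
    family_b: str = ""


def build_target_network(
    edges: Iterable[RegulatoryEdge],
    family_ids: set[str],
    score_min: float = 0.60,
) -> NetworkSummary:
    """Filter regulatory edges and split targets into downstream/upstream.

    Downstream genes are targets of family regulators; upstream genes
    regulate family targets; the feedback set is their intersection.
    Edges below ``score_min`` are dropped (threshold inclusive: >= 0.60).
    """
    downstream: dict[str, set[str]] = {}
    upstream: dict[str, set[str]] = {}
    for e in edges:
        if e.score < score_min:
            continue
        if e.regulator in family_ids:
            downstream.setdefault(e.regulator, set()).add(e.target)
        if e.target in family_ids:
            upstream.setdefault(e.target, set()).add(e.regulator)
    down_sorted = {g: sorted(v) for g, v in sorted(downstream.items())}
    up_sorted = {g: sorted(v) for g, v in sorted(upstream.items())}
    down_all = {t for v in down_sorted.values() for t in v}
    up_all = {r for v in up_sorted.values() for r in v}
    return NetworkSummary(
        downstream=down_sorted,
        upstream=up_sorted,
        feedback=sorted(down_all & up_all),
    )


def pcc_network(
    expr: pd.DataFrame,
    families: Mapping[str, str],
    pos_thr: float = 0.95,
    neg_thr: float = -0.95,
    cross_family_only: bool = False,
) -> list[CoexpressionEdge]:
    """Threshold the pairwise Pearson-correlation matrix into an edge list.

    ``expr`` is genes x samples (>= 3 samples required). Zero-variance
    genes cannot carry a correlation and are excluded with a warning.
    Strict inequalities at both thresholds, matching PCC > .95 / < -.95.
    With ``cross_family_only`` edges within one family label are dropped.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    X = expr.to_numpy(dtype=float)
    var = X.var(axis=1)
    keep = var > 0
    dropped = list(expr.index[~keep])
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} zero-variance genes from the PCC network",
            stacklevel=2,
        )
    genes = list(expr.index[keep])
    if len(genes) < 2:
        return []
    corr = np.corrcoef(X[keep])
    edges: list[CoexpressionEdge] = []
    for i, j in combinations(range(len(genes)), 2):
        r = float(corr[i, j])
        if r > pos_thr:
            sign = "positive"
        elif r < neg_thr:
            sign = "negative"
        else:
            continue
        a, b = sorted((genes[i], genes[j]))
        fa, fb = families.get(a, ""), families.get(b, "")
        if cross_family_only and fa == fb:
            continue
        edges.append(CoexpressionEdge(a, b, r, sign, fa, fb))
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges


def hub_ranking(edges: Sequence[CoexpressionEdge], top_k: int = 20) -> pd.DataFrame:
    """Node degrees, negative-edge degrees and family labels, ranked.

    Sorted by degree descending with ties broken by gene id; the result's
    ``attrs['top_k_family_composition']`` holds family-label counts within
    the top ``top_k`` rows.
    """
    deg: dict[str, int] = {}
    neg: dict[str, int] = {}
    fam: dict[str, str] = {}
    for e in edges:
        for g, f in ((e.gene_a, e.family_a), (e.gene_b, e.family_b)):
            deg[g] = deg.get(g, 0) + 1
            if e.sign == "negative":
                neg[g] = neg.get(g, 0) + 1
            fam.setdefault(g, f)
    table = pd.DataFrame(
        {
            "gene": list(deg),
            "degree": [deg[g] for g in deg],
            "negative_degree": [neg.get(g, 0) for g in deg],
            "family": [fam[g] for g in deg],
        }
    )
    table = table.sort_values(
        ["degree", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = table.head(top_k)
    table.attrs["top_k_family_composition"] = (
        top["family"].value_counts().to_dict()
    )
    return table


def term_enrichment(
    target_genes: set[str],
    annotations: Mapping[str, Iterable[str]],
    background: set[str],
    q_max: float = 0.05,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of targets against a background.

    Only annotated genes enter the counts: n = annotated targets, N =
    annotated background, and per term k / K are targets / background genes
    carrying it. p = P(X >= k) under Hypergeom(N, K, n); q = Bonferroni
    min(1, m*p) over the m tested terms; fold = (k/n)/(K/N). Significant
    iff q < ``q_max`` and fold > ``fold_min``. Rows sorted by q then term.
    """
    if not target_genes <= background:
        raise ValueError("target_genes must be a subset of background")
    annotated_bg = {g for g in background if annotations.get(g)}
    annotated_tg = target_genes & annotated_bg
    n, N = len(annotated_tg), len(annotated_bg)
    if n == 0 or N == 0:
        raise ValueError("no annotated target or background genes")

    term_bg: dict[str, int] = {}
    term_tg: dict[str, int] = {}
    for g in annotated_bg:
        for t in set(annotations[g]):
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in annotated_tg:
                term_tg[t] = term_tg.get(t, 0) + 1
    tested = sorted(t for t, k in term_tg.items() if k >= 1)
    m = len(tested)
    rows = []
    for t in tested:
        k, K = term_tg[t], term_bg[t]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        q = min(1.0, m * p)
        fold = (k / n) / (K / N)
        rows.append(
            {
                "term": t,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "q": q,
                "fold": fold,
                "significant": bool(q < q_max and fold > fold_min),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "k", "n", "K", "N", "p", "q", "fold", "significant"],
    )
    return df.sort_values(["q", "term"], kind="mergesort").reset_index(drop=True)


def venn_partition(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every region of the Venn partition of >= 2 named sets.

    Keys are tuples of the set names an element belongs to (sorted);
    regions with zero elements are reported with count 0 for completeness
    of the partition over non-empty name combinations.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 named sets")
    names = sorted(sets)
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo)) if combo else universe
            outside = set().union(*(sets[n] for n in names if n not in combo)) or set()
            regions[combo] = len(inside - outside)
    return regions
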