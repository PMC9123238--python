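"""Subgenome retention bookkeeping for a triplicated pan-genome.

After the Brassica whole-genome triplication, each reference (Arabidopsis)
gene can survive in 0-3 of the three subgenomes — the least-fractionated
LF and the more-fractionated MF1 and MF2 — of every accession. This
module only counts: syntenic assignments (which copy pairs with which
reference gene) are an input table, producible by cross-species collinear
chaining, so the triplication bookkeeping stays independently testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SyntenyAssignment",
    "RetentionMatrix",
    "SUBGENOMES",
    "count_retention",
    "retention_summary",
    "detect_losses",
]

SUBGENOMES = ("LF", "MF1", "MF2")


@dataclass(frozen=True)
class SyntenyAssignment:
    ref_gene: str
    accession: str
    subgenome: str
    copy_gene: str

    def __post_init__(self) -> None:
        if self.subgenome not in SUBGENOMES:
            raise ValueError(f"invalid subgenome {self.subgenome!r}")


@dataclass
class RetentionMatrix:
    """Reference genes x accessions copy counts (0-3) with per-subgenome detail."""

    counts: pd.DataFrame  # ref genes x accessions, ints 0..3
    per_subgenome: pd.DataFrame  # index (ref_gene, accession, subgenome) -> copy_gene
    copy_genes: dict[str, set[str]]  # accession -> distinct syntenic copy genes


def count_retention(assignments: Sequence[SyntenyAssignment]) -> RetentionMatrix:
    """Tally distinct retained subgenomes per (reference gene, accession).

    A (ref_gene, accession, subgenome) slot holds at most one copy;
    conflicting duplicate assignments are an error, because the 0-3 copy
    structure assumes one surviving homeolog per subgenome.
    """
    slots: dict[tuple[str, str, str], str] = {}
    for a in assignments:
        key = (a.ref_gene, a.accession, a.subgenome)
        if key in slots and slots[key] != a.copy_gene:
            raise ValueError(
                f"conflicting copies for {key}: {slots[key]} vs {a.copy_gene}"
            )
        slots[key] = a.copy_gene

    refs = sorted({k[0] for k in slots})
    accs = sorted({k[1] for k in slots})
    counts = pd.DataFrame(0, index=refs, columns=accs, dtype=int)
    for ref, acc, _sg in slots:
        counts.loc[ref, acc] += 1
    per_sub = pd.DataFrame(
        [
            {"ref_gene": r, "accession": a, "subgenome": s, "copy_gene": c}
            for (r, a, s), c in sorted(slots.items())
        ],
        columns=["ref_gene", "accession", "subgenome", "copy_gene"],
    ).set_index(["ref_gene", "accession", "subgenome"])
    copy_genes: dict[str, set[str]] = {acc: set() for acc in accs}
    for (_r, acc, _s), c in slots.items():
        copy_genes[acc].add(c)
    return RetentionMatrix(counts=counts, per_subgenome=per_sub, copy_genes=copy_genes)


def retention_summary(
    matrix: RetentionMatrix, family_totals: Mapping[str, int]
) -> pd.DataFrame:
    """Per-accession syntenic gene counts and ratios.

    ``family_totals`` gives each accession's total family size (syntenic or
    not); the syntenic ratio is distinct syntenic copies / total. The
    result's ``attrs`` carry the min/max family size over accessions.
    """
    rows = []
    for acc in matrix.counts.columns:
        total = int(family_totals[acc])
        if total <= 0:
            raise ValueError(f"family total for {acc!r} must be > 0")
        syntenic = len(matrix.copy_genes[acc])
        rows.append(
            {
                "accession": acc,
                "syntenic_genes": syntenic,
                "family_total": total,
                "syntenic_ratio": syntenic / total,
            }
        )
    out = pd.DataFrame(rows).set_index("accession")
    totals = [int(family_totals[a]) for a in matrix.counts.columns]
    out.attrs["family_size_min"] = min(totals)
    out.attrs["family_size_max"] = max(totals)
    return out


def detect_losses(matrix: RetentionMatrix) -> pd.DataFrame:
    """All (reference gene, accession) pairs with zero syntenic copies.

    The result flags, per reference gene, whether it is lost in every
    accession (``lost_everywhere``) — the complete-loss pattern.
    """
    rows = []
    for ref in matrix.counts.index:
        zero_accs = [a for a in matrix.counts.columns if matrix.counts.loc[ref, a] == 0]
        everywhere = len(zero_accs) == matrix.counts.shape[1]
        for acc in zero_accs:
            rows.append(
                {"ref_gene": ref, "accession": acc, "lost_everywhere": everywhere}
            )
    return pd.DataFrame(rows, columns=["ref_gene", "accession", "lost_everywhere"])


def write_matrix_tsv(matrix: RetentionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="ref_gene")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="ref_gene")


def read_assignments_tsv(path) -> list[SyntenyAssignment]:
    df = pd.read_csv(path, sep="\t")
    return [
        SyntenyAssignment(r.ref_gene, r.accession, r.subgenome, r.copy_gene)
        for r in df.itertuples(index=False)
    ]
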