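"""Gene-family cataloguing from profile-domain hits.

A gene family (e.g. the plant heat-shock transcription factors, defined by
the Pfam HSF-type DNA-binding domain PF00447) is catalogued per species by

1. collapsing alternative splice isoforms to one representative per locus,
2. selecting genes carrying a qualifying domain hit (e-value below a strict
   threshold, 1e-4 by default), and
3. summarising family size and protein-length statistics against the whole
   genome.

Counts and ratios are kept on a 0-1 scale internally; percent formatting is
left to the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "DomainHit",
    "FamilyCatalog",
    "dedupe_isoforms",
    "select_family_members",
    "summarize_catalog",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene model; ``locus_id`` groups alternative splice isoforms."""

    gene_id: str
    species_id: str
    locus_id: str
    protein_length: int
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError(f"protein_length must be >= 1 for {self.gene_id}")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"start > end for {self.gene_id}")
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-' for {self.gene_id}")


@dataclass(frozen=True)
class DomainHit:
    """One profile-domain match (per-domain e-value, 1-based alignment span)."""

    gene_id: str
    domain_accession: str
    e_value: float
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value for {self.gene_id}")
        if self.ali_from > self.ali_to:
            raise ValueError(f"ali_from > ali_to for {self.gene_id}")


@dataclass
class FamilyCatalog:
    """Per-species family membership plus the genome-wide denominators.

    ``members`` maps species_id to the sorted member gene ids;
    ``genome_gene_count`` and the two mean protein lengths provide the
    denominators for the count-ratio and length-ratio statistics.
    """

    members: dict[str, list[str]]
    genome_gene_count: dict[str, int]
    mean_family_length: dict[str, float]
    mean_genome_length: dict[str, float]

    @property
    def total_members(self) -> int:
        return sum(len(v) for v in self.members.values())

    def species(self) -> list[str]:
        return sorted(self.members)


def dedupe_isoforms(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Collapse alternative splice isoforms to one record per locus.

    The longest protein is retained; ties break to the lexicographically
    smallest gene id. Output is sorted by (species_id, locus_id) so the
    result is deterministic regardless of input order.
    """
    best: dict[tuple[str, str], GeneRecord] = {}
    for rec in records:
        key = (rec.species_id, rec.locus_id)
        cur = best.get(key)
        if (
            cur is None
            or rec.protein_length > cur.protein_length
            or (rec.protein_length == cur.protein_length and rec.gene_id < cur.gene_id)
        ):
            best[key] = rec
    return [best[k] for k in sorted(best)]


def select_family_members(
    hits: Iterable[DomainHit],
    records: Sequence[GeneRecord],
    accession: str,
    e_max: float = 1e-4,
    secondary_hits: Optional[Iterable[DomainHit]] = None,
    secondary_accession: Optional[str] = None,
) -> FamilyCatalog:
    """Build a :class:`FamilyCatalog` from domain hits over deduped records.

    A gene is a family member iff it has at least one hit with the requested
    ``accession`` and ``e_value`` strictly below ``e_max``. When
    ``secondary_hits`` is given (domain validation against a second profile
    database), membership is the intersection of both qualifying sets.

    Raises ``KeyError`` for a hit whose gene id has no record — that signals
    a catalogue/hit-table mismatch rather than a non-member.
    """
    by_gene = {(r.species_id, r.gene_id): r for r in records}
    gene_index: dict[str, GeneRecord] = {}
    for rec in records:
        gene_index[rec.gene_id] = rec

    def qualifying(hit_iter: Iterable[DomainHit], acc: str) -> set[str]:
        out: set[str] = set()
        for h in hit_iter:
            if h.gene_id not in gene_index:
                raise KeyError(
                    f"domain hit for unknown gene id {h.gene_id!r}: "
                    "hit table does not match the gene table"
                )
            if h.domain_accession == acc and h.e_value < e_max:
                out.add(h.gene_id)
        return out

    member_ids = qualifying(hits, accession)
    if secondary_hits is not None:
        member_ids &= qualifying(secondary_hits, secondary_accession or accession)

    species = sorted({r.species_id for r in records})
    members = {sp: [] for sp in species}
    for gid in sorted(member_ids):
        members[gene_index[gid].species_id].append(gid)

    genome_count = {sp: 0 for sp in species}
    length_sum = {sp: 0 for sp in species}
    fam_length_sum = {sp: 0 for sp in species}
    for (sp, gid), rec in by_gene.items():
        genome_count[sp] += 1
        length_sum[sp] += rec.protein_length
        if gid in member_ids:
            fam_length_sum[sp] += rec.protein_length

    mean_family_length = {
        sp: (fam_length_sum[sp] / len(members[sp]) if members[sp] else float("nan"))
        for sp in species
    }
    mean_genome_length = {
        sp: (length_sum[sp] / genome_count[sp] if genome_count[sp] else float("nan"))
        for sp in species
    }
    return FamilyCatalog(
        members=members,
        genome_gene_count=genome_count,
        mean_family_length=mean_family_length,
        mean_genome_length=mean_genome_length,
    )


def summarize_catalog(catalog: FamilyCatalog) -> pd.DataFrame:
    """Per-species family statistics plus global summary rows.

    Columns: ``member_count``, ``count_ratio`` (members / genome genes, 0-1),
    ``log2_member_count`` / ``log10_genome_count`` (NaN when the count is 0
    rather than -inf), ``length_ratio`` (mean family protein length / mean
    genome protein length).

    Three global rows are appended under species id ``__global__``:
    ``mean_member_count``, ``frac_species_gt10`` (share of species with more
    than 10 members) and ``frac_length_ratio_gt1.2``.
    """
    rows = []
    for sp in catalog.species():
        n_genome = catalog.genome_gene_count.get(sp, 0)
        if n_genome <= 0:
            raise ValueError(f"species {sp!r} has genome_gene_count = 0")
        n = len(catalog.members[sp])
        lr = catalog.mean_family_length[sp] / catalog.mean_genome_length[sp]
        rows.append(
            {
                "species_id": sp,
                "member_count": n,
                "count_ratio": n / n_genome,
                "log2_member_count": np.log2(n) if n > 0 else np.nan,
                "log10_genome_count": np.log10(n_genome),
                "length_ratio": lr,
            }
        )
    per_species = pd.DataFrame(rows).set_index("species_id")

    counts = per_species["member_count"]
    lratio = per_species["length_ratio"]
    summary = pd.DataFrame(
        {
            "statistic": [
                "mean_member_count",
                "frac_species_gt10",
                "frac_length_ratio_gt1.2",
            ],
            "value": [
                float(counts.mean()),
                float((counts > 10).mean()),
                float((lratio > 1.2).mean()),
            ],
        }
    )
    per_species.attrs["global"] = summary
    return per_species


def catalog_from_counts(
    member_counts: Mapping[str, int], genome_counts: Mapping[str, int]
) -> FamilyCatalog:
    """Catalogue built from per-species counts alone (no per-gene records).

    Useful when only published count tables are available; member gene ids
    are synthesised as ``<species>_g<i>`` and length statistics are set to 1
    so length ratios are uninformative (1.0) but count statistics are exact.
    """
    members = {
        sp: [f"{sp}_g{i}" for i in range(int(member_counts.get(sp, 0)))]
        for sp in genome_counts
    }
    return FamilyCatalog(
        members=members,
        genome_gene_count=dict(genome_counts),
        mean_family_length={sp: 1.0 for sp in genome_counts},
        mean_genome_length={sp: 1.0 for sp in genome_counts},
    )
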