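"""Readers and writers for the pipeline's tabular and sequence formats.

HMMER domtblout goes through Bio.SearchIO; FASTA through Bio.SeqIO; the
remaining formats are plain TSV tables read with pandas. Homolog pairs
use the 12-column BLAST tabular dialect (query, subject and e-value
columns). All written tables are TSV with headers; coordinates in written
reports are 1-based inclusive.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from Bio import SearchIO, SeqIO

from .duplication import GenePosition, HomologPair
from .family import DomainHit, FamilyCatalog, GeneRecord
from .network import CoexpressionEdge, RegulatoryEdge
from .promoter import GeneModel, HSEHit, PromoterRecord

__all__ = [
    "read_domtblout",
    "read_gene_table",
    "read_fasta_lengths",
    "read_genome_fasta",
    "read_motif_matrix",
    "read_blast_pairs",
    "positions_from_gene_table",
    "read_expression_tsv",
    "read_annotation_tsv",
    "read_regulatory_edges_tsv",
    "write_catalog_tsv",
    "write_coexpression_edges_tsv",
    "read_coexpression_edges_tsv",
    "write_promoters_fasta",
    "read_promoters_fasta",
    "write_hse_hits_tsv",
]


def read_domtblout(path, program: str = "hmmsearch") -> list[DomainHit]:
    """Parse HMMER3 --domtblout per-domain hits.

    With ``program='hmmsearch'`` the target column holds the gene and the
    query the profile; ``'hmmscan'`` is the opposite orientation. The
    per-domain (independent) e-value is used, alignment coordinates are
    returned 1-based inclusive.
    """
    fmt = {"hmmsearch": "hmmsearch3-domtab", "hmmscan": "hmmscan3-domtab"}[program]
    hits: list[DomainHit] = []
    for qres in SearchIO.parse(str(path), fmt):
        for hit in qres:
            for hsp in hit:
                if program == "hmmsearch":
                    gene, acc = hit.id, qres.accession or qres.id
                    frm, to = hsp.hit_start + 1, hsp.hit_end
                else:
                    gene, acc = qres.id, hit.accession or hit.id
                    frm, to = hsp.query_start + 1, hsp.query_end
                acc = acc.split(".")[0]  # PF00447.20 -> PF00447
                hits.append(DomainHit(gene, acc, float(hsp.evalue), frm, to))
    return hits


def read_gene_table(path) -> list[GeneRecord]:
    """TSV: gene_id, species_id, locus_id, length[, chrom, start, end, strand]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for r in df.itertuples(index=False):
        records.append(
            GeneRecord(
                gene_id=str(r.gene_id),
                species_id=str(r.species_id),
                locus_id=str(r.locus_id),
                protein_length=int(r.length),
                chrom=getattr(r, "chrom", None),
                start=int(r.start) if getattr(r, "start", None) is not None and not pd.isna(r.start) else None,
                end=int(r.end) if getattr(r, "end", None) is not None and not pd.isna(r.end) else None,
                strand=getattr(r, "strand", None) if getattr(r, "strand", None) in ("+", "-") else None,
            )
        )
    return records


def read_fasta_lengths(path) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_motif_matrix(path) -> pd.DataFrame:
    """Gene x motif 0/1 TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_blast_pairs(
    path, e_max: float = 1e-5, top_hits_per_query: int | None = 5
) -> list[HomologPair]:
    """12-column BLAST tabular -> canonical homolog pairs.

    Uses columns 1 (query), 2 (subject) and 11 (e-value); self hits are
    dropped, pairs are deduplicated in canonical order, and optionally
    only the ``top_hits_per_query`` best-scoring subjects per query are
    retained (by ascending e-value, ties by subject id).
    """
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 10])
    df.columns = ["query", "subject", "evalue"]
    df = df[(df["query"] != df["subject"]) & (df["evalue"] <= e_max)]
    if top_hits_per_query is not None:
        df = (
            df.sort_values(["query", "evalue", "subject"], kind="mergesort")
            .groupby("query", sort=False)
            .head(top_hits_per_query)
        )
    out: dict[tuple[str, str], HomologPair] = {}
    for r in df.itertuples(index=False):
        p = HomologPair(str(r.query), str(r.subject), float(r.evalue))
        out.setdefault((p.gene_a, p.gene_b), p)
    return [out[k] for k in sorted(out)]


def positions_from_gene_table(path) -> list[GenePosition]:
    """GFF-like TSV (chrom, start, end, strand, gene_id) -> rank positions.

    Ranks are the 1-based order of gene starts along each chromosome,
    which is the coordinate system the duplicate classifier uses.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
    out: list[GenePosition] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        for rank, r in enumerate(grp.itertuples(index=False), start=1):
            out.append(GenePosition(str(r.gene_id), str(chrom), rank, int(r.start)))
    return out


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x sample FPKM matrix with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotation_tsv(path) -> dict[str, list[str]]:
    """TSV (gene_id, term); one row per gene-term assignment."""
    df = pd.read_csv(path, sep="\t")
    ann: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        ann.setdefault(str(r.gene_id), []).append(str(r.term))
    return ann


def read_regulatory_edges_tsv(path) -> list[RegulatoryEdge]:
    """TSV (regulator, target, score)."""
    df = pd.read_csv(path, sep="\t")
    return [
        RegulatoryEdge(str(r.regulator), str(r.target), float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_catalog_tsv(catalog: FamilyCatalog, path) -> None:
    rows = []
    for sp in catalog.species():
        for g in catalog.members[sp]:
            rows.append({"species_id": sp, "gene_id": g})
    pd.DataFrame(rows, columns=["species_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_coexpression_edges_tsv(edges: Sequence[CoexpressionEdge], path) -> None:
    """Edge-list TSV loadable by standard graph tools."""
    pd.DataFrame(
        {
            "source": [e.gene_a for e in edges],
            "target": [e.gene_b for e in edges],
            "weight": [e.pcc for e in edges],
            "sign": [e.sign for e in edges],
            "source_family": [e.family_a for e in edges],
            "target_family": [e.family_b for e in edges],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_coexpression_edges_tsv(path) -> list[CoexpressionEdge]:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip"
    )
    return [
        CoexpressionEdge(
            str(r.source), str(r.target), float(r.weight), str(r.sign),
            str(r.source_family), str(r.target_family),
        )
        for r in df.itertuples(index=False)
    ]


def write_promoters_fasta(promoters: Iterable[PromoterRecord], path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.gene_id}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")


def read_promoters_fasta(path) -> list[PromoterRecord]:
    return [
        PromoterRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_hse_hits_tsv(hits: Sequence[HSEHit], path) -> None:
    """Hit table with 1-based inclusive offsets (documented in the header)."""
    pd.DataFrame(
        {
            "gene_id": [h.gene_id for h in hits],
            "offset_1based": [h.offset + 1 for h in hits],
            "strand": [h.strand for h in hits],
            "sequence": [h.matched for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)


def gene_models_from_table(path) -> list[GeneModel]:
    """TSV (gene_id, chrom, cds_start, cds_end, strand) for promoter extraction."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.cds_start), int(r.cds_end), str(r.strand))
        for r in df.itertuples(index=False)
    ]
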