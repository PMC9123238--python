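"""Promoter extraction and heat-shock-element (HSE) scanning.

The HSE is the cis-regulatory element bound by heat-shock transcription
factors; the scan uses the 13-nt consensus GAAnnTTnnnGAA (n = any base).
Promoters are the 2 kb upstream of the translation initiation site
(truncated at chromosome edges), reported 5'->3' relative to the gene, so
a forward-pattern match on the promoter string is a gene-strand hit and
the reverse strand is scanned by matching the reverse-complement pattern
TTCnnnAAnnTTC on the same string. Overlapping matches are all reported;
windows containing N never match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .network import CoexpressionEdge

__all__ = [
    "PromoterRecord",
    "HSEHit",
    "HSE_CONSENSUS",
    "extract_promoters",
    "scan_hse",
    "hse_subnetwork",
]

HSE_CONSENSUS = "GAAnnTTnnnGAA"
_FWD = re.compile("(?=(GAA[ACGT]{2}TT[ACGT]{3}GAA))")
_REV = re.compile("(?=(TTC[ACGT]{3}AA[ACGT]{2}TTC))")


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    sequence: str  # uppercase DNA over ACGTN, 5'->3' relative to the gene

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty promoter for {self.gene_id}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid bases {bad} in promoter of {self.gene_id}")


@dataclass(frozen=True)
class HSEHit:
    gene_id: str
    offset: int  # 0-based match start on the promoter's forward coordinates
    strand: str  # + | -
    matched: str  # the 13-nt window as it appears on the reported strand


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model for promoter extraction (1-based inclusive CDS)."""

    gene_id: str
    chrom: str
    cds_start: int
    cds_end: int
    strand: str


def extract_promoters(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    length: int = 2000,
) -> list[PromoterRecord]:
    """Cut the ``length`` bases upstream of each translation start.

    Plus-strand genes take the window ending immediately before
    ``cds_start``; minus-strand genes take the window after ``cds_end``,
    reverse-complemented, so every promoter reads 5'->3' toward the gene.
    Windows are truncated at chromosome edges; a CDS outside its
    chromosome is an error.
    """
    out: list[PromoterRecord] = []
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"chromosome {g.chrom!r} of {g.gene_id} not in genome")
        seq = genome[g.chrom].upper()
        L = len(seq)
        if not (1 <= g.cds_start <= g.cds_end <= L):
            raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
        if g.strand == "+":
            lo = max(0, g.cds_start - 1 - length)
            window = seq[lo : g.cds_start - 1]
        elif g.strand == "-":
            window = str(Seq(seq[g.cds_end : g.cds_end + length]).reverse_complement())
        else:
            raise ValueError(f"bad strand {g.strand!r} for {g.gene_id}")
        if window:
            out.append(PromoterRecord(g.gene_id, window))
    return out


def scan_hse(promoter: PromoterRecord, both_strands: bool = True) -> list[HSEHit]:
    """All (overlapping) HSE consensus matches in one promoter.

    Forward hits match GAAnnTTnnnGAA directly; reverse-strand hits are
    found as TTCnnnAAnnTTC on the forward sequence and reported with
    strand '-' and the forward-coordinate offset, the matched string given
    as its reverse complement (the element as read on the minus strand).
    Hits are sorted by offset, then strand ('+' first).
    """
    seq = promoter.sequence
    hits = [
        HSEHit(promoter.gene_id, m.start(), "+", m.group(1))
        for m in _FWD.finditer(seq)
    ]
    if both_strands:
        hits += [
            HSEHit(
                promoter.gene_id,
                m.start(),
                "-",
                str(Seq(m.group(1)).reverse_complement()),
            )
            for m in _REV.finditer(seq)
        ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def hse_positive_genes(promoters: Sequence[PromoterRecord], **kw) -> set[str]:
    """Genes whose promoter carries at least one HSE hit."""
    return {p.gene_id for p in promoters if scan_hse(p, **kw)}


def hse_subnetwork(
    edges: Sequence[CoexpressionEdge],
    hse_positive: set[str],
    hsp_families: set[str] = frozenset(
        {"Hsp20", "Hsp40", "Hsp60", "Hsp70", "Hsp90", "Hsp100"}
    ),
) -> list[CoexpressionEdge]:
    """Restrict a co-expression network to HSE-positive Hsp endpoints.

    An edge survives when every Hsp-family endpoint is HSE-positive
    (non-Hsp endpoints, e.g. the Hsf regulators themselves, are always
    kept). This reconstructs the heat-response subnetwork of direct
    HSE-mediated regulation.
    """
    kept = []
    for e in edges:
        ok = True
        for g, f in ((e.gene_a, e.family_a), (e.gene_b, e.family_b)):
            if f in hsp_families and g not in hse_positive:
                ok = False
                break
        if ok:
            kept.append(e)
    return kept
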