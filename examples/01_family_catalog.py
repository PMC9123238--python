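"""Catalogue a gene family from domain hits and summarise it per species.

Builds a toy two-species gene set with splice isoforms and HSF-domain
(PF00447) hits, collapses isoforms to the longest protein, applies the
strict e-value < 1e-4 membership rule, and prints the per-species summary.
"""

from hsfkit.family import (
    DomainHit,
    GeneRecord,
    dedupe_isoforms,
    select_family_members,
    summarize_catalog,
)

records = dedupe_isoforms(
    [
        GeneRecord("AtHsfA1a.1", "Ath", "L1", 480),
        GeneRecord("AtHsfA1a.2", "Ath", "L1", 495),  # longest isoform wins
        GeneRecord("AtHsfB2b", "Ath", "L2", 300),
        GeneRecord("AtKinase1", "Ath", "L3", 620),
        GeneRecord("OsHsfA2", "Osa", "L4", 350),
        GeneRecord("OsMyb3", "Osa", "L5", 280),
    ]
)
hits = [
    DomainHit("AtHsfA1a.2", "PF00447", 1.4e-30, 41, 136),
    DomainHit("AtHsfB2b", "PF00447", 3.6e-08, 12, 101),
    DomainHit("AtKinase1", "PF00447", 2.6e-03, 20, 70),  # above threshold
    DomainHit("OsHsfA2", "PF00447", 8.0e-21, 30, 125),
]

catalog = select_family_members(hits, records, "PF00447", e_max=1e-4)
table = summarize_catalog(catalog)

print("members:", {sp: catalog.members[sp] for sp in catalog.species()})
print(table[["member_count", "count_ratio", "length_ratio"]].round(4))
print(table.attrs["global"].to_string(index=False))
# member_count is the family size after isoform dedup and the strict
# e-value filter; count_ratio and length_ratio compare the family against
# all genes of the species (AtKinase1 is excluded: 2.6e-3 >= 1e-4).
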