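"""Tally subgenome retention of reference genes across pan-genome accessions.

After a whole-genome triplication each reference gene can survive in 0-3
subgenomes (LF, MF1, MF2) per accession. This example tallies a toy
syntenic-assignment table for three accessions, prints the copy-count
matrix, per-accession syntenic ratios, and the loss report.
"""

from hsfkit.pangenome import (
    SyntenyAssignment,
    count_retention,
    detect_losses,
    retention_summary,
)

assignments = [
    # AT3G22830-like gene: fully retained in three subgenomes of CXA
    *[SyntenyAssignment("AT3G22830", "CXA", s, f"CXA_{s}_1") for s in ("LF", "MF1", "MF2")],
    SyntenyAssignment("AT3G22830", "OIA", "LF", "OIA_LF_1"),
    SyntenyAssignment("AT4G18880", "OIA", "LF", "OIA_LF_2"),
    SyntenyAssignment("AT4G18880", "TUE", "MF1", "TUE_MF1_1"),
    SyntenyAssignment("AT5G45710", "TUE", "LF", "TUE_LF_1"),
    # AT1G77570-like gene: no syntenic copy anywhere
]

matrix = count_retention(assignments)
matrix.counts.loc["AT1G77570"] = 0
print(matrix.counts.to_string())

summary = retention_summary(matrix, {"CXA": 4, "OIA": 4, "TUE": 4})
print(summary.round(3).to_string())

losses = detect_losses(matrix)
print(losses.to_string(index=False))
# Matrix entries are copies retained per accession (0-3). The syntenic
# ratio divides distinct syntenic copies by the accession's family size;
# 'lost_everywhere' flags reference genes with no copy in any accession.
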