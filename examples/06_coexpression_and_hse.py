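"""Build a PCC co-expression network and restrict it to HSE-bearing genes.

Simulates block-correlated FPKM expression over the five-sample heat
series, thresholds Pearson correlations at |PCC| > .95, ranks hubs, scans
synthetic promoters for the heat-shock element GAAnnTTnnnGAA, and keeps
only edges whose Hsp endpoint carries an HSE.
"""

import numpy as np

from hsfkit.network import hub_ranking, pcc_network
from hsfkit.promoter import hse_positive_genes, hse_subnetwork, scan_hse
from hsfkit.simulate import simulate_expression, simulate_promoters

rng = np.random.default_rng(10)
sim = simulate_expression(rng, n_blocks=4, block_size=5, noise_sigma=0.1)

# alternate family labels so edges span Hsf and an Hsp family
genes = list(sim.fpkm.index)
families = {g: ("Hsf" if i % 2 else "Hsp20") for i, g in enumerate(genes)}

edges = pcc_network(sim.fpkm, families, pos_thr=0.95, neg_thr=-0.95)
n_neg = sum(e.sign == "negative" for e in edges)
print(f"{len(edges)} edges above |PCC| > .95 ({n_neg} negative)")
table = hub_ranking(edges, top_k=5)
print(table.head(5).to_string(index=False))

# promoters for the Hsp-side genes; half get a planted HSE
hsp_genes = [g for g in genes if families[g] == "Hsp20"]
prom = simulate_promoters(rng, n_promoters=len(hsp_genes), length=500)
renamed = {p.gene_id: hsp_genes[i] for i, p in enumerate(prom.promoters)}
positives = set()
for p in prom.promoters[: len(hsp_genes) // 2]:
    if scan_hse(p):
        positives.add(renamed[p.gene_id])

filtered = hse_subnetwork(edges, positives)
print(f"HSE-positive Hsp genes: {len(positives)}; "
      f"edges kept in the heat-response subnetwork: {len(filtered)}/{len(edges)}")
# Co-expression above the strict threshold recovers within-block pairs;
# the HSE filter then keeps only interactions whose Hsp partner carries
# the promoter element an Hsf could bind directly.
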