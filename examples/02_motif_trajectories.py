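"""Place motif gains and losses on a species tree under Dollo parsimony.

An ancestral motif (M1) is carried by every species, while a novel motif
(M7) appears only in the two higher plants and was secondarily lost in one
of them — the classic single-gain / multiple-loss trajectory.
"""

import pandas as pd

from hsfkit.motifs import MotifMatrix, dollo_trajectory, species_motif_state, trajectory_table
from hsfkit.reconcile import species_tree_from_newick

# ((Ath,Osa) = higher plants, Cre = alga)
tree = species_tree_from_newick("((Ath,Osa),Cre);")
presence = pd.DataFrame(
    {
        "M1": [1, 1, 1, 1, 1],
        "M7": [1, 1, 1, 0, 0],  # absent from Osa gene and the alga
    },
    index=["ath_g1", "ath_g2", "osa_g1", "osa_g2", "cre_g1"],
)
gene_species = {
    "ath_g1": "Ath", "ath_g2": "Ath",
    "osa_g1": "Osa", "osa_g2": "Osa",
    "cre_g1": "Cre",
}

matrix = MotifMatrix(presence, gene_species)
states = species_motif_state(matrix)
for s in states:
    print(f"{s.species_id:>4} {s.motif_id}: {s.state}")

print(trajectory_table(dollo_trajectory(states, tree)).to_string(index=False))
# M1 gains on the root branch with no losses; M7 gains on the branch to
# the (Ath,Osa) clade. Osa is 'partial' (one of two genes), which still
# counts as presence, so M7 shows zero complete losses.
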