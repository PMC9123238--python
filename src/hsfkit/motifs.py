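"""Per-species motif states and Dollo gain/loss trajectories.

Conserved protein motifs (e.g. the ten MEME motifs of the Hsf family) are
summarised per species as complete / partial / absent, then placed on a
rooted species tree under Dollo parsimony: a motif is gained exactly once —
on the branch above the most recent common ancestor of all species carrying
it — and lost on the minimal set of branches explaining every absence
inside that clade. Lower plants carrying only an ancestral motif subset and
higher plants gaining novel motifs (with sporadic secondary losses) are the
motivating pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "MotifMatrix",
    "MotifState",
    "Trajectory",
    "species_motif_state",
    "dollo_trajectory",
]


@dataclass
class MotifMatrix:
    """Binary gene x motif presence/absence with a gene -> species map."""

    presence: pd.DataFrame  # index: gene_id, columns: motif ids, values 0/1
    gene_species: Mapping[str, str]

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        missing = set(self.presence.index) - set(self.gene_species)
        if missing:
            raise ValueError(f"genes without species mapping: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class MotifState:
    species_id: str
    motif_id: str
    state: str  # complete | partial | absent


@dataclass
class Trajectory:
    """Single-gain / multi-loss placement of one motif on the species tree.

    ``gain_branch`` is the label of the node whose subtending branch carries
    the gain (None when the motif is present nowhere); ``loss_branches`` are
    the branches (child-node labels) on which the motif was lost.
    """

    motif_id: str
    gain_branch: str | None
    loss_branches: list[str] = field(default_factory=list)

    @property
    def loss_count(self) -> int:
        return len(self.loss_branches)


def species_motif_state(matrix: MotifMatrix) -> list[MotifState]:
    """Classify each (species, motif) as complete, partial or absent.

    complete = every family gene of the species carries the motif;
    absent = none does; partial otherwise. Species must have >= 1 gene.
    """
    df = matrix.presence.copy()
    df["__sp"] = [matrix.gene_species[g] for g in df.index]
    out: list[MotifState] = []
    for sp, sub in df.groupby("__sp", sort=True):
        counts = sub.drop(columns="__sp")
        n = len(counts)
        if n == 0:
            raise ValueError(f"species {sp!r} has zero genes in the motif matrix")
        for motif in counts.columns:
            k = int(counts[motif].sum())
            state = "complete" if k == n else ("absent" if k == 0 else "partial")
            out.append(MotifState(str(sp), str(motif), state))
    return out


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or "node_" + "|".join(
        sorted(lf.taxon.label for lf in node.leaf_iter())
    )


def dollo_trajectory(
    states: list[MotifState], tree: dendropy.Tree, motif_id: str | None = None
) -> list[Trajectory]:
    """Dollo-parsimony gain branch and minimal loss branches per motif.

    A species counts as carrying the motif when its state is complete or
    partial (partial loss within a species is reported by
    :func:`species_motif_state`, not collapsed here). Losses are the maximal
    subtrees below the gain node containing no carrier — removing exactly
    those branches explains every absence, and no single-gain scenario can
    do it with fewer (verified by exhaustive enumeration in the test suite).
    Polytomies are handled as given.
    """
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    by_motif: dict[str, set[str]] = {}
    known_species = set()
    for st in states:
        known_species.add(st.species_id)
        by_motif.setdefault(st.motif_id, set())
        if st.state in ("complete", "partial"):
            by_motif[st.motif_id].add(st.species_id)
    unknown = known_species - set(leaves)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")

    motif_ids = [motif_id] if motif_id is not None else sorted(by_motif)
    out: list[Trajectory] = []
    for mid in motif_ids:
        present = by_motif.get(mid, set())
        if not present:
            out.append(Trajectory(mid, None, []))
            continue
        gain = tree.mrca(taxa=[leaves[sp].taxon for sp in present])
        losses: list[str] = []

        def collect(node: dendropy.Node) -> bool:
            # returns True if subtree contains a carrier; records maximal
            # carrier-free subtrees as losses
            if node.is_leaf():
                return node.taxon.label in present
            child_flags = [(c, collect(c)) for c in node.child_nodes()]
            if any(f for _, f in child_flags):
                for c, f in child_flags:
                    if not f:
                        losses.append(_node_label(c))
                return True
            return False

        collect(gain)
        out.append(Trajectory(mid, _node_label(gain), sorted(losses)))
    return out


def trajectory_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Tabular (motif, gain_branch, loss_branches, loss_count) view."""
    return pd.DataFrame(
        {
            "motif": [t.motif_id for t in trajectories],
            "gain_branch": [t.gain_branch for t in trajectories],
            "loss_branches": [";".join(t.loss_branches) for t in trajectories],
            "loss_count": [t.loss_count for t in trajectories],
        }
    )
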