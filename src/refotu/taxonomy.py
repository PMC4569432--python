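"""Identity-threshold taxonomic assignment of species-level units.

A unit's representative sequence is searched against the labelled reference
collection; the best-hit identity decides the deepest reliable rank:
species at >= 96% (the mapping threshold that separates known from novel
species), genus at 94-96%, phylum at 70-94%, unassigned below 70%.  Names at
genus/phylum come from the best hit's lineage even when the species rank is
not granted.  A second species within 0.3 identity percentage points of the
best is reported rather than arbitrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment import AlignmentKernel, DEFAULT_KERNEL, KmerIndex
from .mapping import AbundanceTable, SpeciesCluster
from .records import RefRecord

SPECIES_IDENTITY = 0.96
GENUS_IDENTITY = 0.94
PHYLUM_IDENTITY = 0.70
NEAR_TIE = 0.003

_LEVEL_RANK = {"species": 3, "genus": 2, "phylum": 1, "unassigned": 0}


@dataclass
class TaxonAssignment:
    cluster_id: str
    level: str                          # species | genus | phylum | unassigned
    name: str                           # best-hit species name ('' if none)
    genus: str
    phylum: str
    best_hit_identity: float
    secondary_hit: tuple[str, float] | None = None


class TaxonomyAssigner:
    """Similarity-search assigner over a lineage-labelled reference set."""

    def __init__(self, refs: Sequence[RefRecord], lineage: pd.DataFrame,
                 kernel: AlignmentKernel | None = None, top_n: int = 30):
        if lineage.empty:
            raise ValueError("reference lineage table is empty")
        missing = [r.id for r in refs if r.id not in lineage.index]
        if missing:
            raise ValueError(
                f"references without lineage labels: {missing[:5]}...")
        self.refs = list(refs)
        self.lineage = lineage
        self.kernel = kernel or DEFAULT_KERNEL
        self.top_n = top_n
        self._index = KmerIndex([r.sequence for r in refs])

    def assign(self, cluster: SpeciesCluster) -> TaxonAssignment:
        """Best-hit rank assignment for one species-level unit."""
        per_species: dict[str, float] = {}
        for ref_idx, _shared in self._index.rank(
                cluster.representative_seq, top_n=self.top_n):
            ref = self.refs[ref_idx]
            w0, w1 = self._index.window(cluster.representative_seq, ref_idx)
            res = self.kernel.align(cluster.representative_seq,
                                    ref.sequence[w0:w1])
            sp = str(self.lineage.loc[ref.id, "species"])
            if res.identity > per_species.get(sp, -1.0):
                per_species[sp] = res.identity
        if not per_species:
            return TaxonAssignment(cluster.cluster_id, "unassigned", "", "",
                                   "", 0.0)
        ranked = sorted(per_species.items(), key=lambda t: (-t[1], t[0]))
        best_sp, best_id = ranked[0]
        secondary = None
        if len(ranked) > 1 and best_id - ranked[1][1] <= NEAR_TIE:
            secondary = (ranked[1][0], ranked[1][1])
        row = self.lineage[self.lineage["species"] == best_sp].iloc[0]
        if best_id >= SPECIES_IDENTITY:
            level = "species"
        elif best_id >= GENUS_IDENTITY:
            level = "genus"
        elif best_id >= PHYLUM_IDENTITY:
            level = "phylum"
        else:
            level = "unassigned"
        return TaxonAssignment(
            cluster_id=cluster.cluster_id, level=level,
            name=best_sp if level != "unassigned" else "",
            genus=str(row["genus"]) if level != "unassigned" else "",
            phylum=str(row["phylum"]) if level != "unassigned" else "",
            best_hit_identity=best_id, secondary_hit=secondary)

    def assign_all(self, clusters: Sequence[SpeciesCluster]
                   ) -> dict[str, TaxonAssignment]:
        return {c.cluster_id: self.assign(c) for c in clusters}


def assign_cluster(cluster: SpeciesCluster, refs: Sequence[RefRecord],
                   lineage: pd.DataFrame,
                   kernel: AlignmentKernel | None = None) -> TaxonAssignment:
    return TaxonomyAssigner(refs, lineage, kernel).assign(cluster)


def aggregate_levels(table: AbundanceTable,
                     assignments: dict[str, TaxonAssignment],
                     levels: Sequence[str] = ("phylum", "genus", "species"),
                     ) -> dict[str, pd.DataFrame]:
    """Sum unit counts into per-level tables; too-shallow hits pool into
    'unclassified'.  Totals per sample are conserved at every level."""
    missing = [c for c in table.counts.index if c not in assignments]
    if missing:
        raise ValueError(f"clusters without assignments: {missing[:5]}")
    out: dict[str, pd.DataFrame] = {}
    for level in levels:
        labels = []
        for cid in table.counts.index:
            a = assignments[cid]
            if _LEVEL_RANK[a.level] >= _LEVEL_RANK[level]:
                labels.append(getattr(a, "name" if level == "species" else level))
            else:
                labels.append("unclassified")
        out[level] = table.counts.groupby(pd.Index(labels, name=level)).sum()
    return out
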