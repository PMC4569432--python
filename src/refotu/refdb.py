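"""Full-length 16S reference database construction.

Two stages: sequential quality filtering (length >= 1,400 bp, <= 3 ambiguous
bases, not flagged eukaryotic — applied in that order so the per-rule removal
counts are disjoint and sum with the survivors to the input size), then
greedy 99.8%-identity dereplication that collapses identical and
near-identical records into non-redundant clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import AlignmentKernel, greedy_cluster
from .records import RefRecord

MIN_LENGTH = 1400
MAX_AMBIGUOUS = 3
DEREP_IDENTITY = 0.998


@dataclass
class RefCluster99:
    """A non-redundant reference cluster at the dereplication threshold."""

    representative: str
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


def filter_references(
    records: Sequence[RefRecord],
    min_length: int = MIN_LENGTH,
    max_ambiguous: int = MAX_AMBIGUOUS,
) -> tuple[list[RefRecord], dict[str, int]]:
    """Sequentially remove short, ambiguous and eukaryote-flagged records.

    Returns the retained records (input order preserved) and the per-rule
    removal counts.  Rules are tested in order (length, then ambiguity, then
    eukaryote flag) so each removed record is charged to exactly one rule.
    """
    retained: list[RefRecord] = []
    counts = {"short": 0, "ambiguous": 0, "eukaryotic": 0, "retained": 0}
    for rec in records:
        if not rec.id or not rec.sequence:
            raise ValueError(f"malformed reference record: id={rec.id!r}")
        if rec.length < min_length:
            counts["short"] += 1
        elif rec.ambiguous_count > max_ambiguous:
            counts["ambiguous"] += 1
        elif rec.eukaryote_flag:
            counts["eukaryotic"] += 1
        else:
            retained.append(rec)
            counts["retained"] += 1
    return retained, counts


def dereplicate(
    records: Sequence[RefRecord],
    threshold: float = DEREP_IDENTITY,
    kernel: AlignmentKernel | None = None,
) -> list[RefCluster99]:
    """Greedy centroid dereplication of filtered references.

    Records are processed in descending length (ties by ascending id); each
    joins the first centroid whose semi-global identity reaches the
    threshold, otherwise founds a new cluster.  The result partitions the
    input.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"dereplication threshold must be in (0, 1], got {threshold}")
    clusters = greedy_cluster(
        [r.id for r in records], [r.sequence for r in records],
        threshold, kernel=kernel)
    return [RefCluster99(representative=c.representative, members=c.members)
            for c in clusters]


def cluster_map_frame(clusters: Sequence[RefCluster99]) -> pd.DataFrame:
    rows = [(c.representative, m) for c in clusters for m in c.members]
    return pd.DataFrame(rows, columns=["representative_id", "member_id"])


def write_cluster_map(clusters: Sequence[RefCluster99], path: str | Path) -> None:
    cluster_map_frame(clusters).to_csv(path, sep="\t", index=False)


def representatives(clusters: Sequence[RefCluster99],
                    records: Sequence[RefRecord]) -> list[RefRecord]:
    """The representative record of each dereplication cluster."""
    by_id = {r.id: r for r in records}
    return [by_id[c.representative] for c in clusters]
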