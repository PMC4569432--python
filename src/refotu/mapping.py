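"""Core profiling engine: best-hit read mapping, species-level clustering.

Reads are mapped to the non-redundant full-length reference set by best hit
(semi-global identity >= 96% and read coverage >= 90%).  References that
receive at least one read are clustered at 97% identity into species-level
"rclust" units; reads that fail mapping are clustered de novo at 96% into
"unmap_OTU" units.  Counts of reads per unit per sample form the abundance
table, from which units below 0.1% mean relative abundance in every group
are dropped.

Candidate references per read are ranked by shared 8-mers and aligned inside
a seeded window; a q-gram bound terminates the candidate scan once no
remaining reference can beat the current best hit.  Equivalence with the
exhaustive all-pairs scan is part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentKernel, DEFAULT_KERNEL, KmerIndex, greedy_cluster
from .records import ReadRecord, RefRecord

MIN_IDENTITY = 0.96
MIN_COVERAGE = 0.90
RCLUST_IDENTITY = 0.97
DENOVO_IDENTITY = 0.96
MIN_MEAN_REL = 0.001


@dataclass(frozen=True)
class HitRecord:
    read_id: str
    ref_id: str
    identity: float
    coverage: float


@dataclass
class SpeciesCluster:
    """A species-level unit: reference-backed (rclust) or de novo (unmap_OTU)."""

    cluster_id: str
    kind: str                     # 'rclust' | 'unmap_OTU'
    representative_id: str
    representative_seq: str
    member_ids: list[str]
    best_hit_species: tuple[str, float] | None = None


def map_reads(
    reads: Sequence[ReadRecord],
    refs: Sequence[RefRecord],
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
    top_n: int = 50,
    kernel: AlignmentKernel | None = None,
    k: int = 8,
) -> tuple[list[HitRecord], list[str]]:
    """Best-hit mapping of each read against the reference collection.

    Ties are broken by higher identity, then higher coverage, then smallest
    reference id.  Reads with no hit passing both thresholds are returned as
    unmapped ids.  Identical read sequences share one alignment pass.
    """
    if not refs:
        raise ValueError("empty reference collection")
    kernel = kernel or DEFAULT_KERNEL
    index = KmerIndex([r.sequence for r in refs], k=k)
    ref_ids = [r.id for r in refs]

    cache: dict[str, tuple[str, float, float] | None] = {}
    hits: list[HitRecord] = []
    unmapped: list[str] = []
    for read in reads:
        seq = read.sequence
        if seq not in cache:
            cache[seq] = _best_hit(seq, index, ref_ids, kernel,
                                   min_identity, min_coverage, top_n, k)
        best = cache[seq]
        if best is None:
            unmapped.append(read.id)
        else:
            hits.append(HitRecord(read.id, best[0], best[1], best[2]))
    return hits, unmapped


def _best_hit(seq, index, ref_ids, kernel, min_identity, min_coverage,
              top_n, k):
    L = len(seq)
    best = None  # (identity, coverage, ref_id)
    for ref_idx, shared in index.rank(seq, top_n=top_n):
        # no remaining candidate (sorted by shared k-mers) can beat this
        e_min = max(0, int(np.ceil(((L - k + 1) - shared) / k)))
        upper = 1.0 - e_min / (1.5 * L)
        floor = min_identity if best is None else max(min_identity, best[0])
        if upper < floor - 1e-12:
            break
        w0, w1 = index.window(seq, ref_idx)
        res = kernel.align(seq, index.sequences[ref_idx][w0:w1])
        if res.identity < min_identity or res.coverage < min_coverage:
            continue
        cand = (res.identity, res.coverage, ref_ids[ref_idx])
        if best is None or (cand[0], cand[1], _neg(cand[2])) > (best[0], best[1], _neg(best[2])):
            best = cand
    if best is None:
        return None
    return (best[2], best[0], best[1])


class _neg:
    """Reverse-order wrapper so lexicographically smaller ids win ties."""

    __slots__ = ("s",)

    def __init__(self, s):
        self.s = s

    def __lt__(self, other):
        return self.s > other.s

    def __gt__(self, other):
        return self.s < other.s

    def __eq__(self, other):
        return self.s == other.s


def build_rclust(
    hits: Sequence[HitRecord],
    refs: Sequence[RefRecord],
    threshold: float = RCLUST_IDENTITY,
    kernel: AlignmentKernel | None = None,
) -> tuple[list[SpeciesCluster], dict[str, str]]:
    """Cluster the hit references at 97% into species-level rclust units.

    Only references that received at least one best hit are clustered.
    Returns the clusters and a reference-id -> cluster-id map through which
    each read's count is transferred (reads are never re-mapped to cluster
    representatives).
    """
    if not hits:
        raise ValueError("no hits to cluster")
    by_id = {r.id: r for r in refs}
    hit_ids = sorted({h.ref_id for h in hits})
    raw = greedy_cluster(hit_ids, [by_id[i].sequence for i in hit_ids],
                         threshold, kernel=kernel)
    clusters: list[SpeciesCluster] = []
    ref_to_cluster: dict[str, str] = {}
    for i, c in enumerate(raw, start=1):
        cid = f"rclust{i:05d}"
        clusters.append(SpeciesCluster(
            cluster_id=cid, kind="rclust",
            representative_id=c.representative,
            representative_seq=by_id[c.representative].sequence,
            member_ids=list(c.members)))
        for m in c.members:
            ref_to_cluster[m] = cid
    return clusters, ref_to_cluster


def cluster_unmapped(
    reads: Sequence[ReadRecord],
    threshold: float = DENOVO_IDENTITY,
    kernel: AlignmentKernel | None = None,
) -> tuple[list[SpeciesCluster], dict[str, str]]:
    """De-novo greedy clustering of unmapped reads into unmap_OTU units."""
    if not reads:
        return [], {}
    raw = greedy_cluster([r.id for r in reads], [r.sequence for r in reads],
                         threshold, kernel=kernel)
    seq_by_id = {r.id: r.sequence for r in reads}
    clusters: list[SpeciesCluster] = []
    read_to_cluster: dict[str, str] = {}
    for i, c in enumerate(raw, start=1):
        cid = f"unmap_OTU{i:05d}"
        clusters.append(SpeciesCluster(
            cluster_id=cid, kind="unmap_OTU",
            representative_id=c.representative,
            representative_seq=seq_by_id[c.representative],
            member_ids=list(c.members)))
        for m in c.members:
            read_to_cluster[m] = cid
    return clusters, read_to_cluster


# ---------------------------------------------------------------------------
# abundance table


@dataclass
class AbundanceTable:
    """Cluster x sample read counts at a fixed per-sample depth."""

    counts: pd.DataFrame          # clusters x samples
    groups: pd.Series             # sample id -> group label
    depth: int = 3000
    kinds: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self):
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups[self.groups.isna()].index)
            raise ValueError(f"samples without group labels: {missing}")
        if self.kinds.empty and len(self.counts.index):
            self.kinds = pd.Series(
                ["unmap_OTU" if str(c).startswith("unmap_OTU") else "rclust"
                 for c in self.counts.index], index=self.counts.index)

    @property
    def relative(self) -> pd.DataFrame:
        return self.counts / self.depth

    def group_mean_relative(self) -> pd.DataFrame:
        """Unweighted per-group mean relative abundance (clusters x groups)."""
        return self.relative.T.groupby(self.groups).mean().T

    def subset(self, cluster_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.counts.loc[list(cluster_ids)], self.groups,
                              self.depth, self.kinds.reindex(cluster_ids))


def assemble_table(
    hits: Sequence[HitRecord],
    ref_to_cluster: dict[str, str],
    read_to_otu: dict[str, str],
    reads: Sequence[ReadRecord],
    groups: pd.Series,
    depth: int = 3000,
    cluster_order: Sequence[str] | None = None,
) -> AbundanceTable:
    """Count reads per species-level unit per sample."""
    sample_of = {r.id: r.sample_id for r in reads}
    samples = sorted({r.sample_id for r in reads})
    tallies: dict[tuple[str, str], int] = {}
    for h in hits:
        key = (ref_to_cluster[h.ref_id], sample_of[h.read_id])
        tallies[key] = tallies.get(key, 0) + 1
    for read_id, cid in read_to_otu.items():
        key = (cid, sample_of[read_id])
        tallies[key] = tallies.get(key, 0) + 1
    if cluster_order is None:
        cluster_order = sorted({c for c, _s in tallies})
    counts = pd.DataFrame(0, index=list(cluster_order), columns=samples,
                          dtype=int)
    for (cid, sid), n in tallies.items():
        counts.at[cid, sid] = n
    kinds = pd.Series(
        ["rclust" if c.startswith("rclust") else "unmap_OTU"
         for c in counts.index], index=counts.index)
    return AbundanceTable(counts, groups, depth, kinds)


def abundance_filter(
    table: AbundanceTable,
    min_mean_rel: float = MIN_MEAN_REL,
) -> tuple[AbundanceTable, dict[str, int]]:
    """Keep units whose mean relative abundance reaches the floor in >= 1 group.

    Returns the filtered table and per-kind removal counts.
    """
    for g, n in table.groups.value_counts().items():
        if n == 0:
            raise ValueError(f"group {g} has no samples")
    if table.groups.nunique() < 1:
        raise ValueError("no group labels")
    gm = table.group_mean_relative()
    keep = (gm >= min_mean_rel).any(axis=1)
    removed = table.counts.index[~keep]
    removal = {"rclust": 0, "unmap_OTU": 0}
    for cid in removed:
        kind = table.kinds.get(cid, "rclust")
        removal[kind] = removal.get(kind, 0) + 1
    return table.subset(list(table.counts.index[keep])), removal
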