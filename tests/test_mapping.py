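"""Best-hit mapping, species-cluster construction, abundance filtering."""

import numpy as np
import pandas as pd
import pytest

from refotu.alignment import DEFAULT_KERNEL
from refotu.mapping import (AbundanceTable, abundance_filter, assemble_table,
                            build_rclust, cluster_unmapped, map_reads)
from refotu.records import ReadRecord, RefRecord

from conftest import mutate, random_dna


def _refs(n, length, rng):
    return [RefRecord(id=f"R{i:02d}", sequence=random_dna(rng, length))
            for i in range(n)]


def _read(seq, id_="r", sid="S1"):
    return ReadRecord(id=id_, sequence=seq, qualities=[30] * len(seq),
                      sample_id=sid)


def exhaustive_best_hits(reads, refs, min_identity, min_coverage, kernel):
    """All-pairs semi-global oracle with the documented tie-breaks."""
    out = {}
    for read in reads:
        best = None
        for ref in refs:
            res = kernel.align(read.sequence, ref.sequence)
            if res.identity < min_identity or res.coverage < min_coverage:
                continue
            key = (res.identity, res.coverage)
            if best is None or key > best[0] or (key == best[0]
                                                 and ref.id < best[1]):
                best = (key, ref.id)
        out[read.id] = None if best is None else best[1]
    return out


class TestMapReads:
    def test_exact_substring_maps_at_full_identity(self):
        rng = np.random.default_rng(0)
        refs = _refs(5, 900, rng)
        read = _read(refs[3].sequence[200:500], id_="q")
        hits, unmapped = map_reads([read], refs)
        assert unmapped == []
        assert hits[0].ref_id == "R03"
        assert hits[0].identity == 1.0 and hits[0].coverage == 1.0

    def test_ten_percent_divergence_goes_unmapped(self):
        rng = np.random.default_rng(1)
        refs = _refs(3, 900, rng)
        read = _read(mutate(refs[0].sequence[100:400], 30, rng), id_="q")
        hits, unmapped = map_reads([read], refs)
        assert hits == [] and unmapped == ["q"]

    def test_matches_exhaustive_alignment_oracle(self):
        rng = np.random.default_rng(2)
        refs = _refs(15, 700, rng)
        reads = []
        for i in range(120):
            src = refs[int(rng.integers(0, len(refs)))]
            start = int(rng.integers(0, 350))
            n_sub = int(rng.integers(0, 20))  # 0-6.6% divergence
            reads.append(_read(mutate(src.sequence[start:start + 300],
                                      n_sub, rng), id_=f"q{i:03d}"))
        hits, unmapped = map_reads(reads, refs)
        oracle = exhaustive_best_hits(reads, refs, 0.96, 0.90, DEFAULT_KERNEL)
        got = {h.read_id: h.ref_id for h in hits}
        got.update({rid: None for rid in unmapped})
        assert got == oracle

    def test_raising_identity_threshold_shrinks_mapped_set(self):
        rng = np.random.default_rng(3)
        refs = _refs(6, 700, rng)
        reads = [_read(mutate(refs[i % 6].sequence[50:350],
                              int(rng.integers(0, 18)), rng), id_=f"q{i}")
                 for i in range(60)]
        mapped = {}
        for thr in (0.90, 0.94, 0.98):
            hits, _ = map_reads(reads, refs, min_identity=thr)
            mapped[thr] = {h.read_id for h in hits}
        assert mapped[0.98] <= mapped[0.94] <= mapped[0.90]

    def test_empty_reference_collection_is_config_error(self):
        with pytest.raises(ValueError):
            map_reads([_read("ACGT" * 50)], [])


class TestBuildRclust:
    def test_similar_references_merge_and_divergent_split(self):
        rng = np.random.default_rng(4)
        base = random_dna(rng, 1000)
        refs = [RefRecord(id="A", sequence=base),
                RefRecord(id="B", sequence=mutate(base, 20, rng)),   # 98%
                RefRecord(id="C", sequence=mutate(base, 100, rng))]  # 90%
        reads = [_read(base[:300], id_="r1"), _read(refs[2].sequence[:300], "r2")]
        hits, _ = map_reads(reads, refs)
        # make every reference a hit target
        from refotu.mapping import HitRecord
        hits = [HitRecord("r1", "A", 1.0, 1.0), HitRecord("r1b", "B", 0.99, 1.0),
                HitRecord("r2", "C", 1.0, 1.0)]
        clusters, ref_to_cluster = build_rclust(hits, refs, threshold=0.97)
        assert len(clusters) == 2
        assert ref_to_cluster["A"] == ref_to_cluster["B"]
        assert ref_to_cluster["C"] != ref_to_cluster["A"]

    def test_only_hit_references_are_clustered(self):
        rng = np.random.default_rng(5)
        refs = _refs(4, 800, rng)
        from refotu.mapping import HitRecord
        hits = [HitRecord("r1", "R00", 1.0, 1.0)]
        clusters, _ = build_rclust(hits, refs)
        assert len(clusters) == 1 and clusters[0].member_ids == ["R00"]


class TestClusterUnmapped:
    def test_empty_input(self):
        assert cluster_unmapped([]) == ([], {})

    def test_identical_reads_form_one_otu(self):
        reads = [_read("ACGT" * 75, id_=f"r{i}") for i in range(7)]
        clusters, mapping = cluster_unmapped(reads)
        assert len(clusters) == 1
        assert len(clusters[0].member_ids) == 7
        assert set(mapping.values()) == {clusters[0].cluster_id}

    def test_three_planted_species_recovered(self):
        rng = np.random.default_rng(6)
        species = [random_dna(rng, 300) for _ in range(3)]
        reads = []
        for s, base in enumerate(species):
            for i in range(10):
                reads.append(_read(mutate(base, int(rng.integers(0, 3)), rng),
                                   id_=f"s{s}r{i}"))
        clusters, _ = cluster_unmapped(reads, threshold=0.96)
        assert len(clusters) == 3
        for c in clusters:
            sources = {m[:2] for m in c.member_ids}
            assert len(sources) == 1


def printed_composition_table():
    """Counts matching the published retention arithmetic: 760 reference
    clusters of which 101 reach 0.1% mean relative abundance in a group, and
    1,321 de-novo OTUs of which 29 do, over 40 + 20 samples at depth 3,000."""
    n_hc, n_ms = 40, 20
    samples = [f"HC{i:02d}" for i in range(n_hc)] + \
              [f"MS{i:02d}" for i in range(n_ms)]
    groups = pd.Series(["HC"] * n_hc + ["MS"] * n_ms, index=samples)
    rows, index = [], []

    def add(prefix, n_pass, n_fail, start=1):
        for i in range(n_pass):
            index.append(f"{prefix}{start + i:05d}")
            rows.append([6] * n_hc + [3] * n_ms)        # 0.2% / 0.1%
        for i in range(n_fail):
            index.append(f"{prefix}{start + n_pass + i:05d}")
            row = [0] * (n_hc + n_ms)
            row[i % (n_hc + n_ms)] = 1                   # mean << 0.1%
            rows.append(row)

    add("rclust", 101, 659)
    add("unmap_OTU", 29, 1292)
    counts = pd.DataFrame(rows, index=index, columns=samples)
    return AbundanceTable(counts, groups, depth=3000)


class TestAbundanceFilter:
    def test_printed_retention_arithmetic(self):
        table = printed_composition_table()
        filtered, removed = abundance_filter(table, min_mean_rel=0.001)
        assert filtered.counts.shape[0] == 130
        assert removed == {"rclust": 659, "unmap_OTU": 1292}
        kinds = filtered.kinds.value_counts()
        assert kinds["rclust"] == 101 and kinds["unmap_OTU"] == 29

    def test_boundary_exactly_one_permille_in_one_group_is_retained(self):
        samples = ["HC1", "HC2", "MS1", "MS2"]
        groups = pd.Series(["HC", "HC", "MS", "MS"], index=samples)
        counts = pd.DataFrame(
            {"HC1": [3, 0], "HC2": [3, 0], "MS1": [0, 0], "MS2": [0, 0]},
            index=["rclust00001", "rclust00002"])
        table = AbundanceTable(counts, groups, depth=3000)
        filtered, removed = abundance_filter(table)
        assert list(filtered.counts.index) == ["rclust00001"]
        assert removed["rclust"] == 1

    def test_group_means_are_unweighted_sample_means(self):
        table = printed_composition_table()
        gm = table.group_mean_relative()
        assert gm.loc["rclust00001", "HC"] == pytest.approx(6 / 3000)
        assert gm.loc["rclust00001", "MS"] == pytest.approx(3 / 3000)


def test_assemble_table_conserves_reads():
    rng = np.random.default_rng(8)
    refs = _refs(3, 600, rng)
    reads = []
    for i in range(30):
        src = refs[i % 2]
        reads.append(_read(src.sequence[100:400], id_=f"q{i:02d}",
                           sid=f"S{i % 3}"))
    for i in range(6):  # unmappable reads
        reads.append(_read(random_dna(rng, 300), id_=f"u{i}", sid=f"S{i % 3}"))
    hits, unmapped = map_reads(reads, refs)
    clusters, ref_to_cluster = build_rclust(hits, refs)
    uclusters, read_to_otu = cluster_unmapped(
        [r for r in reads if r.id in set(unmapped)])
    groups = pd.Series({"S0": "HC", "S1": "HC", "S2": "MS"})
    table = assemble_table(hits, ref_to_cluster, read_to_otu, reads, groups,
                           depth=12)
    assert int(table.counts.to_numpy().sum()) == len(reads)
    assert (table.counts.sum(axis=0) == 12).all()
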