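"""Synthetic 16S V1-V2 study generator with full ground truth.

Everything the pipeline consumes can be generated here: a full-length
reference collection with planted quality defects and near-identical
redundancy, per-sample amplicon read sets for a case/control design with
planted differentially abundant species, and a longitudinal healthy-control
series.  The community is evolved along a random birth-death phylogeny, so
the generating tree is itself ground truth for the phylogenetics stage, and
a subset of community species is withheld from the reference collection so
that a realistic fraction of reads fails reference mapping and must be
clustered de novo.

Scale defaults mirror the emulated study design: 20 case (MS) and 40 control
(HC) cross-sectional samples, 18 longitudinal control subjects sampled at 9
timepoints, negative-binomial per-sample read totals around 7,080 +/- 825
(case) and 7,590 +/- 616 (control), a 3,000-read profiling depth, a per-base
substitution error rate of 0.5%, and 21 planted effects (2 enriched, 19
depleted, |log10 FC| between 0.4 and 1.8).
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .records import ReadRecord, RefRecord, write_fastq, write_reference_fasta

# The study's amplification primers for the 16S V1-V2 region.
FORWARD_PRIMER = "AGRGTTTGATYMTGGCTCAG"   # 27Fmod
REVERSE_PRIMER = "TGCTGCCTCCCGTAGGAGT"    # 338R

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# Default planted log10(MS/HC) effects: 2 enrichments and 19 depletions whose
# magnitudes span 0.4-1.8.  Six of the depletions are placed on species absent
# from the reference so they surface as de-novo OTUs.
DEFAULT_EFFECTS_REFERENCE = (0.45, 0.44, -0.43, -0.50, -0.66, -0.82, -0.82,
                             -0.83, -0.86, -1.07, -1.11, -1.43, -1.77, -0.40,
                             -0.40)
DEFAULT_EFFECTS_NOVEL = (-0.46, -0.63, -0.92, -1.08, -1.11, -1.15)


def substream(seed: int, *parts: int | str) -> np.random.Generator:
    """Independent RNG substream derived from the run seed and stable keys."""
    words = [int(seed) & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            words.append(zlib.crc32(p.encode()) & 0x7FFFFFFF)
        else:
            words.append(int(p) & 0x7FFFFFFF)
    return np.random.default_rng(words)


@dataclass
class SimConfig:
    """Study-design knobs for the generator.

    ``planted_effects`` is a tuple of (community species index, log10 fold
    change) pairs; ``None`` selects the default 21-effect panel.  Defect
    counts are (short, ambiguous, eukaryotic) reference records to plant.
    """

    seed: int = 0
    n_ref_species: int = 160
    n_novel_species: int = 12
    n_community_species: int = 130
    defect_counts: tuple[int, int, int] = (0, 0, 0)
    redundancy_per_species: int | Sequence[int] = 1
    n_case_samples: int = 20
    n_control_samples: int = 40
    n_longitudinal_subjects: int = 18
    n_timepoints: int = 9
    reads_per_sample: int = 3000
    mean_reads_case: float = 7080.0
    sd_reads_case: float = 825.0
    mean_reads_control: float = 7590.0
    sd_reads_control: float = 616.0
    planted_effects: tuple[tuple[int, float], ...] | None = None
    error_rate: float = 0.005
    quality_profile: tuple[float, float] = (32.0, 6.0)
    low_quality_fraction: float = 0.06
    low_quality_mean: float = 20.0
    concentration_control: float = 500.0
    concentration_case: float = 250.0
    seq_length: int = 1500
    insert_length: int = 300
    min_tip_length: float = 0.04
    tree_height: float = 0.12

    def validate(self) -> None:
        if self.reads_per_sample < 3000:
            raise ValueError("reads_per_sample must be >= 3000 (profiling depth)")
        if self.n_community_species > self.n_ref_species + self.n_novel_species:
            raise ValueError("community larger than the species pool")
        if self.n_novel_species > self.n_community_species:
            raise ValueError("more novel species than community species")
        if any(c < 0 for c in self.defect_counts):
            raise ValueError("defect counts must be non-negative")
        if self.planted_effects is not None:
            for idx, _fc in self.planted_effects:
                if not (0 <= idx < self.n_community_species):
                    raise ValueError(f"planted species index {idx} out of range")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be a probability")

    def redundancy_list(self) -> list[int]:
        if isinstance(self.redundancy_per_species, int):
            return [self.redundancy_per_species] * self.n_ref_species
        r = list(self.redundancy_per_species)
        if len(r) != self.n_ref_species:
            raise ValueError("redundancy list length must equal n_ref_species")
        return r


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    species_sequences: dict[str, str]
    generating_tree: dendropy.Tree
    lineage: pd.DataFrame                 # species -> genus, phylum
    community_species: list[str]
    novel_species: list[str]
    base_proportions: dict[str, float]    # control-group expectation
    case_proportions: dict[str, float]    # after planted effects + closure
    planted: dict[str, float]             # species id -> log10 fold change
    insert_start: int
    insert_end: int
    amplicon_start: int
    amplicon_end: int
    sample_composition: dict[str, dict[str, float]] = field(default_factory=dict)

    def insert(self, species: str) -> str:
        return self.species_sequences[species][self.insert_start:self.insert_end]

    def amplicon(self, species: str) -> str:
        return self.species_sequences[species][self.amplicon_start:self.amplicon_end]

    def tree_newick(self) -> str:
        return self.generating_tree.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# species backbone


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    from .alignment import IUPAC_SETS
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in primer)


def _evolve_tree_sequences(tree: dendropy.Tree, root_seq: np.ndarray,
                           mutable: np.ndarray,
                           rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Substitution-only evolution of the root sequence along the tree."""
    seqs: dict[str, np.ndarray] = {}
    mut_pos = np.flatnonzero(mutable)

    def descend(node, seq):
        for child in node.child_nodes():
            d = min(max(child.edge.length or 0.0, 0.0), 0.70)
            child_seq = seq.copy()
            hit = mut_pos[rng.random(len(mut_pos)) < d]
            if len(hit):
                child_seq[hit] = (child_seq[hit] + rng.integers(1, 4, len(hit))) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    root = tree.seed_node
    if root.is_leaf():
        seqs[root.taxon.label] = root_seq.copy()
    descend(root, root_seq)
    return seqs


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _build_backbone(config: SimConfig):
    """Random birth-death tree plus evolved species sequences and lineages."""
    n_total = config.n_ref_species + config.n_novel_species
    py_rng = random.Random(int(substream(config.seed, "tree").integers(2**31)))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.4, num_extant_tips=n_total, rng=py_rng)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"SP{i:04d}"

    # scale to the target height, then enforce a minimum tip edge so every
    # species pair is safely below the 96% mapping threshold
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    scale = config.tree_height / max(max(depths), 1e-9)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * scale
    for leaf in tree.leaf_node_iter():
        if (leaf.edge.length or 0.0) < config.min_tip_length:
            leaf.edge.length = config.min_tip_length

    rng = substream(config.seed, "backbone")
    L = config.seq_length
    root = rng.integers(0, 4, L).astype(np.uint8)
    fwd_site = _resolve_iupac(FORWARD_PRIMER, rng)
    rev_site_plus = _revcomp_str(REVERSE_PRIMER)
    a0 = 10                                  # amplicon start (fwd primer site)
    i0 = a0 + len(FORWARD_PRIMER)            # insert start
    i1 = i0 + config.insert_length           # insert end
    a1 = i1 + len(REVERSE_PRIMER)            # amplicon end
    if a1 + 50 > L:
        raise ValueError("seq_length too short for the amplicon layout")
    root[a0:i0] = [_BASE_INDEX[c] for c in fwd_site]
    root[i1:a1] = [_BASE_INDEX[c] for c in rev_site_plus]
    mutable = np.ones(L, dtype=bool)
    mutable[a0:i0] = False
    mutable[i1:a1] = False

    raw = _evolve_tree_sequences(tree, root, mutable, rng)
    species_sequences = {sp: _codes_to_str(raw[sp]) for sp in sorted(raw)}

    # genus/phylum labels from patristic structure so taxonomy has a truth
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    Z = linkage(squareform(dm, checks=False), method="average")
    phyla = fcluster(Z, t=4, criterion="maxclust")
    genera = fcluster(Z, t=max(4, n // 6), criterion="maxclust")
    lineage = pd.DataFrame({
        "species": [t.label for t in taxa],
        "genus": [f"Genus{g:03d}" for g in genera],
        "phylum": [f"Phylum{p:02d}" for p in phyla],
    }).set_index("species")
    return tree, species_sequences, lineage, (a0, i0, i1, a1)


def _revcomp_str(seq: str) -> str:
    from .alignment import reverse_complement
    return reverse_complement(seq)


# ---------------------------------------------------------------------------
# reference database with planted defects


def _mutate_copy(codes: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    if n_sub:
        pos = rng.choice(len(codes), size=n_sub, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, n_sub)) % 4
    return out


def generate_reference_db(config: SimConfig) -> tuple[list[RefRecord], GroundTruth]:
    """Reference records (clean + planted defects) and the ground truth.

    Clean records are >= 1,400 bp with <= 3 ambiguous bases; the three defect
    classes (short, ambiguous, flagged-eukaryotic) are disjoint by
    construction so a sequential filter removes exactly the planted counts.
    """
    config.validate()
    tree, species_sequences, lineage, layout = _build_backbone(config)
    a0, i0, i1, a1 = layout
    rng = substream(config.seed, "refdb")

    species = sorted(species_sequences)
    perm = rng.permutation(len(species))
    ref_backed = [species[i] for i in perm[:config.n_ref_species]]
    novel = sorted(species[i] for i in perm[config.n_ref_species:])
    n_comm_ref = config.n_community_species - len(novel)
    community = sorted(ref_backed[:n_comm_ref]) + novel

    truth = GroundTruth(
        species_sequences=species_sequences,
        generating_tree=tree,
        lineage=lineage,
        community_species=community,
        novel_species=novel,
        base_proportions={},
        case_proportions={},
        planted={},
        insert_start=i0, insert_end=i1, amplicon_start=a0, amplicon_end=a1,
    )
    _plant_community(config, truth, rng)

    records: list[RefRecord] = []
    redundancy = config.redundancy_list()
    for sp, n_copies in zip(ref_backed, redundancy):
        codes = np.frombuffer(species_sequences[sp].encode(), dtype=np.uint8)
        codes = np.searchsorted(_BASES, codes).astype(np.uint8)  # ACGT -> 0..3
        for c in range(n_copies):
            n_sub = 0 if c == 0 else int(rng.integers(0, 3))
            copy = codes if n_sub == 0 else _mutate_copy(codes, n_sub, rng)
            records.append(RefRecord(
                id=f"REF_{sp}_{c:03d}",
                sequence=_codes_to_str(copy),
                source=sp,
            ))

    n_short, n_ambig, n_euk = config.defect_counts
    for j in range(n_short):
        length = int(rng.integers(600, 1400))
        seq = _codes_to_str(rng.integers(0, 4, length).astype(np.uint8))
        records.append(RefRecord(id=f"SHORT_{j:06d}", sequence=seq, source="defect"))
    ambig_codes = np.frombuffer(b"NRYWSKM", dtype=np.uint8)
    for j in range(n_ambig):
        base = rng.integers(0, 4, config.seq_length).astype(np.uint8)
        seq = bytearray(_BASES[base])
        n_amb = int(rng.integers(4, 9))
        for pos in rng.choice(config.seq_length, n_amb, replace=False):
            seq[pos] = int(rng.choice(ambig_codes))
        records.append(RefRecord(id=f"AMBIG_{j:06d}", sequence=bytes(seq).decode(),
                                 source="defect"))
    for j in range(n_euk):
        seq = _codes_to_str(rng.integers(0, 4, config.seq_length).astype(np.uint8))
        records.append(RefRecord(id=f"EUK_{j:06d}", sequence=seq,
                                 eukaryote_flag=True, source="defect"))
    return records, truth


def _plant_community(config: SimConfig, truth: GroundTruth,
                     rng: np.random.Generator) -> None:
    """Draw base proportions and apply the planted effects under closure."""
    community = truth.community_species
    novel = set(truth.novel_species)
    ref_comm = [sp for sp in community if sp not in novel]

    if config.planted_effects is None:
        planted_ref = [str(sp) for sp in
                       rng.permutation(ref_comm)[:len(DEFAULT_EFFECTS_REFERENCE)]]
        planted_nov = [str(sp) for sp in
                       rng.permutation(sorted(novel))[:len(DEFAULT_EFFECTS_NOVEL)]]
        effects = dict(zip(planted_ref, DEFAULT_EFFECTS_REFERENCE))
        effects.update(dict(zip(planted_nov, DEFAULT_EFFECTS_NOVEL)))
    else:
        effects = {community[idx]: fc for idx, fc in config.planted_effects}

    # planted species (and non-planted novel species) get absolute control
    # proportions drawn log-uniformly; the non-planted reference-backed
    # background shares the remaining mass via lognormal weights
    base = {}
    for sp in community:
        if sp in effects:
            base[sp] = float(10 ** rng.uniform(np.log10(0.005), np.log10(0.03)))
        elif sp in novel:
            base[sp] = float(10 ** rng.uniform(np.log10(0.002), np.log10(0.01)))
    assigned = sum(base.values())
    if assigned >= 0.8:
        raise ValueError(
            "planted + novel species claim >= 80% of the community; reduce "
            "their number or the community design")
    background = [sp for sp in community if sp not in base]
    if background:
        weights = np.exp(rng.normal(0.0, 1.0, len(background)))
        weights *= (1.0 - assigned) / weights.sum()
        for sp, w in zip(background, weights):
            base[sp] = float(w)
    else:  # every species planted or novel: renormalise directly
        base = {sp: p / assigned for sp, p in base.items()}

    case = {sp: p * (10 ** effects[sp]) if sp in effects else p
            for sp, p in base.items()}
    planted_mass = sum(case[sp] for sp in effects)
    base_planted_mass = sum(base[sp] for sp in effects)
    if base_planted_mass < 1.0:
        scale = (1.0 - planted_mass) / (1.0 - base_planted_mass)
        for sp in case:
            if sp not in effects:
                case[sp] = case[sp] * scale
    total = sum(case.values())
    case = {sp: p / total for sp, p in case.items()}

    truth.base_proportions = base
    truth.case_proportions = case
    truth.planted = effects


# ---------------------------------------------------------------------------
# amplicon read sets


def _negbin_reads(mean: float, sd: float, floor: int,
                  rng: np.random.Generator) -> int:
    var = sd * sd
    if var > mean:
        r = mean * mean / (var - mean)
        n = int(rng.negative_binomial(r, r / (r + mean)))
    else:
        n = int(rng.poisson(mean))
    return max(n, floor)


def _sample_composition(config: SimConfig, truth: GroundTruth, group: str,
                        rng: np.random.Generator,
                        base: dict[str, float] | None = None) -> np.ndarray:
    props = base if base is not None else (
        truth.case_proportions if group == "MS" else truth.base_proportions)
    conc = (config.concentration_case if group == "MS"
            else config.concentration_control)
    alpha = np.array([props[sp] for sp in truth.community_species]) * conc
    return rng.dirichlet(np.maximum(alpha, 1e-6))


def _reads_for_sample(config: SimConfig, truth: GroundTruth, sample_id: str,
                      comp: np.ndarray, n_reads: int,
                      rng: np.random.Generator) -> list[ReadRecord]:
    counts = rng.multinomial(n_reads, comp)
    qa_mean, qa_sd = config.quality_profile
    reads: list[ReadRecord] = []
    species_of: list[str] = []
    ridx = 0
    for sp, cnt in zip(truth.community_species, counts):
        if cnt == 0:
            continue
        amp = truth.amplicon(sp)
        codes = np.searchsorted(_BASES, np.frombuffer(amp.encode(), np.uint8))
        block = np.tile(codes.astype(np.uint8), (cnt, 1))
        if config.error_rate > 0:
            mask = rng.random(block.shape) < config.error_rate
            n_err = int(mask.sum())
            if n_err:
                block[mask] = (block[mask] + rng.integers(1, 4, n_err)) % 4
        lowq = rng.random(cnt) < config.low_quality_fraction
        read_means = np.where(lowq,
                              rng.normal(config.low_quality_mean, 2.0, cnt),
                              rng.normal(qa_mean, 3.0, cnt))
        quals = rng.normal(read_means[:, None], qa_sd, block.shape)
        quals = np.clip(np.rint(quals), 2, 40).astype(np.uint8)
        seqs = _BASES[block]
        for i in range(cnt):
            reads.append(ReadRecord(
                id=f"{sample_id}_r{ridx:06d}",
                sequence=seqs[i].tobytes().decode(),
                qualities=quals[i],
                sample_id=sample_id,
            ))
            species_of.append(sp)
            ridx += 1
    # deterministic shuffle so species are interleaved as on a sequencer;
    # read ids carry the true source species for ground-truth tracing
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    for new_i, old_i in enumerate(order):
        reads[new_i].id = f"{sample_id}_r{new_i:06d}_{species_of[old_i]}"
    return reads


def read_species(read_id: str) -> str:
    """True source species encoded in a simulated read's id."""
    return read_id.rsplit("_", 1)[-1]


def sample_sheet(config: SimConfig,
                 cohorts: Sequence[str] = ("case", "control", "longitudinal"),
                 ) -> pd.DataFrame:
    """Sample metadata: sample_id, subject_id, group, timepoint."""
    rows = []
    if "case" in cohorts:
        for i in range(1, config.n_case_samples + 1):
            rows.append((f"MS{i:02d}", f"MS{i:02d}", "MS", 0))
    if "control" in cohorts:
        for i in range(1, config.n_control_samples + 1):
            rows.append((f"HC{i:02d}", f"HC{i:02d}", "HC", 0))
    if "longitudinal" in cohorts:
        for s in range(1, config.n_longitudinal_subjects + 1):
            for t in range(1, config.n_timepoints + 1):
                rows.append((f"LHC{s:02d}_T{t}", f"LHC{s:02d}", "HC", t))
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "group",
                                       "timepoint"])


def generate_samples(config: SimConfig, truth: GroundTruth,
                     cohorts: Sequence[str] = ("case", "control", "longitudinal"),
                     ) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame]:
    """Per-sample read collections plus the sample sheet.

    Longitudinal subjects keep a persistent subject-level composition across
    timepoints (with small per-timepoint wobble) so planted effects stay
    directionally stable over the series.
    """
    config.validate()
    sheet = sample_sheet(config, cohorts)
    samples: dict[str, list[ReadRecord]] = {}
    subject_base: dict[str, dict[str, float]] = {}

    for row in sheet.itertuples(index=False):
        rng = substream(config.seed, "sample", row.sample_id)
        if row.timepoint and row.subject_id not in subject_base:
            srng = substream(config.seed, "subject", row.subject_id)
            comp0 = _sample_composition(config, truth, row.group, srng)
            subject_base[row.subject_id] = dict(
                zip(truth.community_species, comp0))
        if row.timepoint:
            base = subject_base[row.subject_id]
            alpha = np.array([base[sp] for sp in truth.community_species])
            comp = rng.dirichlet(np.maximum(alpha * 2000.0, 1e-6))
        else:
            comp = _sample_composition(config, truth, row.group, rng)
        if row.group == "MS":
            mean, sd = config.mean_reads_case, config.sd_reads_case
        else:
            mean, sd = config.mean_reads_control, config.sd_reads_control
        floor = int(config.reads_per_sample /
                    max(1.0 - config.low_quality_fraction, 0.5) * 1.15)
        n_reads = _negbin_reads(mean, sd, floor, rng)
        samples[row.sample_id] = _reads_for_sample(
            config, truth, row.sample_id, comp, n_reads, rng)
        truth.sample_composition[row.sample_id] = dict(
            zip(truth.community_species, comp))
    return samples, sheet


def generate_count_tables(config: SimConfig, truth: GroundTruth,
                          cohorts: Sequence[str] = ("case", "control", "longitudinal"),
                          depth: int = 3000,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species x sample read-count table drawn at the profiling depth.

    Uses the same per-sample composition substreams as the read-level
    generator but skips sequence synthesis; intended for statistical
    calibration and power studies where the alignment stages are not under
    test.
    """
    config.validate()
    sheet = sample_sheet(config, cohorts)
    cols = {}
    subject_base: dict[str, dict[str, float]] = {}
    for row in sheet.itertuples(index=False):
        rng = substream(config.seed, "sample", row.sample_id)
        if row.timepoint and row.subject_id not in subject_base:
            srng = substream(config.seed, "subject", row.subject_id)
            comp0 = _sample_composition(config, truth, row.group, srng)
            subject_base[row.subject_id] = dict(zip(truth.community_species, comp0))
        if row.timepoint:
            base = subject_base[row.subject_id]
            alpha = np.array([base[sp] for sp in truth.community_species])
            comp = rng.dirichlet(np.maximum(alpha * 2000.0, 1e-6))
        else:
            comp = _sample_composition(config, truth, row.group, rng)
        cols[row.sample_id] = rng.multinomial(depth, comp)
    counts = pd.DataFrame(cols, index=truth.community_species)
    return counts, sheet


# ---------------------------------------------------------------------------
# on-disk layout


def write_simulation(outdir: str | Path, config: SimConfig,
                     records: list[RefRecord], truth: GroundTruth,
                     samples: dict[str, list[ReadRecord]],
                     sheet: pd.DataFrame) -> None:
    """FASTA references, per-sample FASTQ, TSV sheet, Newick tree, JSON truth."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    write_reference_fasta(records, outdir / "references.fasta")
    for sample_id, reads in samples.items():
        write_fastq(reads, outdir / "reads" / f"{sample_id}.fastq")
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    (outdir / "generating_tree.nwk").write_text(truth.tree_newick() + "\n")
    truth.lineage.reset_index().to_csv(outdir / "lineage.tsv", sep="\t", index=False)
    sidecar = {
        "community_species": truth.community_species,
        "novel_species": truth.novel_species,
        "base_proportions": truth.base_proportions,
        "case_proportions": truth.case_proportions,
        "planted_log10_fc": truth.planted,
        "insert": [truth.insert_start, truth.insert_end],
        "amplicon": [truth.amplicon_start, truth.amplicon_end],
        "sample_composition": truth.sample_composition,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))


def reference_lineage(records: Iterable[RefRecord],
                      truth: GroundTruth) -> pd.DataFrame:
    """Per-reference lineage table (ref_id -> species, genus, phylum)."""
    rows = []
    for r in records:
        sp = r.source
        if sp in truth.lineage.index:
            lin = truth.lineage.loc[sp]
            rows.append((r.id, sp, lin["genus"], lin["phylum"]))
    return pd.DataFrame(rows, columns=["ref_id", "species", "genus",
                                       "phylum"]).set_index("ref_id")
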