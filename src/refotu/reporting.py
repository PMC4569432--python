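"""End-to-end orchestration and read-accounting reports.

The pipeline chains reference filtering and dereplication, per-sample read
preparation, best-hit mapping, species-level cluster construction, abundance
filtering, taxonomy, alpha/beta diversity and differential abundance with
longitudinal validation.  Its primary human-readable artifact is the
read-accounting report: totals and per-group percentages (one decimal) for
every stage, so a run can be audited the way a sequencing study reports its
bookkeeping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import betadiv, diffabund, diversity, mapping, phylo, readprep, refdb
from .records import ReadRecord, RefRecord, read_fastq, read_reference_fasta, write_fasta
from .taxonomy import TaxonomyAssigner, aggregate_levels


@dataclass
class RunConfig:
    """All thresholds of the analysis, with the study's printed defaults."""

    refdb_fasta: str = ""
    reads_dir: str = ""
    sample_sheet: str = ""
    lineage_tsv: str = ""
    output_dir: str = "refotu_out"
    seed: int = 0
    min_length: int = 1400
    max_ambiguous: int = 3
    derep_identity: float = 0.998
    depth: int = 3000
    min_mean_q: float = 25.0
    map_identity: float = 0.96
    map_coverage: float = 0.90
    rclust_identity: float = 0.97
    denovo_identity: float = 0.96
    min_mean_rel: float = 0.001
    alpha: float = 0.05
    n_perm: int = 999
    run_alpha_diversity: bool = True
    run_beta_diversity: bool = True

    def validate(self) -> None:
        for name in ("derep_identity", "map_identity", "map_coverage",
                     "rclust_identity", "denovo_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 <= self.min_mean_rel < 1.0):
            raise ValueError("min_mean_rel must be a fraction below 1")
        if self.depth < 1:
            raise ValueError("depth must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def percentages(mapped: dict[str, int], unmapped: dict[str, int]) -> dict:
    """Read-accounting percentages, rounded to one decimal as reported.

    ``mapped``/``unmapped`` are per-group read counts; the overall mapped
    percentage and each group's unmapped percentage are derived from their
    totals.
    """
    groups = sorted(set(mapped) | set(unmapped))
    total_mapped = sum(mapped.values())
    total = total_mapped + sum(unmapped.values())
    if total == 0:
        raise ValueError("no reads in the accounting")
    out = {
        "total_reads": total,
        "mapped_reads": total_mapped,
        "unmapped_reads": total - total_mapped,
        "percent_mapped_overall": round(100.0 * total_mapped / total, 1),
    }
    for g in groups:
        gm, gu = mapped.get(g, 0), unmapped.get(g, 0)
        gt = gm + gu
        out[f"reads_{g}"] = gt
        out[f"mapped_{g}"] = gm
        out[f"unmapped_{g}"] = gu
        out[f"percent_unmapped_{g}"] = round(100.0 * gu / gt, 1) if gt else 0.0
    return out


@dataclass
class RunResult:
    report: dict
    table: mapping.AbundanceTable | None = None
    filtered_table: mapping.AbundanceTable | None = None
    clusters: list = field(default_factory=list)
    assignments: dict = field(default_factory=dict)
    level_tables: dict = field(default_factory=dict)
    alpha_diversity: pd.DataFrame | None = None
    unifrac_unweighted: pd.DataFrame | None = None
    unifrac_weighted: pd.DataFrame | None = None
    anosim: dict = field(default_factory=dict)
    diff: pd.DataFrame | None = None
    longitudinal: pd.DataFrame | None = None
    tree: phylo.PhyloTree | None = None


class StageError(RuntimeError):
    """Pipeline failure annotated with the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_study(records: Sequence[RefRecord],
              samples: dict[str, list[ReadRecord]],
              sheet: pd.DataFrame,
              lineage: pd.DataFrame | None = None,
              config: RunConfig | None = None) -> RunResult:
    """Execute the full analysis on in-memory inputs.

    The sample sheet must carry sample_id/subject_id/group/timepoint;
    samples with timepoint 0 form the cross-sectional case/control
    comparison, timepointed samples the longitudinal validation series.
    """
    cfg = config or RunConfig()
    cfg.validate()
    report: dict = {"config_hash": cfg.config_hash()}
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, e) from e
        return wrap

    # reference database
    run = stage("refdb")
    kept, counts = run(refdb.filter_references, records,
                       cfg.min_length, cfg.max_ambiguous)
    report["refdb_input"] = len(records)
    report["refdb_removed"] = {k: v for k, v in counts.items() if k != "retained"}
    report["refdb_retained"] = counts["retained"]
    clusters99 = run(refdb.dereplicate, kept, cfg.derep_identity)
    reps = refdb.representatives(clusters99, kept)
    report["refdb_nonredundant"] = len(clusters99)

    # read preparation
    run = stage("readprep")
    prepared: dict[str, list[ReadRecord]] = {}
    prep_stats = {}
    for sid, reads in samples.items():
        prepared[sid], prep_stats[sid] = run(
            readprep.prepare_sample, reads, cfg.depth, cfg.min_mean_q,
            cfg.seed, sid)
    report["reads_total"] = int(sum(s["total"] for s in prep_stats.values()))
    report["reads_filter_passed"] = int(sum(s["filter_passed"]
                                            for s in prep_stats.values()))
    report["reads_subsampled"] = int(sum(s["subsampled"]
                                         for s in prep_stats.values()))

    groups = sheet["group"]
    cross = [sid for sid in prepared if sheet.loc[sid, "timepoint"] in (0, None)]
    longi = [sid for sid in prepared if sid not in cross]

    # mapping + clustering
    run = stage("mapping")
    all_reads = [r for sid in prepared for r in prepared[sid]]
    hits, unmapped_ids = run(mapping.map_reads, all_reads, reps,
                             cfg.map_identity, cfg.map_coverage)
    sample_of = {r.id: r.sample_id for r in all_reads}
    mapped_by_group: dict[str, int] = {}
    unmapped_by_group: dict[str, int] = {}
    for h in hits:
        g = groups[sample_of[h.read_id]]
        mapped_by_group[g] = mapped_by_group.get(g, 0) + 1
    for rid in unmapped_ids:
        g = groups[sample_of[rid]]
        unmapped_by_group[g] = unmapped_by_group.get(g, 0) + 1
    report["accounting"] = percentages(mapped_by_group, unmapped_by_group)
    report["refs_hit"] = len({h.ref_id for h in hits})

    rclusters, ref_to_cluster = run(mapping.build_rclust, hits, reps,
                                    cfg.rclust_identity)
    unmapped_reads = [r for r in all_reads if r.id in set(unmapped_ids)]
    uclusters, read_to_otu = run(mapping.cluster_unmapped, unmapped_reads,
                                 cfg.denovo_identity)
    all_clusters = rclusters + uclusters
    report["n_rclust"] = len(rclusters)
    report["n_unmap_otu"] = len(uclusters)

    table = run(mapping.assemble_table, hits, ref_to_cluster, read_to_otu,
                all_reads, groups, cfg.depth)
    cross_table = mapping.AbundanceTable(
        table.counts[cross], groups[cross], cfg.depth,
        table.kinds)
    filtered, removed = run(mapping.abundance_filter, cross_table,
                            cfg.min_mean_rel)
    report["clusters_removed_by_abundance"] = removed
    report["clusters_retained"] = int(filtered.counts.shape[0])

    result = RunResult(report=report, table=table, filtered_table=filtered,
                       clusters=all_clusters)

    # taxonomy
    if lineage is not None and not lineage.empty:
        run = stage("taxonomy")
        labelled_ids = set(lineage.index)
        labelled = [r for r in reps if r.id in labelled_ids]
        assigner = TaxonomyAssigner(labelled, lineage)
        retained = [c for c in all_clusters
                    if c.cluster_id in filtered.counts.index]
        result.assignments = run(assigner.assign_all, retained)
        result.level_tables = run(aggregate_levels, filtered,
                                  result.assignments)
        report["assigned_levels"] = dict(pd.Series(
            [a.level for a in result.assignments.values()]
        ).value_counts())

    # alpha diversity
    if cfg.run_alpha_diversity:
        run = stage("diversity")
        alpha_rows = [run(diversity.sample_diversity, sid, prepared[sid],
                          expected_depth=cfg.depth) for sid in cross]
        result.alpha_diversity = diversity.diversity_frame(alpha_rows)
        report["alpha_mean_observed"] = {
            g: round(float(result.alpha_diversity.loc[
                [s for s in cross if groups[s] == g], "observed"].mean()), 1)
            for g in sorted(groups[cross].unique())}

    # beta diversity on a tree over the retained clusters
    if cfg.run_beta_diversity and filtered.counts.shape[0] >= 3:
        run = stage("betadiv")
        rep_seqs = [(c.cluster_id, c.representative_seq)
                    for c in all_clusters
                    if c.cluster_id in filtered.counts.index]
        sim = run(phylo.pairwise_identity, rep_seqs)
        tree = run(phylo.nj_tree, 1.0 - sim).midpoint_root()
        result.tree = tree
        result.unifrac_unweighted = run(betadiv.unifrac, filtered, tree, False)
        result.unifrac_weighted = run(betadiv.unifrac, filtered, tree, True)
        if groups[cross].nunique() >= 2:
            r_u, p_u = run(betadiv.anosim, result.unifrac_unweighted,
                           groups[cross], cfg.n_perm, cfg.seed)
            r_w, p_w = run(betadiv.anosim, result.unifrac_weighted,
                           groups[cross], cfg.n_perm, cfg.seed)
            result.anosim = {"unweighted": {"R": r_u, "p": p_u},
                             "weighted": {"R": r_w, "p": p_w}}
            report["anosim"] = result.anosim

    # differential abundance + longitudinal validation
    if groups[cross].nunique() >= 2:
        run = stage("diffabund")
        result.diff = run(diffabund.differential_abundance, filtered,
                          alpha=cfg.alpha)
        report["n_significant_p"] = int(result.diff["significant"].sum())
        report["n_significant_q"] = int(result.diff["significant_q"].sum())
        if longi:
            sig = result.diff.index[result.diff["significant"]]
            case_cols = [s for s in cross if groups[s] == "MS"]
            long_counts = table.counts[longi]
            tps = sheet.loc[longi, "timepoint"]
            checks = run(diffabund.longitudinal_validation,
                         table.counts.loc[sig, case_cols].mean(axis=1),
                         result.diff.loc[sig, "log10_fc"],
                         long_counts, tps, cfg.depth)
            result.longitudinal = diffabund.longitudinal_frame(checks)
            if checks:
                report["longitudinal_sign_consistency_mean"] = float(
                    np.mean([c.sign_consistency for c in checks]))
    return result


def run_pipeline(config: RunConfig) -> RunResult:
    """Disk-to-disk run: read the standard layout, write all artifacts."""
    config.validate()
    records = read_reference_fasta(config.refdb_fasta)
    sheet = pd.read_csv(config.sample_sheet, sep="\t")
    reads_dir = Path(config.reads_dir)
    samples = {}
    for sid in sheet["sample_id"]:
        fq = reads_dir / f"{sid}.fastq"
        if not fq.exists():
            fq = reads_dir / f"{sid}.fastq.gz"
        samples[sid] = read_fastq(fq, sample_id=sid)
    lineage = None
    if config.lineage_tsv:
        lineage = pd.read_csv(config.lineage_tsv, sep="\t").set_index("ref_id")

    result = run_study(records, samples, sheet, lineage, config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_outputs(result, outdir, config)
    return result


def write_outputs(result: RunResult, outdir: Path, config: RunConfig) -> None:
    meta = f"# config_hash={config.config_hash()}\n"

    def tsv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(meta)
            df.to_csv(fh, sep="\t", index=index)

    (outdir / "report.json").write_text(json.dumps(result.report, indent=1,
                                                   default=str))
    if result.table is not None:
        tsv(result.table.counts, "abundance_all.tsv")
    if result.filtered_table is not None:
        tsv(result.filtered_table.counts, "abundance_filtered.tsv")
    if result.alpha_diversity is not None:
        tsv(result.alpha_diversity, "alpha_diversity.tsv")
    if result.unifrac_unweighted is not None:
        tsv(result.unifrac_unweighted, "unifrac_unweighted.tsv")
        tsv(result.unifrac_weighted, "unifrac_weighted.tsv")
    if result.diff is not None:
        tsv(result.diff, "differential_abundance.tsv")
    if result.longitudinal is not None:
        tsv(result.longitudinal, "longitudinal_validation.tsv", index=False)
    if result.tree is not None:
        (outdir / "cluster_tree.nwk").write_text(result.tree.newick())
    for level, frame in result.level_tables.items():
        tsv(frame, f"abundance_{level}.tsv")
    if result.clusters:
        write_fasta([(c.cluster_id, c.representative_seq)
                     for c in result.clusters], outdir / "representatives.fasta")
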