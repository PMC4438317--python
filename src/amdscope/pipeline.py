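"""End-to-end pipeline orchestration: synthesize -> partition -> merge ->
bin -> profile, with a serializable config, per-stage outputs, and a
checksummed manifest for reproducibility checks.

Timings are logged, never written to the manifest, so two runs with the same
config produce byte-identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from . import binning, expression, merge, partition, synthetic
from .mapping import SeedIndex, map_pairs
from .synthetic import CommunityTruth, GenomeSpec

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_against_truth",
           "default_demo_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters and seeds of one pipeline run."""

    # community
    n_genomes: int = 5
    genome_length: int = 80_000
    gc_low: float = 0.38
    gc_high: float = 0.67
    dominant_abundance: float = 0.91
    genes_per_genome: int = 50
    expr_sigma: float = 1.0
    # reads
    n_dna_pairs: int = 20_000
    n_cdna_reads: int = 20_000
    read_len: int = 101
    insert_mean: int = 500
    insert_sd: float = 50.0
    error_rate: float = 0.0
    # partition
    k: int = 31
    depth_threshold: float = 15.0
    min_read_len: int = 63
    # contigs / merge
    fragment_min: int = 5000
    fragment_max: int = 7500
    min_contig_len: int = 3000
    derep_identity: float = 0.98
    merge_identity: float = 0.98
    min_overlap: int = 40
    length_pool_threshold: int = 2000
    # binning
    k_min: int = 2
    k_max: int = 8
    fix_k: Optional[int] = None
    mad_factor: float = 3.0
    # expression
    iqr_mode: str = "fence"
    iqr_factor: float = 1.5
    iv_threshold: float = 50.0
    alpha: float = 0.05
    top_n: int = 10
    # reproducibility
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if not 0.5 < self.dominant_abundance < 1.0:
            raise ValueError("dominant_abundance must be in (0.5, 1)")
        if self.depth_threshold < 0:
            raise ValueError("depth_threshold must be >= 0")
        if self.k % 2 == 0 or not 3 <= self.k <= 63:
            raise ValueError("k must be odd and in [3, 63]")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        if not 0.9 < self.derep_identity <= 1.0:
            raise ValueError("derep_identity must be in (0.9, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 2 <= self.k_min < self.k_max:
            raise ValueError("require 2 <= k_min < k_max")
        if self.iqr_mode not in ("fence", "literal"):
            raise ValueError("iqr_mode must be 'fence' or 'literal'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.seed < 0 or self.seed >= 2 ** 31:
            raise ValueError("seed must be in [0, 2^31)")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- derived community ------------------------------------------------
    def abundances(self) -> np.ndarray:
        rest = (1.0 - self.dominant_abundance) / (self.n_genomes - 1)
        return np.array([self.dominant_abundance]
                        + [rest] * (self.n_genomes - 1))

    def genome_specs(self) -> list[GenomeSpec]:
        gcs = np.linspace(self.gc_low, self.gc_high, self.n_genomes)
        return [
            GenomeSpec(
                name=f"G{i + 1:02d}",
                length=self.genome_length,
                gc=float(gcs[i]),
                markov_order=3,
                seed=(self.seed * 1000 + i) % (2 ** 31),
            )
            for i in range(self.n_genomes)
        ]

    def stage_seed(self, stage: int) -> int:
        return (self.seed * 100 + stage) % (2 ** 31)


def default_demo_config(seed: int = 1) -> PipelineConfig:
    """The bundled 5-genome demo configuration."""
    return PipelineConfig(seed=seed)


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g",
              lineterminator="\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage into ``outdir`` and return the manifest dict.

    The manifest records the config, per-stage record counts and output file
    checksums; it is written as ``manifest.json`` (sorted keys), so reruns
    with the same config are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    t_all = time.perf_counter()

    def finish(stage: str, files: dict[str, Path], counts: dict, t0: float):
        manifest["stages"][stage] = {
            "outputs": {k: {"path": str(p.relative_to(outdir)),
                            "sha256": _sha256(p)}
                        for k, p in sorted(files.items())},
            "counts": counts,
        }
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

    # -- stage 1: synthesize ---------------------------------------------
    t0 = time.perf_counter()
    truth = synthetic.generate_community(
        config.genome_specs(), config.abundances(), config.genes_per_genome,
        seed=config.stage_seed(1), expr_sigma=config.expr_sigma)
    synthdir = outdir / "synth"
    truth_paths = synthetic.write_truth_tables(truth, synthdir)
    dna = synthetic.simulate_dna_reads(
        truth, config.n_dna_pairs, read_len=config.read_len,
        insert_mean=config.insert_mean, insert_sd=config.insert_sd,
        error_rate=config.error_rate, seed=config.stage_seed(2))
    cdna, true_probs = synthetic.simulate_cdna_reads(
        truth, config.n_cdna_reads, read_len=config.read_len,
        seed=config.stage_seed(3))
    dna_paths = dna.write_fastq(synthdir / "dna")
    cdna_paths = cdna.write_fastq(synthdir / "cdna")
    probs_df = pd.DataFrame(sorted(true_probs.items()),
                            columns=["gene_id", "true_prob"])
    _write_tsv(probs_df, synthdir / "cdna_true_probs.tsv")
    finish("synth",
           {**{k: Path(v) for k, v in truth_paths.items()},
            **{f"dna_{i + 1}": Path(p) for i, p in enumerate(dna_paths)},
            "cdna_1": Path(cdna_paths[0]),
            "cdna_true_probs": synthdir / "cdna_true_probs.tsv"},
           {"genomes": config.n_genomes, "dna_pairs": len(dna),
            "cdna_reads": len(cdna), "genes": len(truth.gene_models)},
           t0)

    # -- stage 2: partition ------------------------------------------------
    t0 = time.perf_counter()
    table = partition.count_kmers(dna, k=config.k)
    part = partition.partition_reads(dna, table,
                                     depth_threshold=config.depth_threshold,
                                     min_len=config.min_read_len)
    partdir = outdir / "partition"
    partdir.mkdir(exist_ok=True)
    part_paths = partition.write_partition(part, partdir / "partition")
    finish("partition", {k: Path(v) for k, v in part_paths.items()},
           {"distinct_kmers": len(table), "high": len(part.high),
            "low": len(part.low), "discarded": len(part.discarded)},
           t0)

    # -- stage 3: contigs (assembly stand-in) + merge ----------------------
    t0 = time.perf_counter()
    contigs = synthetic.fragment_genomes(
        truth, (config.fragment_min, config.fragment_max),
        min_len=max(500, config.min_contig_len // 2),
        seed=config.stage_seed(4))
    contigs = merge.split_scaffolds(contigs)
    contigs, derep_report = merge.dereplicate(
        contigs, identity=config.derep_identity, return_report=True)
    short, longs = merge.pool_by_length(contigs, config.length_pool_threshold)
    merged_short = merge.merge_overlaps(short, config.merge_identity,
                                        config.min_overlap)
    pool = merge.ContigSet(list(merged_short) + list(longs))
    pool = merge.merge_overlaps(pool, config.merge_identity,
                                config.min_overlap)
    mergedir = outdir / "contigs"
    mergedir.mkdir(exist_ok=True)
    pool.to_fasta(mergedir / "contigs.fasta")
    _write_tsv(derep_report, mergedir / "derep_report.tsv")
    cov_df = pd.DataFrame(
        [(c.id, c.coverage, c.origin) for c in pool],
        columns=["contig_id", "coverage", "true_origin"])
    _write_tsv(cov_df, mergedir / "coverage.tsv")
    finish("contigs",
           {"contigs": mergedir / "contigs.fasta",
            "derep_report": mergedir / "derep_report.tsv",
            "coverage": mergedir / "coverage.tsv"},
           {"contigs": len(pool), "bases": pool.total_bases()},
           t0)

    # -- stage 4: binning --------------------------------------------------
    t0 = time.perf_counter()
    ids, profiles = binning.tnf_profiles(pool, min_len=config.min_contig_len)
    chosen_k, diagnostics = binning.select_bin_count(
        ids, profiles, k_min=config.k_min,
        k_max=min(config.k_max, len(ids) - 1), seed=config.stage_seed(5))
    k_use = config.fix_k or chosen_k
    assignment = binning.cluster_contigs(ids, profiles, k_use)
    coverages = {c.id: c.coverage for c in pool if c.coverage is not None}
    assignment = binning.refine_bins(assignment, ids, profiles, coverages,
                                     mad_factor=config.mad_factor)
    bindir = outdir / "bins"
    bindir.mkdir(exist_ok=True)
    members = pd.DataFrame(
        sorted(assignment.assignments.items()), columns=["contig_id", "bin"])
    _write_tsv(members, bindir / "bin_membership.tsv")
    _write_tsv(diagnostics, bindir / "bin_diagnostics.tsv")
    summary = assignment.summarize(pool)
    _write_tsv(summary, bindir / "bin_summary.tsv")
    contig_index = SeedIndex(pool.sequences(), seed_len=config.k)
    pair_map = map_pairs(dna, contig_index)
    abundance = binning.relative_abundance(pair_map, assignment)
    _write_tsv(abundance.rename("fraction").reset_index()
               .rename(columns={"index": "bin"}), bindir / "abundance.tsv")
    finish("bins",
           {"membership": bindir / "bin_membership.tsv",
            "diagnostics": bindir / "bin_diagnostics.tsv",
            "summary": bindir / "bin_summary.tsv",
            "abundance": bindir / "abundance.tsv"},
           {"binned_contigs": len(assignment.assignments),
            "selected_k": int(chosen_k), "used_k": int(k_use),
            "unbinned": len(assignment.unbinned)},
           t0)

    # -- stage 5: expression ----------------------------------------------
    t0 = time.perf_counter()
    genome_index = SeedIndex(truth.sequences, seed_len=config.k)
    dna_counts, dna_tot, dna_un = expression.map_reads_to_features(
        dna, truth.gene_models, truth.sequences, index=genome_index)
    cdna_counts, cdna_tot, cdna_un = expression.map_reads_to_features(
        cdna, truth.gene_models, truth.sequences, index=genome_index)
    xt_gene = expression.build_expression_table(dna_counts, cdna_counts)
    xt_ko = expression.build_expression_table(
        dna_counts, cdna_counts, gene_models=truth.gene_models, level="KO")
    rta_gene = expression.rta(xt_gene)
    rta_ko = expression.rta(xt_ko)
    outliers, _ = expression.detect_outliers(
        xt_ko, factor=config.iqr_factor, mode=config.iqr_mode)
    iv = expression.indicator_value(xt_ko)
    ind = expression.identify_indicators(outliers, iv,
                                         threshold=config.iv_threshold)
    ko_cat = truth.ko_categories
    contrasts = expression.compare_rta(rta_ko.table, ko_cat,
                                       alpha=config.alpha)
    zmat, _ = expression.zscore_profile(
        expression.category_rta_matrix(rta_ko.table, ko_cat))
    top = expression.top_expressed(rta_gene, xt_gene, n=config.top_n)
    exprdir = outdir / "expression"
    exprdir.mkdir(exist_ok=True)
    _write_tsv(rta_gene.table.reset_index(), exprdir / "rta_gene.tsv")
    _write_tsv(rta_ko.table.reset_index(), exprdir / "rta_ko.tsv")
    ind_long = (ind.indicator.stack().rename("indicator").reset_index()
                .merge(ind.iv.stack().rename("iv").reset_index(),
                       on=["feature", "genome"])
                .merge(ind.outlier.stack().rename("outlier").reset_index(),
                       on=["feature", "genome"]))
    _write_tsv(ind_long, exprdir / "indicators.tsv")
    _write_tsv(contrasts, exprdir / "category_contrasts.tsv")
    _write_tsv(zmat.reset_index(), exprdir / "zscore_matrix.tsv")
    _write_tsv(top, exprdir / "top_expressed.tsv")
    finish("expression",
           {"rta_gene": exprdir / "rta_gene.tsv",
            "rta_ko": exprdir / "rta_ko.tsv",
            "indicators": exprdir / "indicators.tsv",
            "contrasts": exprdir / "category_contrasts.tsv",
            "zscore": exprdir / "zscore_matrix.tsv",
            "top": exprdir / "top_expressed.tsv"},
           {"dna_unassigned": dna_un, "cdna_unassigned": cdna_un,
            "indicator_calls": int(ind.indicator.to_numpy().sum())},
           t0)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline done in %.1fs", time.perf_counter() - t_all)
    return manifest


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

def _true_indicators(truth: CommunityTruth, true_probs: dict[str, float],
                     iqr_mode: str, iqr_factor: float,
                     iv_threshold: float) -> pd.DataFrame:
    """Indicator calls from exact expected counts (deterministic truth)."""
    scale = 1_000_000
    gene_of = {g.gene_id: g for g in truth.gene_models}
    rows = []
    for gid, p in true_probs.items():
        g = gene_of[gid]
        rows.append((g.ko, g.genome, p * scale, g.length))
    df = pd.DataFrame(rows, columns=["feature", "genome", "cdna_count",
                                     "dna_count"])
    counts = df.groupby(["feature", "genome"]).sum()
    tot = counts.groupby(level="genome").sum()
    tot.columns = ["cdna_total", "dna_total"]
    xt = expression.ExpressionTable(
        counts=counts[["dna_count", "cdna_count"]],
        totals=tot[["dna_total", "cdna_total"]], level="KO")
    outl, _ = expression.detect_outliers(xt, factor=iqr_factor, mode=iqr_mode)
    iv = expression.indicator_value(xt)
    return expression.identify_indicators(outl, iv, iv_threshold).indicator


def evaluate_against_truth(outdir, truth: CommunityTruth,
                           config: PipelineConfig) -> pd.DataFrame:
    """Score a run directory against the generating truth.

    Reports bin ARI and purity, the largest relative-abundance error, the
    Spearman correlation between gene RTA and true expression weight, and
    indicator precision/recall against indicator calls computed from the
    exact expected counts.
    """
    outdir = Path(outdir)
    members = pd.read_csv(outdir / "bins" / "bin_membership.tsv", sep="\t")
    cov = pd.read_csv(outdir / "contigs" / "coverage.tsv", sep="\t")
    origin_of = dict(zip(cov["contig_id"], cov["true_origin"]))
    members = members[members["contig_id"].map(origin_of).notna()]
    y_true = [origin_of[c] for c in members["contig_id"]]
    y_pred = members["bin"].tolist()
    ari = float(adjusted_rand_score(y_true, y_pred))
    purity = float(np.mean([
        max(sub.value_counts()) / len(sub)
        for _, sub in pd.Series(y_true, index=y_pred).groupby(level=0)
    ]))

    abundance = pd.read_csv(outdir / "bins" / "abundance.tsv", sep="\t")
    ab_col = abundance.columns[0]
    est = dict(zip(abundance[ab_col], abundance["fraction"]))
    # bin -> dominant true origin, then compare to true abundance
    bin_origin = (pd.Series(y_true, index=[f"bin{b}" for b in y_pred])
                  .groupby(level=0).agg(lambda s: s.value_counts().idxmax()))
    errors = []
    for name, true_ab in zip(truth.names, truth.abundances):
        est_ab = sum(v for b, v in est.items()
                     if b != "unmapped" and bin_origin.get(b) == name)
        errors.append(abs(est_ab - float(true_ab)))
    abundance_err = float(max(errors))

    rta_gene = pd.read_csv(outdir / "expression" / "rta_gene.tsv", sep="\t")
    w_of = {g.gene_id: g.weight for g in truth.gene_models}
    sub = rta_gene.dropna(subset=["rta"])
    rho = float(spearmanr(sub["feature"].map(w_of), sub["rta"]).statistic)

    probs = pd.read_csv(outdir / "synth" / "cdna_true_probs.tsv", sep="\t")
    true_ind = _true_indicators(
        truth, dict(zip(probs["gene_id"], probs["true_prob"])),
        config.iqr_mode, config.iqr_factor, config.iv_threshold)
    est_ind_long = pd.read_csv(outdir / "expression" / "indicators.tsv",
                               sep="\t")
    est_pairs = set(map(tuple, est_ind_long.loc[
        est_ind_long["indicator"], ["feature", "genome"]].to_numpy()))
    true_pairs = set(true_ind.stack()[lambda s: s].index.tolist())
    tp = len(est_pairs & true_pairs)
    precision = tp / len(est_pairs) if est_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0

    return pd.DataFrame(
        [("bin_ari", ari), ("bin_purity", purity),
         ("abundance_max_error", abundance_err),
         ("rta_spearman", rho),
         ("indicator_precision", float(precision)),
         ("indicator_recall", float(recall))],
        columns=["metric", "value"])
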