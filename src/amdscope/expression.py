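"""Per-taxon transcriptional statistics.

Implements the study's statistical layer on a feature (gene/KO/COG) x genome
table of DNA and cDNA read counts:

* relative abundances: a feature's share of its genome's DNA or cDNA reads;
* Relative Transcriptional Activity, RTA(a, b) = cDNA share / DNA share —
  1 means transcription proportional to gene dosage;
* expression outliers: cDNA counts above an IQR fence within each genome;
* Indicator Value, IV(a, b) = 100 x cDNA_share(a, b) / sum_j cDNA_share(a, j)
  over the g genomes — the percentage of a KO's community-wide cDNA relative
  abundance contributed by one genome;
* indicator KOs: expression outliers with IV strictly above 50;
* cross-taxon Wilcoxon rank-sum contrasts of RTA by functional category;
* z-scored per-category activity profiles and per-taxon top-N rankings.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ReadSet
from .mapping import SeedIndex, map_mates

__all__ = [
    "ExpressionTable", "RTAResult", "IndicatorResult",
    "map_reads_to_features", "build_expression_table", "relative_abundances",
    "rta", "detect_outliers", "indicator_value", "identify_indicators",
    "ranksum_pvalue", "compare_rta", "category_rta_matrix", "zscore_profile",
    "top_expressed",
]


@dataclass
class ExpressionTable:
    """Feature x genome DNA/cDNA counts with per-genome totals.

    ``counts`` is indexed by (feature, genome) with integer columns
    ``dna_count`` and ``cdna_count``; ``totals`` is indexed by genome with
    columns ``dna_total`` and ``cdna_total``. Totals default to the
    feature-mapped sums but may be larger (reads may be intergenic).
    """

    counts: pd.DataFrame
    totals: pd.DataFrame
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.level not in ("gene", "KO", "COG"):
            raise ValueError("level must be one of gene/KO/COG")
        need = {"dna_count", "cdna_count"}
        if not need.issubset(self.counts.columns):
            raise ValueError(f"counts needs columns {need}")
        if (self.counts[list(need)] < 0).any().any():
            raise ValueError("counts must be non-negative")
        per_g = self.counts.groupby(level="genome")[["dna_count", "cdna_count"]].sum()
        tot = self.totals.reindex(per_g.index)
        if (per_g["dna_count"] > tot["dna_total"] + 1e-9).any() or (
                per_g["cdna_count"] > tot["cdna_total"] + 1e-9).any():
            raise ValueError("feature counts exceed genome totals")

    @property
    def genomes(self) -> list[str]:
        return list(self.totals.index)


@dataclass
class RTAResult:
    """RTA per (feature, genome) with a per-entry method flag.

    flags: 'ok', 'pseudocount' (zero DNA, positive cDNA; pseudocount 0.5
    applied), 'undefined' (both counts zero; RTA is NaN).
    """

    table: pd.DataFrame  # columns: rta, flag
    pseudocount: float = 0.5

    @property
    def rta(self) -> pd.Series:
        return self.table["rta"]


@dataclass
class IndicatorResult:
    """Outlier flags, indicator values and indicator calls per (KO, genome)."""

    outlier: pd.DataFrame  # features x genomes, bool
    iv: pd.DataFrame       # features x genomes, [0, 100]
    g: int
    indicator: pd.DataFrame  # features x genomes, bool
    skipped_genomes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def _gene_lookup(gene_models) -> dict[str, tuple[np.ndarray, np.ndarray, list]]:
    per: dict[str, list] = {}
    for g in gene_models:
        per.setdefault(g.genome, []).append(g)
    out = {}
    for genome, genes in per.items():
        genes = sorted(genes, key=lambda g: g.start)
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        out[genome] = (starts, ends, genes)
    return out


def map_reads_to_features(
    reads: ReadSet,
    gene_models,
    genome_seqs: dict[str, str],
    seed_len: int = 31,
    index: Optional[SeedIndex] = None,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Count reads per gene by exact-seed placement.

    A read is assigned to the unique genome holding an exact canonical
    ``seed_len``-mer of it, and to a gene when the mapped interval midpoint
    falls inside the gene (genes are non-overlapping). Returns (per-gene
    counts frame indexed by (feature, genome) with column ``count``,
    per-genome mapped-read totals, number of unassigned reads).
    """
    if index is None:
        index = SeedIndex(genome_seqs, seed_len=seed_len)
    lookup = _gene_lookup(gene_models)
    gene_counts: dict[tuple[str, str], int] = {}
    genome_totals: dict[str, int] = {g: 0 for g in genome_seqs}
    unassigned = 0
    mapped = map_mates(reads, index)
    for ref, start, length in zip(mapped["reference"], mapped["start"],
                                  mapped["length"]):
        if not isinstance(ref, str):
            unassigned += 1
            continue
        genome_totals[ref] += 1
        mid = start + length // 2
        if ref not in lookup:
            continue
        starts, ends, genes = lookup[ref]
        j = int(np.searchsorted(starts, mid, side="right")) - 1
        if j >= 0 and mid < ends[j]:
            key = (genes[j].gene_id, ref)
            gene_counts[key] = gene_counts.get(key, 0) + 1
    idx = pd.MultiIndex.from_tuples(
        [(g.gene_id, g.genome) for g in gene_models],
        names=["feature", "genome"])
    counts = pd.DataFrame(
        {"count": [gene_counts.get(t, 0) for t in idx]}, index=idx)
    totals = pd.Series(genome_totals, name="total").sort_index()
    return counts, totals, unassigned


def build_expression_table(
    dna_counts: pd.DataFrame,
    cdna_counts: pd.DataFrame,
    gene_models=None,
    level: str = "gene",
    totals: str = "feature",
    dna_genome_totals: Optional[pd.Series] = None,
    cdna_genome_totals: Optional[pd.Series] = None,
) -> ExpressionTable:
    """Assemble an :class:`ExpressionTable` from per-gene count frames.

    ``level='KO'`` aggregates gene counts to KO labels via ``gene_models``.
    ``totals='feature'`` (default) uses feature-mapped sums as genome totals;
    ``totals='genome'`` uses the supplied genome-wide mapped totals instead
    (includes intergenic reads).
    """
    df = pd.DataFrame({
        "dna_count": dna_counts["count"],
        "cdna_count": cdna_counts["count"],
    }).fillna(0).astype(int)
    if level == "KO":
        if gene_models is None:
            raise ValueError("gene_models required for KO aggregation")
        ko_of = {g.gene_id: g.ko for g in gene_models}
        df = df.reset_index()
        df["feature"] = df["feature"].map(ko_of)
        df = df.groupby(["feature", "genome"]).sum()
    if totals == "feature":
        tot = df.groupby(level="genome").sum()
        tot.columns = ["dna_total", "cdna_total"]
    elif totals == "genome":
        if dna_genome_totals is None or cdna_genome_totals is None:
            raise ValueError("genome totals required for totals='genome'")
        tot = pd.DataFrame({"dna_total": dna_genome_totals,
                            "cdna_total": cdna_genome_totals})
    else:
        raise ValueError("totals must be 'feature' or 'genome'")
    return ExpressionTable(counts=df, totals=tot, level=level)


# ---------------------------------------------------------------------------
# shares and RTA
# ---------------------------------------------------------------------------

def relative_abundances(table: ExpressionTable) -> tuple[pd.DataFrame, list[str]]:
    """Per-(feature, genome) DNA and cDNA shares of the genome totals.

    Genomes with a zero DNA or cDNA total are excluded (with the excluded
    names returned), mirroring the exclusion of taxa with too little
    transcriptome information.
    """
    tot = table.totals
    ok = (tot["dna_total"] > 0) & (tot["cdna_total"] > 0)
    excluded = list(tot.index[~ok])
    if excluded:
        warnings.warn(
            f"genomes excluded for zero totals: {', '.join(excluded)}",
            stacklevel=2)
    counts = table.counts[
        table.counts.index.get_level_values("genome").isin(tot.index[ok])]
    g = counts.index.get_level_values("genome")
    shares = pd.DataFrame({
        "dna_share": counts["dna_count"].to_numpy()
        / tot.loc[g, "dna_total"].to_numpy(),
        "cdna_share": counts["cdna_count"].to_numpy()
        / tot.loc[g, "cdna_total"].to_numpy(),
    }, index=counts.index)
    return shares, excluded


def rta(table: ExpressionTable, pseudocount: float = 0.5) -> RTAResult:
    """Relative Transcriptional Activity per (feature, genome).

    RTA = cDNA share / DNA share. Where the DNA count is zero but cDNA is
    positive, ``pseudocount`` is added to both counts and the entry flagged;
    where both are zero, RTA is NaN ('undefined').
    """
    shares, _ = relative_abundances(table)
    counts = table.counts.loc[shares.index]
    tot = table.totals
    g = shares.index.get_level_values("genome")
    dna_tot = tot.loc[g, "dna_total"].to_numpy(dtype=float)
    cdna_tot = tot.loc[g, "cdna_total"].to_numpy(dtype=float)
    dna = counts["dna_count"].to_numpy(dtype=float)
    cdna = counts["cdna_count"].to_numpy(dtype=float)

    val = np.full(len(shares), np.nan)
    flag = np.full(len(shares), "undefined", dtype=object)
    normal = dna > 0
    val[normal] = (cdna[normal] / cdna_tot[normal]) / (dna[normal] / dna_tot[normal])
    flag[normal] = "ok"
    pseudo = (dna == 0) & (cdna > 0)
    val[pseudo] = ((cdna[pseudo] + pseudocount) / cdna_tot[pseudo]) / (
        pseudocount / dna_tot[pseudo])
    flag[pseudo] = "pseudocount"
    return RTAResult(
        table=pd.DataFrame({"rta": val, "flag": flag}, index=shares.index),
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# outliers / indicator values
# ---------------------------------------------------------------------------

def detect_outliers(
    table: ExpressionTable,
    factor: float = 1.5,
    mode: str = "fence",
) -> tuple[pd.DataFrame, list[str]]:
    """Flag expression outliers per genome from cDNA counts.

    ``mode='fence'`` (default): count > Q3 + factor x IQR, the standard
    boxplot fence; ``mode='literal'``: count > factor x IQR, the literal
    reading of the rule. Quartiles use linear interpolation. Genomes with
    fewer than 4 features are skipped with a warning; their flags are False.
    Returns (features x genomes boolean frame, skipped genomes).
    """
    if mode not in ("fence", "literal"):
        raise ValueError("mode must be 'fence' or 'literal'")
    wide = table.counts["cdna_count"].unstack("genome")
    flags = pd.DataFrame(False, index=wide.index, columns=wide.columns)
    skipped: list[str] = []
    for genome in wide.columns:
        col = wide[genome].dropna()
        if len(col) < 4:
            skipped.append(genome)
            continue
        q1, q3 = np.percentile(col.to_numpy(), [25, 75])
        iqr = q3 - q1
        thr = q3 + factor * iqr if mode == "fence" else factor * iqr
        flags.loc[col.index, genome] = col > thr
    if skipped:
        warnings.warn(
            f"genomes skipped for outlier detection (<4 features): "
            f"{', '.join(skipped)}", stacklevel=2)
    return flags, skipped


def indicator_value(table: ExpressionTable) -> pd.DataFrame:
    """Indicator Value per (feature, genome): 100 x the genome's share of the
    feature's summed cross-genome cDNA relative abundance (0 where the
    feature is expressed nowhere). Rows sum to 100 for expressed features."""
    shares, _ = relative_abundances(table)
    wide = shares["cdna_share"].unstack("genome").fillna(0.0)
    denom = wide.sum(axis=1)
    iv = wide.mul(0.0, axis=0)
    nz = denom > 0
    iv.loc[nz] = 100.0 * wide.loc[nz].div(denom[nz], axis=0)
    return iv


def identify_indicators(
    outliers: pd.DataFrame,
    iv: pd.DataFrame,
    threshold: float = 50.0,
) -> IndicatorResult:
    """Indicator KO calls: expression outlier AND IV strictly above
    ``threshold``."""
    idx = outliers.index.union(iv.index)
    cols = outliers.columns.union(iv.columns)
    out = outliers.reindex(index=idx, columns=cols, fill_value=False)
    ivf = iv.reindex(index=idx, columns=cols, fill_value=0.0)
    indicator = out & (ivf > threshold)
    return IndicatorResult(outlier=out, iv=ivf, g=len(cols),
                           indicator=indicator)


# ---------------------------------------------------------------------------
# rank-sum contrasts
# ---------------------------------------------------------------------------

def ranksum_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null when both samples have n <= 12 and there are no ties;
    otherwise the normal approximation with continuity and tie correction
    (the classical large-sample form). Degenerate inputs with zero rank
    variance give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < nx + ny
    if nx <= 12 and ny <= 12 and not has_ties:
        return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="exact").pvalue)
    ranks = sps.rankdata(pooled)
    W = ranks[:nx].sum()
    n = nx + ny
    mu = nx * (n + 1) / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t ** 3 - t).sum() / (n * (n - 1.0))
    sigma2 = nx * ny / 12.0 * ((n + 1.0) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = W - mu
    z -= 0.5 * np.sign(z)  # continuity correction
    p = 2.0 * sps.norm.sf(abs(z) / np.sqrt(sigma2))
    return float(min(p, 1.0))


def compare_rta(
    rta_table: pd.DataFrame,
    category_map: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(category, genome) rank-sum contrast of RTA values.

    For each functional category and genome: the genome's RTA values in the
    category vs all other genomes' values in that category; ``enriched`` is
    True when p < alpha and the genome's median is the higher one. Groups
    with fewer than 2 observations give NaN p with a reason.
    """
    if isinstance(rta_table, RTAResult):
        rta_table = rta_table.table
    df = rta_table.reset_index()
    df["category"] = df["feature"].map(category_map)
    df = df.dropna(subset=["category", "rta"])
    rows = []
    for cat, sub in df.groupby("category", sort=True):
        for genome in sorted(sub["genome"].unique()):
            x = sub.loc[sub["genome"] == genome, "rta"].to_numpy()
            y = sub.loc[sub["genome"] != genome, "rta"].to_numpy()
            if len(x) < 2 or len(y) < 2:
                rows.append({"category": cat, "genome": genome,
                             "n_genome": len(x), "n_other": len(y),
                             "p_value": np.nan, "enriched": False,
                             "reason": "degenerate group (<2 observations)"})
                continue
            p = ranksum_pvalue(x, y)
            rows.append({
                "category": cat, "genome": genome,
                "n_genome": len(x), "n_other": len(y), "p_value": p,
                "enriched": bool(p < alpha
                                 and np.median(x) > np.median(y)),
                "reason": "",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profiles and rankings
# ---------------------------------------------------------------------------

def category_rta_matrix(
    rta_table: pd.DataFrame,
    category_map: dict[str, str],
) -> pd.DataFrame:
    """Category x genome matrix of mean RTA over the category's features."""
    if isinstance(rta_table, RTAResult):
        rta_table = rta_table.table
    df = rta_table.reset_index()
    df["category"] = df["feature"].map(category_map)
    df = df.dropna(subset=["category", "rta"])
    return df.pivot_table(index="category", columns="genome", values="rta",
                          aggfunc="mean")


def zscore_profile(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Z-score each row across taxa (population sd).

    Zero-variance rows become all zeros and are returned as flagged."""
    vals = matrix.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flagged = [matrix.index[i] for i in np.flatnonzero(sd.ravel() == 0)]
    safe = np.where(sd == 0, 1.0, sd)
    z = (vals - mu) / safe
    z[sd.ravel() == 0, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def top_expressed(
    rta_result: RTAResult,
    table: ExpressionTable,
    n: int = 10,
) -> pd.DataFrame:
    """Top-``n`` features per genome by RTA.

    Ties break by higher cDNA count, then feature id; genomes with fewer
    than ``n`` defined features return all of them with a warning. The
    result is a long frame with a 1-based ``rank`` column.
    """
    df = rta_result.table.join(table.counts["cdna_count"]).reset_index()
    df = df.dropna(subset=["rta"])
    rows = []
    for genome, sub in df.groupby("genome", sort=True):
        sub = sub.sort_values(
            by=["rta", "cdna_count", "feature"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        if len(sub) < n:
            warnings.warn(
                f"genome {genome}: only {len(sub)} features with defined RTA "
                f"(requested top {n})", stacklevel=2)
        top = sub.head(n).copy()
        top["rank"] = np.arange(1, len(top) + 1)
        rows.append(top)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["feature", "genome", "rta", "flag", "cdna_count", "rank"])
    return out[["genome", "rank", "feature", "rta", "cdna_count", "flag"]]
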