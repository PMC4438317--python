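"""Synthetic community generator with full ground truth.

Emulates a low-diversity community of the acid-mine-drainage kind: one
dominant taxon (relative abundance >90%) plus several rare taxa (<1% each),
genomes with distinct GC contents and distinguishable tetranucleotide
signatures, shotgun DNA read depth proportional to abundance, and cDNA reads
drawn from per-gene expression levels so that transcriptional-activity ground
truth is known exactly.

Genomes are produced by per-genome Markov chains (default order 3) whose
stationary base composition is corrected to the requested GC, so different
seeds yield different 4-mer signatures at the same GC.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import sequtils
from .containers import Contig, ContigSet, Read, ReadSet

__all__ = [
    "GenomeSpec",
    "GeneModel",
    "CommunityTruth",
    "generate_genome",
    "generate_community",
    "simulate_dna_reads",
    "simulate_cdna_reads",
    "fragment_genomes",
    "write_truth_tables",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome.

    ``gc`` is the target stationary G+C fraction; ``markov_order`` controls
    how much genome-specific 4-mer structure the sequence carries (order 3
    makes tetranucleotide signatures genome-specific).
    """

    name: str
    length: int
    gc: float
    markov_order: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 10_000:
            raise ValueError(f"genome length must be >= 10000, got {self.length}")
        if not 0.2 <= self.gc <= 0.8:
            raise ValueError(f"gc must be in [0.2, 0.8], got {self.gc}")
        if self.markov_order < 0:
            raise ValueError("markov_order must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval on a genome (0-based, half-open) with a KO label and
    a relative expression weight."""

    gene_id: str
    genome: str
    start: int
    end: int
    strand: str
    ko: str
    weight: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CommunityTruth:
    """Ground truth of a synthetic community: genome specs and sequences,
    relative abundances, gene models with expression weights, and the
    KO -> functional-category map."""

    genomes: list[GenomeSpec]
    abundances: np.ndarray
    gene_models: list[GeneModel]
    sequences: dict[str, str]
    ko_categories: dict[str, str] = field(default_factory=dict)
    expr_params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.genomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {g.name: g.length for g in self.genomes}

    def genes_of(self, genome: str) -> list[GeneModel]:
        return [g for g in self.gene_models if g.genome == genome]

    def abundance_of(self, genome: str) -> float:
        return float(self.abundances[self.names.index(genome)])


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _stationary_base_freqs(T: np.ndarray, order: int) -> np.ndarray:
    """Base marginal of the stationary distribution of an order-``order``
    Markov chain with context-transition matrix ``T`` (4^order x 4)."""
    S = T.shape[0]
    pi = np.full(S, 1.0 / S)
    ctx = np.arange(S)
    nxt = [(ctx * 4 + b) % S for b in range(4)]
    for _ in range(200):
        new = np.zeros(S)
        for b in range(4):
            np.add.at(new, nxt[b], pi * T[:, b])
        if np.abs(new - pi).sum() < 1e-12:
            pi = new
            break
        pi = new
    return pi @ T


def generate_genome(spec: GenomeSpec) -> str:
    """Generate a deterministic random genome for ``spec``.

    The sequence is drawn from a seed-specific Markov chain of order
    ``spec.markov_order`` whose per-context transition probabilities are
    lognormal perturbations of the target base composition, iteratively
    rescaled so the chain's stationary GC equals ``spec.gc``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.markov_order
    S = 4 ** m
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])

    W = rng.lognormal(0.0, 0.7, size=(S, 4))
    T = W * p
    T /= T.sum(axis=1, keepdims=True)
    # fixed-point correction of the stationary base composition
    for _ in range(30):
        q = _stationary_base_freqs(T, m)
        if np.abs(q - p).max() < 1e-10:
            break
        T *= p / q
        T /= T.sum(axis=1, keepdims=True)

    cum = T.cumsum(axis=1)
    cum[:, 3] = 1.0 + 1e-12

    codes = np.empty(spec.length, dtype=np.uint8)
    first = rng.choice(4, size=max(m, 1), p=p)
    codes[: max(m, 1)] = first
    ctx = 0
    for b in first[:m]:
        ctx = (ctx * 4 + int(b)) % S
    start = max(m, 1)
    u = rng.random(spec.length - start)
    for i in range(start, spec.length):
        row = cum[ctx]
        r = u[i - start]
        if r < row[0]:
            b = 0
        elif r < row[1]:
            b = 1
        elif r < row[2]:
            b = 2
        else:
            b = 3
        codes[i] = b
        ctx = (ctx * 4 + b) % S
    return sequtils.decode(codes)


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def generate_community(
    specs: Sequence[GenomeSpec],
    abundances: Sequence[float],
    genes_per_genome: int,
    seed: int = 0,
    *,
    expr_mu: float = 0.0,
    expr_sigma: float = 1.0,
    gene_length_range: tuple[int, int] = (600, 1200),
    n_categories: int = 8,
    expression_weights: Optional[dict[str, Sequence[float]]] = None,
) -> CommunityTruth:
    """Build a :class:`CommunityTruth`.

    Gene intervals are placed without overlap on each genome; expression
    weights default to i.i.d. log-normal(``expr_mu``, ``expr_sigma``) draws
    (recorded in ``expr_params``). Gene ``i`` carries KO label ``K{i+1:05d}``
    in every genome, so KOs form cross-genome orthologous groups, and each KO
    maps to one of ``n_categories`` functional categories.

    ``expression_weights`` (genome name -> per-gene weights) overrides the
    random weights, e.g. to plant a known highly expressed gene.
    """
    specs = list(specs)
    ab = np.asarray(abundances, dtype=float)
    if len(specs) != len(ab):
        raise ValueError("specs and abundances must have equal length")
    if abs(ab.sum() - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1, got {ab.sum()!r}")
    if np.any(ab < 0):
        raise ValueError("abundances must be non-negative")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("genome names must be unique")
    if genes_per_genome < 1:
        raise ValueError("genes_per_genome must be >= 1")

    rng = np.random.default_rng(seed)
    sequences = {s.name: generate_genome(s) for s in specs}

    lo, hi = gene_length_range
    gene_models: list[GeneModel] = []
    ko_categories: dict[str, str] = {}
    for s in specs:
        lengths = rng.integers(lo, hi + 1, size=genes_per_genome)
        slack = s.length - int(lengths.sum())
        if slack < 0:
            raise ValueError(
                f"genome {s.name} too short for {genes_per_genome} genes "
                f"of length {lo}-{hi}"
            )
        cuts = np.sort(rng.integers(0, slack + 1, size=genes_per_genome))
        if expression_weights is not None and s.name in expression_weights:
            weights = np.asarray(expression_weights[s.name], dtype=float)
            if len(weights) != genes_per_genome:
                raise ValueError("expression_weights length mismatch")
            if np.any(weights < 0):
                raise ValueError("expression weights must be >= 0")
        else:
            weights = rng.lognormal(expr_mu, expr_sigma, size=genes_per_genome)
        pos = 0
        offset = 0
        for i in range(genes_per_genome):
            start = int(cuts[i]) + offset
            end = start + int(lengths[i])
            offset += int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            ko = f"K{i + 1:05d}"
            ko_categories.setdefault(ko, f"M{(i % n_categories) + 1:02d}")
            gene_models.append(
                GeneModel(
                    gene_id=f"{s.name}_g{i + 1:04d}",
                    genome=s.name,
                    start=start,
                    end=end,
                    strand=strand,
                    ko=ko,
                    weight=float(weights[i]),
                )
            )
            pos = end

    return CommunityTruth(
        genomes=specs,
        abundances=ab,
        gene_models=gene_models,
        sequences=sequences,
        ko_categories=ko_categories,
        expr_params={"distribution": "lognormal", "mu": expr_mu, "sigma": expr_sigma},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seqs: list[str], error_rate: float, rng: np.random.Generator) -> None:
    """In-place i.i.d. substitution errors at ``error_rate`` per base."""
    if error_rate <= 0 or not seqs:
        return
    chunk = 2000
    for c0 in range(0, len(seqs), chunk):
        block = seqs[c0:c0 + chunk]
        L = len(block[0])
        mask = rng.random((len(block), L)) < error_rate
        if not mask.any():
            continue
        subs = rng.integers(1, 4, size=int(mask.sum()))
        si = 0
        for bi, row in enumerate(mask):
            if not row.any():
                continue
            s = list(block[bi])
            for pos in np.flatnonzero(row):
                orig = "ACGT".find(s[pos])
                if orig < 0:
                    si += 1
                    continue
                s[pos] = "ACGT"[(orig + int(subs[si])) % 4]
                si += 1
            seqs[c0 + bi] = "".join(s)


def simulate_dna_reads(
    truth: CommunityTruth,
    n_pairs: int,
    read_len: int = 101,
    insert_mean: int = 500,
    insert_sd: float = 50.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Simulate paired-end shotgun DNA reads (FR orientation).

    Pairs are drawn from genomes with probability proportional to
    abundance x length; inserts are normal(``insert_mean``, ``insert_sd``)
    clipped to [read_len, genome length]; substitution errors are i.i.d. at
    ``error_rate``. Each read records its origin genome and 0-based start.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    if read_len > insert_mean:
        raise ValueError("read_len must not exceed insert_mean")

    rng = np.random.default_rng(seed)
    lengths = np.array([g.length for g in truth.genomes], dtype=float)
    p = truth.abundances * lengths
    p = p / p.sum()
    counts = rng.multinomial(n_pairs, p)

    mate1: list[str] = []
    mate2: list[str] = []
    origins: list[str] = []
    positions: list[int] = []
    for g, n_g in zip(truth.genomes, counts):
        if n_g == 0:
            continue
        seq = truth.sequences[g.name]
        L = g.length
        ins = np.rint(rng.normal(insert_mean, insert_sd, size=n_g)).astype(int)
        ins = np.clip(ins, read_len, L)
        starts = (rng.random(n_g) * (L - ins + 1)).astype(int)
        for s, i in zip(starts, ins):
            mate1.append(seq[s:s + read_len])
            mate2.append(sequtils.revcomp(seq[s + i - read_len:s + i]))
            origins.append(g.name)
            positions.append(int(s))

    order = rng.permutation(len(mate1))  # drawn before error noise so the
    # read order is invariant to the error rate
    _apply_errors(mate1, error_rate, rng)
    _apply_errors(mate2, error_rate, rng)
    records = [
        Read(
            id=f"pair{j:07d}",
            mate1=mate1[i],
            mate2=mate2[i],
            origin=origins[i],
            position=positions[i],
        )
        for j, i in enumerate(order)
    ]
    return ReadSet(records)


def simulate_cdna_reads(
    truth: CommunityTruth,
    n_reads: int,
    read_len: int = 101,
    seed: int = 0,
) -> tuple[ReadSet, dict[str, float]]:
    """Simulate single-end cDNA reads from gene intervals.

    A read comes from gene ``g`` with probability proportional to
    abundance(genome) x expression weight x gene length; reads from minus
    strand genes are reverse complemented. Returns the read set and the exact
    per-gene sampling probabilities (summing to 1).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    genes = truth.gene_models
    w = np.array(
        [truth.abundance_of(g.genome) * g.weight * g.length for g in genes],
        dtype=float,
    )
    if w.sum() <= 0:
        raise ValueError("all expression weights are zero")
    for name in truth.names:
        if not any(g.weight > 0 for g in truth.genes_of(name)):
            raise ValueError(f"genome {name} has no gene with positive weight")
    probs = w / w.sum()
    true_probs = {g.gene_id: float(pi) for g, pi in zip(genes, probs)}
    if n_reads == 0:
        return ReadSet([]), true_probs

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)
    records: list[Read] = []
    j = 0
    for g, n_g in zip(genes, counts):
        if n_g == 0:
            continue
        seq = truth.sequences[g.genome]
        glen = len(seq)
        hi = max(g.start, min(g.end - read_len, glen - read_len))
        starts = rng.integers(g.start, hi + 1, size=n_g)
        for s in starts:
            frag = seq[s:s + read_len]
            if g.strand == "-":
                frag = sequtils.revcomp(frag)
            records.append(
                Read(id=f"cdna{j:07d}", mate1=frag, origin=g.gene_id, position=int(s))
            )
            j += 1
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    records = [
        Read(f"cdna{j:07d}", r.mate1, None, r.origin, r.position)
        for j, r in enumerate(records)
    ]
    return ReadSet(records), true_probs


# ---------------------------------------------------------------------------
# assembly stand-in
# ---------------------------------------------------------------------------

def fragment_genomes(
    truth: CommunityTruth,
    fragment_len,
    min_len: int = 500,
    seed: int = 0,
    depth: float = 100.0,
    coverage_noise_sd: float = 0.1,
    label_taxonomy: bool = False,
) -> ContigSet:
    """Tile each genome into contigs, substituting for de novo assembly.

    ``fragment_len`` is either a constant int or an inclusive (lo, hi) range
    sampled uniformly. Each contig is an exact substring of its source genome
    and carries a coverage value of abundance x ``depth`` with multiplicative
    lognormal noise (sd ``coverage_noise_sd``; 0 disables noise). Trailing
    fragments shorter than ``min_len`` are dropped.
    """
    if min_len < 500:
        raise ValueError("min_len must be >= 500")
    if isinstance(fragment_len, (tuple, list)):
        lo, hi = int(fragment_len[0]), int(fragment_len[1])
        if lo > hi or lo < min_len:
            raise ValueError("invalid fragment length range")
    else:
        lo = hi = int(fragment_len)
        if lo < min_len:
            raise ValueError("fragment_len must be >= min_len")

    rng = np.random.default_rng(seed)
    records: list[Contig] = []
    for g in truth.genomes:
        seq = truth.sequences[g.name]
        base_cov = truth.abundance_of(g.name) * depth
        pos = 0
        i = 0
        while g.length - pos >= min_len:
            L = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            L = min(L, g.length - pos)
            if L < min_len:
                break
            i += 1
            noise = (
                float(np.exp(rng.normal(0.0, coverage_noise_sd)))
                if coverage_noise_sd > 0
                else 1.0
            )
            records.append(
                Contig(
                    id=f"{g.name}_c{i:04d}",
                    seq=seq[pos:pos + L],
                    coverage=base_cov * noise,
                    taxonomy=g.name if label_taxonomy else None,
                    origin=g.name,
                    origin_start=pos,
                )
            )
            pos += L
    return ContigSet(records)


# ---------------------------------------------------------------------------
# truth table output
# ---------------------------------------------------------------------------

def write_truth_tables(truth: CommunityTruth, outdir) -> dict[str, str]:
    """Write genomes (FASTA), gene models and abundances (TSV) to ``outdir``.

    Gene coordinates are written 1-based inclusive (GFF-like convention).
    Returns the mapping of table name to path.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": str(outdir / "genomes.fasta"),
        "genes": str(outdir / "genes.tsv"),
        "abundances": str(outdir / "abundances.tsv"),
    }
    sequtils.write_fasta(paths["genomes"], truth.sequences.items())
    with open(paths["genes"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "genome", "start", "end", "strand", "ko",
                    "category", "weight"])
        for g in truth.gene_models:
            w.writerow([g.gene_id, g.genome, g.start + 1, g.end, g.strand,
                        g.ko, truth.ko_categories.get(g.ko, ""), f"{g.weight:.6g}"])
    with open(paths["abundances"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome", "abundance", "length", "gc"])
        for g, a in zip(truth.genomes, truth.abundances):
            w.writerow([g.name, f"{a:.6g}", g.length, f"{g.gc:.4f}"])
    return paths
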