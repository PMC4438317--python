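"""'Divide and conquer' pre-assembly read partitioning.

Counts canonical k-mers across a read pool and splits reads into high- and
low-abundance groups by a per-read k-mer depth threshold, so that dominant
and rare genomes can be assembled separately. Defaults follow the study
conditions: k = 31, depth threshold 15, minimum read length 63 bp.

The per-read depth statistic is the MEDIAN canonical k-mer count (the
convention of khmer-style abundance partitioning; robust to single erroneous
k-mers). A pair is assigned by the maximum of its two mates' depths so mates
stay together.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import sequtils
from .containers import Read, ReadSet

__all__ = ["KmerCountTable", "PartitionResult", "count_kmers", "read_depth",
           "partition_reads", "write_partition"]

_ACGT = frozenset("ACGT")


@dataclass
class KmerCountTable:
    """Exact canonical k-mer -> count table."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


@dataclass
class PartitionResult:
    """High/low/discarded partition of a read pool."""

    high: ReadSet
    low: ReadSet
    discarded: ReadSet
    threshold: float
    k: int
    min_len: int

    def summary(self) -> list[dict]:
        rows = []
        for group, rs in (("high", self.high), ("low", self.low),
                          ("discarded", self.discarded)):
            bases = sum(
                len(r.mate1) + (len(r.mate2) if r.mate2 else 0) for r in rs
            )
            rows.append({"group": group, "pairs": len(rs), "bases": bases})
        return rows


def _bad_prefix(seq: str) -> np.ndarray | None:
    """Cumulative count of non-ACGT symbols, or None if the sequence is clean."""
    if _ACGT.issuperset(seq):
        return None
    bad = np.fromiter((c not in _ACGT for c in seq), dtype=np.int32, count=len(seq))
    return np.concatenate(([0], np.cumsum(bad)))


def _iter_canonical(seq: str, k: int):
    """Yield the canonical form of every clean length-k window of ``seq``."""
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return
    rc = sequtils.revcomp(seq)
    cum = _bad_prefix(seq)
    for i in range(n - k + 1):
        if cum is not None and cum[i + k] - cum[i]:
            continue
        f = seq[i:i + k]
        r = rc[n - i - k:n - i]
        yield f if f <= r else r


def count_kmers(reads: ReadSet, k: int = 31) -> KmerCountTable:
    """Count canonical k-mers over every mate of every read.

    k must be odd (even k makes a k-mer its own reverse complement possible,
    so canonicalization would be ambiguous) and within [3, 63]. Windows
    containing non-ACGT symbols are skipped.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonicalization ambiguity)")
    if not 3 <= k <= 63:
        raise ValueError("k must be in [3, 63]")
    counts: dict[str, int] = {}
    for read in reads:
        for mate in (read.mate1, read.mate2):
            if mate is None:
                continue
            for c in _iter_canonical(mate, k):
                counts[c] = counts.get(c, 0) + 1
    return KmerCountTable(k=k, counts=counts)


def read_depth(seq: str, table: KmerCountTable) -> float:
    """Median canonical k-mer count of a read (absent k-mers count 0).

    Windows containing non-ACGT symbols are excluded. Raises ValueError for
    reads that cannot be scored (shorter than k, or no clean window).
    """
    if len(seq) < table.k:
        raise ValueError("read shorter than k: unscorable")
    depths = [table.get(c) for c in _iter_canonical(seq, table.k)]
    if not depths:
        raise ValueError("read has no valid k-mer window: unscorable")
    return float(np.median(depths))


def partition_reads(
    reads: ReadSet,
    table: KmerCountTable,
    depth_threshold: float = 15,
    min_len: int = 63,
) -> PartitionResult:
    """Split reads into high (depth >= threshold), low, and discarded groups.

    A mate is scorable if it is at least ``min_len`` bp (and at least k bp)
    long; reads whose mates are all unscorable are discarded. Pairs are
    scored by the maximum of their mates' median depths and kept together.
    """
    if depth_threshold < 0:
        raise ValueError("depth_threshold must be >= 0")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    high: list[Read] = []
    low: list[Read] = []
    discarded: list[Read] = []
    for read in reads:
        depths = []
        for mate in (read.mate1, read.mate2):
            if mate is None or len(mate) < min_len or len(mate) < table.k:
                continue
            try:
                depths.append(read_depth(mate, table))
            except ValueError:
                continue
        if not depths:
            discarded.append(read)
        elif max(depths) >= depth_threshold:
            high.append(read)
        else:
            low.append(read)
    return PartitionResult(
        high=ReadSet(high),
        low=ReadSet(low),
        discarded=ReadSet(discarded),
        threshold=depth_threshold,
        k=table.k,
        min_len=min_len,
    )


def write_partition(result: PartitionResult, out_prefix) -> dict[str, str]:
    """Write partition FASTQs (``<prefix>.high_[12].fastq`` etc.) and a TSV
    summary; returns the paths written."""
    out_prefix = str(out_prefix)
    paths: dict[str, str] = {}
    for group, rs in (("high", result.high), ("low", result.low)):
        for p in rs.write_fastq(f"{out_prefix}.{group}"):
            paths[p.rsplit("/", 1)[-1]] = p
    disc_path = f"{out_prefix}.discarded.fastq"
    sequtils.write_fastq(
        disc_path,
        (
            (f"{r.id}/{i + 1}", m)
            for r in result.discarded
            for i, m in enumerate((r.mate1, r.mate2))
            if m is not None
        ),
    )
    paths["discarded.fastq"] = disc_path
    summary_path = f"{out_prefix}.summary.tsv"
    with open(summary_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["group", "pairs", "bases"],
                           delimiter="\t", lineterminator="\n")
        w.writeheader()
        w.writerows(result.summary())
    paths["summary.tsv"] = summary_path
    return paths
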