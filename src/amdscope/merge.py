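"""Post-assembly contig processing.

Splits scaffolds at N-runs, removes redundant (contained) contigs at 98%
identity with full coverage of the shorter sequence (CD-hit style
``-c 0.98 -aS 1 -g 1 -r 1``), and greedily merges contigs sharing
high-identity suffix/prefix overlaps (Newbler/Minimus2 style: >= 40 bp at
>= 98% identity), iterating to a fixpoint.

Identity is computed from edit distance (edlib) over the aligned span:
identity = 1 - editDistance / span.
"""
from __future__ import annotations

import logging
import re

import edlib
import pandas as pd

from . import sequtils
from .containers import Contig, ContigSet

__all__ = ["split_scaffolds", "dereplicate", "merge_overlaps", "pool_by_length"]

log = logging.getLogger(__name__)

_N_RUN = re.compile("[Nn]+")


def split_scaffolds(scaffolds: ContigSet) -> ContigSet:
    """Break each scaffold into contigs at runs of one or more Ns.

    Each maximal N-free segment becomes ``<scaffold>_<i>`` (1-based); a
    scaffold without Ns is kept unchanged. Segments inherit the parent's
    coverage and labels. All-N scaffolds vanish.
    """
    out: list[Contig] = []
    for sc in scaffolds:
        parts = [p for p in _N_RUN.split(sc.seq) if p]
        if len(parts) == 1 and parts[0] == sc.seq:
            out.append(sc)
            continue
        for i, part in enumerate(parts, start=1):
            out.append(
                Contig(
                    id=f"{sc.id}_{i}",
                    seq=part,
                    coverage=sc.coverage,
                    taxonomy=sc.taxonomy,
                    origin=sc.origin,
                )
            )
    return ContigSet(out)


def _contained(query: str, target: str, max_ed: int) -> int:
    """Edit distance of the best full-query infix alignment, or -1."""
    if len(query) > len(target) + max_ed:
        return -1
    res = edlib.align(query, target, mode="HW", task="distance", k=max_ed)
    return res["editDistance"]


def dereplicate(
    contigs: ContigSet,
    identity: float = 0.98,
    short_coverage: float = 1.0,
    return_report: bool = False,
):
    """Remove contigs contained in a longer (or earlier, on ties) contig.

    Greedy longest-first clustering: a contig is removed if it aligns, on
    either strand, over its full length to an already-kept contig at
    >= ``identity``. Kept contigs are returned in input order. Only
    ``short_coverage = 1.0`` (full containment of the shorter sequence,
    the CD-hit ``-aS 1`` setting used here) is supported.
    """
    if not 0.9 < identity <= 1.0:
        raise ValueError("identity must be in (0.9, 1.0]")
    if short_coverage != 1.0:
        raise ValueError("only short_coverage=1.0 (full containment) is supported")

    records = list(contigs)
    order = sorted(range(len(records)), key=lambda i: (-records[i].length, i))
    kept: list[int] = []
    removed: set[int] = set()
    rows = []
    for i in order:
        q = records[i].seq.upper()
        max_ed = int((1.0 - identity) * len(q))
        hit = None
        for j in kept:
            t = records[j].seq.upper()
            ed = _contained(q, t, max_ed)
            strand = "+"
            if ed < 0:
                ed = _contained(sequtils.revcomp(q), t, max_ed)
                strand = "-"
            if ed >= 0:
                hit = (j, ed, strand)
                break
        if hit is None:
            kept.append(i)
        else:
            j, ed, strand = hit
            removed.add(i)
            rows.append({
                "representative": records[j].id,
                "member": records[i].id,
                "identity": 1.0 - ed / len(q),
                "coverage_of_shorter": 1.0,
                "strand": strand,
            })
    out = ContigSet([c for i, c in enumerate(records) if i not in removed])
    if return_report:
        return out, pd.DataFrame(
            rows, columns=["representative", "member", "identity",
                           "coverage_of_shorter", "strand"])
    return out


def _best_suffix_prefix(a: str, b: str, min_overlap: int, min_identity: float):
    """Best (overlap, identity) where a suffix of ``a`` matches a prefix of
    ``b`` at >= min_identity over >= min_overlap bases; None if none."""
    best = None
    k = min(16, min_overlap)
    for j in (0, k, 2 * k):
        if j + k > len(b):
            break
        anchor = b[j:j + k]
        start = 0
        while (p := a.find(anchor, start)) != -1:
            start = p + 1
            ov = len(a) - p + j
            if ov < min_overlap or ov > len(a) or ov > len(b):
                continue
            ed = edlib.align(b[:ov], a[len(a) - ov:], mode="NW",
                             task="distance")["editDistance"]
            ident = 1.0 - ed / ov
            if ident >= min_identity and (best is None or ov > best[0]):
                best = (ov, ident)
    return best


def _merge_pair(a: Contig, bseq: str, b: Contig, ov: int, counter: list[int]) -> Contig:
    """Merge ``a`` with oriented sequence ``bseq`` of ``b`` over ``ov`` bases.

    Overlap disagreements take the longer contig's bases."""
    aseq = a.seq
    if len(aseq) >= len(bseq):
        merged = aseq + bseq[ov:]
    else:
        merged = aseq[:len(aseq) - ov] + bseq
    counter[0] += 1
    cov = None
    if a.coverage is not None and b.coverage is not None:
        cov = (a.coverage * len(aseq) + b.coverage * len(bseq)) / (
            len(aseq) + len(bseq))
    origin = a.origin if a.origin == b.origin else None
    tax = a.taxonomy if a.taxonomy == b.taxonomy else None
    return Contig(id=a.id, seq=merged, coverage=cov, taxonomy=tax, origin=origin)


def merge_overlaps(
    contigs: ContigSet,
    min_identity: float = 0.98,
    min_overlap: int = 40,
) -> ContigSet:
    """Greedily merge contigs sharing suffix/prefix overlaps to a fixpoint.

    Both strands are considered; at each step the longest qualifying overlap
    (ties: higher identity, then input order) is merged. The merged contig
    keeps the first contig's id; overlap disagreements are resolved in favor
    of the longer contig. Input should be dereplicated (containments are not
    merged). Self-merges are never attempted, so overlap cycles terminate by
    contig-count decrease; the remaining junction is left unmerged and logged.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0.5 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0.5, 1.0]")

    pool: list[Contig] = list(contigs)
    n_merged = [0]
    while True:
        best = None  # (ov, ident, i, j, oriented_b_seq)
        for i, a in enumerate(pool):
            for j, b in enumerate(pool):
                if i == j:
                    continue
                for bseq in (b.seq, sequtils.revcomp(b.seq)):
                    hit = _best_suffix_prefix(a.seq, bseq, min_overlap,
                                              min_identity)
                    if hit is None:
                        continue
                    ov, ident = hit
                    if best is None or (ov, ident) > (best[0], best[1]):
                        best = (ov, ident, i, j, bseq)
        if best is None:
            break
        ov, ident, i, j, bseq = best
        merged = _merge_pair(pool[i], bseq, pool[j], ov, n_merged)
        pool = [c for idx, c in enumerate(pool) if idx not in (i, j)]
        pool.insert(min(i, j), merged)
    if n_merged[0]:
        log.info("merge_overlaps: %d merges, %d contigs remain",
                 n_merged[0], len(pool))
    return ContigSet(pool)


def pool_by_length(contigs: ContigSet, threshold: int = 2000) -> tuple[ContigSet, ContigSet]:
    """Partition contigs into (short, long) pools; length >= threshold is long."""
    short = [c for c in contigs if c.length < threshold]
    longs = [c for c in contigs if c.length >= threshold]
    return ContigSet(short), ContigSet(longs)
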