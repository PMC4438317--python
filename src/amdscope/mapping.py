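"""Deterministic exact-seed read mapping.

A light mapper for synthetic, error-free or low-error reads: each reference
position's canonical 31-mer is indexed; a read is placed by the first
unambiguous exact seed hit, scanning a few offsets so reads overhanging a
contig end still map by their clean side. Seeds occurring at more than one
indexed position are ambiguous and skipped.
"""
from __future__ import annotations

from typing import Optional

import pandas as pd

from . import sequtils
from .containers import ReadSet

__all__ = ["SeedIndex", "map_pairs", "map_mates"]

_ACGT = frozenset("ACGT")


class SeedIndex:
    """Canonical k-mer -> (reference, position, orientation) index."""

    def __init__(self, seqs: dict[str, str], seed_len: int = 31):
        if seed_len % 2 == 0 or seed_len < 11:
            raise ValueError("seed_len must be odd and >= 11")
        self.k = seed_len
        self.index: dict[str, Optional[tuple[str, int, bool]]] = {}
        k = seed_len
        for name, seq in seqs.items():
            seq = seq.upper()
            n = len(seq)
            if n < k:
                continue
            rc = sequtils.revcomp(seq)
            clean = _ACGT.issuperset(seq)
            for i in range(n - k + 1):
                f = seq[i:i + k]
                if not clean and not _ACGT.issuperset(f):
                    continue
                r = rc[n - i - k:n - i]
                fwd_is_canon = f <= r
                c = f if fwd_is_canon else r
                if c in self.index:
                    self.index[c] = None  # ambiguous
                else:
                    self.index[c] = (name, i, fwd_is_canon)

    def locate(self, read: str, step: int = 10) -> Optional[tuple[str, int, int]]:
        """Return (reference, 0-based read start, strand ±1) or None.

        Seeds are tried at offsets 0, step, 2*step, ... plus the final
        offset; the first unambiguous hit wins.
        """
        k = self.k
        n = len(read)
        if n < k:
            return None
        read = read.upper()
        offsets = list(range(0, n - k + 1, step))
        if offsets[-1] != n - k:
            offsets.append(n - k)
        for o in offsets:
            w = read[o:o + k]
            wrc = sequtils.revcomp(w)
            w_is_canon = w <= wrc
            hit = self.index.get(w if w_is_canon else wrc, False)
            if hit is False or hit is None:
                continue
            name, pos, fwd_is_canon = hit
            if w_is_canon == fwd_is_canon:  # read window equals reference window
                return name, pos - o, 1
            return name, pos - (n - k - o), -1
        return None


def map_pairs(reads: ReadSet, index: SeedIndex) -> pd.DataFrame:
    """Map one row per pair (mate1, falling back to mate2).

    Columns: read_id, reference (None if unmapped), start, strand.
    """
    rows = []
    for r in reads:
        loc = index.locate(r.mate1)
        if loc is None and r.mate2 is not None:
            loc = index.locate(r.mate2)
        name, start, strand = loc if loc is not None else (None, -1, 0)
        rows.append((r.id, name, start, strand))
    return pd.DataFrame(rows, columns=["read_id", "reference", "start", "strand"])


def map_mates(reads: ReadSet, index: SeedIndex) -> pd.DataFrame:
    """Map every mate independently (one row per mate)."""
    rows = []
    for r in reads:
        for mi, mate in enumerate((r.mate1, r.mate2), start=1):
            if mate is None:
                continue
            loc = index.locate(mate)
            name, start, strand = loc if loc is not None else (None, -1, 0)
            rows.append((f"{r.id}/{mi}", name, start, strand, len(mate)))
    return pd.DataFrame(
        rows, columns=["read_id", "reference", "start", "strand", "length"])
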