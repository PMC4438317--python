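"""Shared in-memory containers: reads, contigs and their file round trips."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from . import sequtils


@dataclass(frozen=True)
class Read:
    """A sequencing read (paired if ``mate2`` is set) with optional truth labels."""

    id: str
    mate1: str
    mate2: Optional[str] = None
    origin: Optional[str] = None
    position: Optional[int] = None


@dataclass
class ReadSet:
    """An ordered collection of (possibly paired) reads."""

    records: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.records)

    @property
    def paired(self) -> bool:
        return bool(self.records) and self.records[0].mate2 is not None

    def write_fastq(self, prefix) -> list[str]:
        """Write ``<prefix>_1.fastq`` (+ ``_2`` when paired); returns paths written."""
        prefix = str(prefix)
        paths = [f"{prefix}_1.fastq"]
        sequtils.write_fastq(paths[0], ((r.id, r.mate1) for r in self.records))
        if self.paired:
            paths.append(f"{prefix}_2.fastq")
            sequtils.write_fastq(paths[1], ((r.id, r.mate2) for r in self.records))
        return paths

    @classmethod
    def from_fastq(cls, path1, path2=None) -> "ReadSet":
        r1 = sequtils.read_fastq(path1)
        if path2 is None:
            return cls([Read(i, s) for i, s in r1])
        r2 = sequtils.read_fastq(path2)
        if len(r1) != len(r2):
            raise ValueError("mate files have different record counts")
        return cls([Read(i1, s1, s2) for (i1, s1), (_, s2) in zip(r1, r2)])


@dataclass(frozen=True)
class Contig:
    """A contig/scaffold record with optional coverage and truth labels."""

    id: str
    seq: str
    coverage: Optional[float] = None
    taxonomy: Optional[str] = None
    origin: Optional[str] = None
    origin_start: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ContigSet:
    """An ordered collection of contigs with unique ids."""

    records: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("contig ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.records)

    def __getitem__(self, i: int) -> Contig:
        return self.records[i]

    def get(self, contig_id: str) -> Contig:
        for c in self.records:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.records]

    def sequences(self) -> dict[str, str]:
        return {c.id: c.seq for c in self.records}

    def total_bases(self) -> int:
        return sum(c.length for c in self.records)

    def to_fasta(self, path) -> int:
        return sequtils.write_fasta(path, ((c.id, c.seq) for c in self.records))

    @classmethod
    def from_fasta(cls, path, coverages: Optional[dict] = None,
                   taxonomy: Optional[dict] = None) -> "ContigSet":
        coverages = coverages or {}
        taxonomy = taxonomy or {}
        return cls([
            Contig(i, s, coverage=coverages.get(i), taxonomy=taxonomy.get(i))
            for i, s in sequtils.read_fasta(path)
        ])


def subset(contigs: ContigSet, keep: Sequence[str]) -> ContigSet:
    keep_set = set(keep)
    return ContigSet([c for c in contigs if c.id in keep_set])
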