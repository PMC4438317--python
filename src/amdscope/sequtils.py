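"""Low-level nucleotide sequence helpers shared across the pipeline."""
from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte lookup: A/C/G/T (upper or lower) -> 0..3, anything else -> 4
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE_LUT[_c] = _i
for _i, _c in enumerate(b"acgt"):
    _CODE_LUT[_c] = _i


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N, case is preserved."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes 0..3 (A,C,G,T); other symbols become 4."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).tobytes().translate(
        bytes.maketrans(bytes(range(4)), b"ACGT")
    ).decode("ascii")


# ---------------------------------------------------------------------------
# FASTA / FASTQ round trips (Biopython-backed)
# ---------------------------------------------------------------------------

def write_fasta(path, records: Iterable[tuple[str, str]]) -> int:
    """Write (id, sequence) pairs as FASTA; returns the number of records."""
    return SeqIO.write(
        (SeqRecord(Seq(s), id=str(n), description="") for n, s in records),
        str(path),
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(path, records: Iterable[tuple[str, str]], quality: int = 30) -> int:
    """Write (id, sequence) pairs as FASTQ with a constant Phred quality."""
    def _gen() -> Iterator[SeqRecord]:
        for name, seq in records:
            rec = SeqRecord(Seq(seq), id=str(name), description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            yield rec

    return SeqIO.write(_gen(), str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]
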