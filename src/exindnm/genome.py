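"""Genome sequence container and nucleotide encoding.

Sequences are kept as uppercase strings over {A, C, G, T, N} and lazily
encoded to ``uint8`` arrays (A=0, C=1, G=2, T=3, N=4) for vectorised
k-mer arithmetic.  All coordinates in the package are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (N and anything else -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass
class GenomeSequence:
    """Per-chromosome nucleotide sequences.

    Invariants: chromosome names unique; every base in {A,C,G,T,N}.
    """

    sequences: dict[str, str]
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        clean = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {name} contains invalid bases {sorted(bad)}")
            clean[name] = seq
        self.sequences = clean

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def codes(self, chrom: str) -> np.ndarray:
        """Cached uint8 encoding of a chromosome."""
        if chrom not in self._codes:
            self._codes[chrom] = encode(self.sequences[chrom])
        return self._codes[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(records)


def gc_content(seq: str) -> float:
    """Fraction of G+C among non-N bases."""
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / total
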