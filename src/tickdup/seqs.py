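"""Coding-sequence container and FASTA I/O (Bio.SeqIO-backed)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class CodingSequence:
    """A nucleotide coding/transcript sequence with identity and provenance."""

    id: str
    seq: str
    source: str = ""  # e.g. "singleton", "pair", "family", "tc", "input"

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self) -> "CodingSequence":
        return CodingSequence(self.id, str(Seq(self.seq).reverse_complement()), self.source)


def read_fasta(path: str | Path, source: str = "input") -> list[CodingSequence]:
    return [
        CodingSequence(rec.id, str(rec.seq).upper(), source)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
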