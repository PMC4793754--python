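"""Six-frame open-reading-frame extraction and longest-ORF selection.

ORFs are maximal stop-to-stop regions: every run of codons strictly between
stop codons (or between a sequence boundary and a stop) in each of the six
reading frames, with at least ``min_codons`` codons. This is the
stop-to-stop convention of classic ORF scanners, not ATG-initiated — it
maximizes recovered coding length from transcript fragments. Terminal
partial codons are discarded. Ambiguous bases translate to X and never
count as stop codons.

Coordinates are 0-based half-open on the forward strand of the parent
sequence; ``frame`` is the frame offset on the reading strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

from ._codons import translate_codon
from .seqs import CodingSequence

__all__ = ["Orf", "find_orfs", "longest_orf", "orf_table", "NoOrfError"]

IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")


class NoOrfError(ValueError):
    """A sequence yielded no ORF of the required minimum length."""


@dataclass(frozen=True)
class Orf:
    parent_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 on the reading strand
    start: int  # forward-strand coordinates, 0-based half-open
    end: int
    protein: str

    @property
    def aa_length(self) -> int:
        return len(self.protein)

    def nucleotides(self, parent_seq: str) -> str:
        """Reading-strand nucleotide sequence of the ORF."""
        region = parent_seq[self.start : self.end]
        if self.strand == "-":
            region = str(Seq(region).reverse_complement())
        return region


def _scan_frames(seq: str, min_codons: int) -> Iterable[tuple[int, int, int, str]]:
    """Yield (frame, start, end, protein) stop-to-stop runs on one strand."""
    n = len(seq)
    for frame in range(3):
        run_start = frame
        protein: list[str] = []
        for pos in range(frame, n - 2, 3):
            aa = translate_codon(seq[pos : pos + 3])
            if aa == "*":
                if len(protein) >= min_codons:
                    yield frame, run_start, pos, "".join(protein)
                run_start = pos + 3
                protein = []
            else:
                protein.append(aa)
        if len(protein) >= min_codons:
            yield frame, run_start, run_start + 3 * len(protein), "".join(protein)


def find_orfs(seq: CodingSequence, min_codons: int = 30) -> list[Orf]:
    """All stop-to-stop ORFs of >= ``min_codons`` codons in six frames."""
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    s = seq.seq.upper().replace("U", "T")
    if len(s) < 3:
        raise ValueError(f"sequence {seq.id!r} shorter than one codon")
    bad = set(s) - IUPAC_NT
    if bad:
        raise ValueError(f"sequence {seq.id!r} contains non-IUPAC characters {bad}")
    orfs: list[Orf] = []
    for frame, start, end, protein in _scan_frames(s, min_codons):
        orfs.append(Orf(seq.id, "+", frame, start, end, protein))
    rc = str(Seq(s).reverse_complement())
    n = len(s)
    for frame, start, end, protein in _scan_frames(rc, min_codons):
        # mirror reverse-strand coordinates back to the forward strand
        orfs.append(Orf(seq.id, "-", frame, n - end, n - start, protein))
    return orfs


def longest_orf(orfs: list[Orf]) -> Orf:
    """The ORF with maximal amino-acid length.

    Ties break to the '+' strand, then to the smallest forward-strand
    start. Raises :class:`NoOrfError` on an empty list so callers can drop
    the sequence from pairing and log it.
    """
    if not orfs:
        raise NoOrfError("no ORF found")
    return max(orfs, key=lambda o: (o.aa_length, o.strand == "+", -o.start))


def orf_table(orf_lists: Iterable[list[Orf]]) -> pd.DataFrame:
    rows = [
        {
            "parent_id": o.parent_id,
            "strand": o.strand,
            "frame": o.frame,
            "start": o.start,
            "end": o.end,
            "aa_length": o.aa_length,
        }
        for orfs in orf_lists
        for o in orfs
    ]
    return pd.DataFrame(
        rows, columns=["parent_id", "strand", "frame", "start", "end", "aa_length"]
    )
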