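"""Nei–Gojobori (1986) counting estimator of Ka and Ks with Jukes–Cantor
multiple-hit correction, and the selection classification built on it.

For each paralog pair the nucleotide sequences are turned into a gap-free
codon alignment (by back-translating a global protein alignment), synonymous
and nonsynonymous sites and differences are counted, proportions are
corrected for multiple hits, and the Ka/Ks ratio is classified as positive
(> 1), negative (< 1) or neutral selection. Pairs that are identical, lack
synonymous substitutions, or are saturated (p >= 3/4, where the correction
is undefined) are excluded — older duplications are confounded by sequence
saturation, so no rate is reported for them.

Differences between codons that disagree at several positions are
pathway-averaged: all orderings of the single-nucleotide steps are
enumerated, orderings passing through a stop codon are discarded, and the
synonymous/nonsynonymous step counts are averaged over the remaining
orderings (equal weights, classic NG86).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import GENETIC_CODE, SYN_SITES, is_stop

SATURATION_P = 0.75

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "build_codon_alignment",
    "count_sites",
    "count_differences",
    "compute_kaks",
    "classify_selection",
    "jukes_cantor",
]


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free codon alignment of one pair (no stops, gaps or Ns)."""

    pair_id: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon columns must have equal length")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float | None
    label: str  # positive | negative | neutral | excluded
    exclusion_reason: str  # identical | ks_zero | saturated | no_sites | none
    n_codons: int = 0
    n_skipped_columns: int = 0

    @property
    def excluded(self) -> bool:
        return self.label == "excluded"


def count_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site fractions of a sense codon.

    Per position: (synonymous non-stop alternatives) / (non-stop
    alternatives); s + n = 3 exactly. Stop codons are rejected.
    """
    s = SYN_SITES.get(codon)
    if s is None:
        if is_stop(codon):
            raise ValueError(f"stop codon {codon!r}")
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between two
    sense codons.

    All orderings of the differing positions are enumerated; orderings that
    pass through a stop codon are discarded; counts are averaged over the
    valid orderings. Returns (sd, nd) with sd + nd = number of differing
    positions. Raises ValueError when every ordering passes through a stop
    (the column should be skipped).
    """
    if is_stop(codon_a) or is_stop(codon_b):
        raise ValueError("stop codon in aligned column")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_s = 0.0
    total_n = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        cur = codon_a
        path_s = 0
        path_n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        if ok:
            n_valid += 1
            total_s += path_s
            total_n += path_n
    if n_valid == 0:
        raise ValueError(
            f"all mutational pathways between {codon_a} and {codon_b} pass through stops"
        )
    return total_s / n_valid, total_n / n_valid


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= SATURATION_P:
        raise ValueError("proportion at or beyond saturation (p >= 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_VALID = frozenset("ACGT")


def build_codon_alignment(
    pair_id: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Codon alignment of two in-frame coding sequences.

    The protein translations are globally aligned; the alignment is
    back-translated to codons and every column containing a gap, a stop or
    an ambiguous base is dropped.
    """
    codons_a = [cds_a[i : i + 3].upper() for i in range(0, len(cds_a) - len(cds_a) % 3, 3)]
    codons_b = [cds_b[i : i + 3].upper() for i in range(0, len(cds_b) - len(cds_b) % 3, 3)]
    prot_a = "".join(GENETIC_CODE.get(c, "X") for c in codons_a)
    prot_b = "".join(GENETIC_CODE.get(c, "X") for c in codons_b)
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    cols_a: list[str] = []
    cols_b: list[str] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            ca, cb = codons_a[i], codons_b[j]
            if is_stop(ca) or is_stop(cb):
                continue
            if not (_VALID.issuperset(ca) and _VALID.issuperset(cb)):
                continue
            cols_a.append(ca)
            cols_b.append(cb)
    return CodonAlignment(pair_id, tuple(cols_a), tuple(cols_b))


def compute_kaks(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks for one codon alignment.

    Sites are averaged over the two sequences; differences are
    pathway-averaged per column (columns whose pathways all hit stops are
    skipped and counted in ``n_skipped_columns``).
    """
    if aln.n_codons < 1:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    n_skipped = 0
    used = 0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        try:
            sd, nd = count_differences(ca, cb)
        except ValueError:
            n_skipped += 1
            continue
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        Sd += sd
        Nd += nd
        used += 1

    def _excluded(reason: str, pS: float = 0.0, pN: float = 0.0,
                  Ks: float = 0.0, Ka: float = 0.0) -> KaKsResult:
        return KaKsResult(aln.pair_id, S, N, Sd, Nd, pS, pN, Ks, Ka, None,
                          "excluded", reason, used, n_skipped)

    if used == 0 or S <= 0.0 or N <= 0.0:
        return _excluded("no_sites")
    if Sd == 0.0 and Nd == 0.0:
        return _excluded("identical")
    pS = Sd / S
    pN = Nd / N
    if pS >= SATURATION_P or pN >= SATURATION_P:
        return _excluded("saturated", pS, pN)
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    if Ks == 0.0:
        # no synonymous substitutions: ratio undefined
        return _excluded("ks_zero", pS, pN, Ks, Ka)
    ratio = Ka / Ks
    result = KaKsResult(aln.pair_id, S, N, Sd, Nd, pS, pN, Ks, Ka, ratio,
                        "unclassified", "none", used, n_skipped)
    label = classify_selection(result)
    return KaKsResult(aln.pair_id, S, N, Sd, Nd, pS, pN, Ks, Ka, ratio,
                      label, "none", used, n_skipped)


def classify_selection(result: KaKsResult, neutral_tol: float = 1e-9) -> str:
    """Selection label from the Ka/Ks ratio: > 1 positive, < 1 negative,
    within ``neutral_tol`` of 1 neutral."""
    if result.label == "excluded" or result.ratio is None:
        raise ValueError("cannot classify an excluded result")
    if abs(result.ratio - 1.0) <= neutral_tol:
        return "neutral"
    return "positive" if result.ratio > 1.0 else "negative"
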