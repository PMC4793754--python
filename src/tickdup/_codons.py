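"""Universal genetic code tables and per-codon site counts.

The standard (universal) code is hard-coded; no alternative translation
tables are supported.
"""

from __future__ import annotations

from itertools import product

NUCLEOTIDES = "ACGT"

GENETIC_CODE: dict[str, str] = {}
for _c, _aa in zip(
    ("".join(t) for t in product("TCAG", repeat=3)),
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
):
    GENETIC_CODE[_c] = _aa

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; 'X' when any base is not A/C/G/T."""
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        return "X"


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def synonymous_site_fraction(codon: str) -> float:
    """Synonymous sites in a sense codon (0..3), stop changes excluded.

    At each position the contribution is (synonymous alternatives) /
    (non-stop alternatives); positions whose every alternative is a stop
    contribute 0.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            non_stop += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s


# cached per-codon synonymous site counts for the 61 sense codons
SYN_SITES: dict[str, float] = {c: synonymous_site_fraction(c) for c in SENSE_CODONS}
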