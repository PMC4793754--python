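"""Independent brute-force oracles, written separately from the package
implementation and kept deliberately naive.

Each oracle recomputes a quantity by direct enumeration so the optimized
package code can be checked against it:

* six-frame ORF extraction by translating every frame string and splitting
  on stops;
* synonymous/nonsynonymous site and difference counting by exhaustive
  recursion over mutational pathways;
* Needleman–Wunsch-free identity via an exhaustive O(n*m) local-alignment
  dynamic program (small inputs only);
* graph connected components by hand-rolled breadth-first search.
"""

from __future__ import annotations

from collections import deque

# --- genetic code (independent copy, written from the codon wheel) -------

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODE = {}
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            CODE[_b1 + _b2 + _b3] = _AA[_i]
            _i += 1

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT.get(c, "N") for c in reversed(seq))


def translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(CODE.get(codon, "X"))
    return "".join(out)


# --- ORFs ----------------------------------------------------------------

def orfs_six_frames(seq: str, min_codons: int) -> set[tuple[str, int, int, str]]:
    """All stop-to-stop ORFs as (strand, fwd_start, fwd_end, protein)."""
    found: set[tuple[str, int, int, str]] = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            prot = translate(s[frame:])
            # split on stops, tracking codon offsets
            start_codon = 0
            current = []
            for ci, aa in enumerate(prot + "*"):
                if aa == "*":
                    if len(current) >= min_codons:
                        nt_start = frame + 3 * start_codon
                        nt_end = nt_start + 3 * len(current)
                        if strand == "-":
                            nt_start, nt_end = n - nt_end, n - nt_start
                        found.add((strand, nt_start, nt_end, "".join(current)))
                    start_codon = ci + 1
                    current = []
                else:
                    current.append(aa)
    return found


# --- NG86 counting -------------------------------------------------------

def site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) sites; stop alternatives excluded from
    the per-position denominator."""
    aa = CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = non_stop = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if CODE[mut] == "*":
                continue
            non_stop += 1
            if CODE[mut] == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


def _walk(cur: str, target: str, remaining: list[int], s: float, n: float, acc: list):
    if not remaining:
        acc.append((s, n))
        return
    for i, pos in enumerate(remaining):
        nxt = cur[:pos] + target[pos] + cur[pos + 1 :]
        if CODE[nxt] == "*":
            continue
        ds = 1 if CODE[nxt] == CODE[cur] else 0
        _walk(nxt, target, remaining[:i] + remaining[i + 1 :], s + ds,
              n + (1 - ds), acc)


def diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (sd, nd) by exhaustive recursion; raises ValueError
    when every pathway crosses a stop."""
    remaining = [i for i in range(3) if codon_a[i] != codon_b[i]]
    acc: list[tuple[float, float]] = []
    _walk(codon_a, codon_b, remaining, 0.0, 0.0, acc)
    if remaining and not acc:
        raise ValueError("no stop-free pathway")
    if not remaining:
        return 0.0, 0.0
    return (sum(s for s, _ in acc) / len(acc), sum(n for _, n in acc) / len(acc))


def ng86(codons_a: list[str], codons_b: list[str]):
    """(S, N, Sd, Nd, Ks, Ka) for a gap-free codon alignment, or None for a
    column-free/saturated case. Mirrors nothing from the package: sums are
    accumulated from the oracle's own counters and corrected in place."""
    from math import log

    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        try:
            sd, nd = diff_counts(ca, cb)
        except ValueError:
            continue
        sa, na = site_counts(ca)
        sb, nb = site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += sd
        Nd += nd
    pS = Sd / S
    pN = Nd / N
    if pS >= 0.75 or pN >= 0.75:
        return S, N, Sd, Nd, None, None
    Ks = -0.75 * log(1 - 4 * pS / 3)
    Ka = -0.75 * log(1 - 4 * pN / 3)
    return S, N, Sd, Nd, Ks, Ka


# --- exhaustive local alignment DP --------------------------------------

def local_identity(a: str, b: str, match: int = 2, mismatch: int = -1,
                   gap: int = -3) -> float:
    """Identity over aligned columns of the best-scoring local alignment
    (Smith–Waterman, linear gaps), by full DP with traceback."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            h = max(0, diag, H[i - 1][j] + gap, H[i][j - 1] + gap)
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    ident = cols = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        sc = match if a[i - 1] == b[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + sc:
            cols += 1
            ident += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
    return ident / cols if cols else 0.0


# --- connected components ------------------------------------------------

def bfs_components(edges: list[tuple[str, str]]) -> set[frozenset[str]]:
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen: set[str] = set()
    comps: set[frozenset[str]] = set()
    for node in adj:
        if node in seen:
            continue
        comp = set()
        queue = deque([node])
        while queue:
            cur = queue.popleft()
            if cur in comp:
                continue
            comp.add(cur)
            queue.extend(adj[cur] - comp)
        seen |= comp
        comps.add(frozenset(comp))
    return comps
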