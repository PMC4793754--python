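"""All-against-all paralog detection on longest-ORF proteins.

Each input sequence is reduced to its single longest ORF, every candidate
pair of proteins is locally aligned (BLOSUM62, affine gaps), and a pair is
retained when its identity exceeds the similarity threshold and both
coverage fractions meet the stringency level:

* low:    identity > 0.75, smaller member coverage >= 0.75, larger >= 0.50
* medium: identity > 0.75, coverages >= 0.85 / 0.70
* high:   identity > 0.75, coverages >= 0.95 / 0.80

"Similarity" is exact residue identity over aligned non-gap columns
(matrix-independent and reproducible); coverage is the local-alignment
span on each sequence divided by its full length. Reciprocality is
automatic because the pairwise alignment is symmetric. Sequences in no
passing pair are singletons. Passing pairs are clustered by connected
components; only clusters of exactly two sequences (paralog pairs) are
retained — larger components are multi-gene families and are excluded from
downstream Ka/Ks.

For speed an optional k-mer prefilter only aligns pairs sharing at least
one exact 8-mer peptide; at the 0.75 identity threshold and desk-scale
protein lengths this loses nothing (verified against exhaustive
all-vs-all in the test suite), and it can be disabled.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .orf_finder import NoOrfError, Orf, find_orfs, longest_orf
from .seqs import CodingSequence

__all__ = [
    "StringencyPolicy",
    "PairAlignment",
    "Cluster",
    "POLICIES",
    "align_proteins",
    "all_alignments",
    "detect_pairs",
    "build_clusters",
    "longest_orfs",
]


@dataclass(frozen=True)
class StringencyPolicy:
    name: str
    min_identity: float
    min_cov_small: float
    min_cov_large: float

    def __post_init__(self) -> None:
        if not 0 < self.min_cov_large <= self.min_cov_small <= 1:
            raise ValueError("need 0 < min_cov_large <= min_cov_small <= 1")

    def passes(self, aln: "PairAlignment") -> bool:
        return (
            aln.identity > self.min_identity
            and aln.cov_small >= self.min_cov_small
            and aln.cov_large >= self.min_cov_large
        )


POLICIES: dict[str, StringencyPolicy] = {
    "low": StringencyPolicy("low", 0.75, 0.75, 0.50),
    "medium": StringencyPolicy("medium", 0.75, 0.85, 0.70),
    "high": StringencyPolicy("high", 0.75, 0.95, 0.80),
}


@dataclass(frozen=True)
class PairAlignment:
    id_a: str
    id_b: str
    identity: float  # identical residues / aligned non-gap columns
    cov_small: float  # aligned span / length, shorter member
    cov_large: float
    aln_length: int  # alignment columns including internal gaps

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster has at least two members")

    @property
    def is_pair(self) -> bool:
        return len(self.members) == 2


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _local_aligner()


def align_proteins(a: Orf, b: Orf) -> PairAlignment:
    """Local alignment statistics for two longest-ORF proteins.

    Symmetric up to label swap: identity/coverages do not depend on the
    argument order.
    """
    pa, pb = a.protein, b.protein
    if not pa or not pb:
        raise ValueError("proteins must be non-empty")
    aln = _ALIGNER.align(pa, pb)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_cols = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        aligned_cols += ea - sa
        matches += sum(pa[i] == pb[j] for i, j in zip(range(sa, ea), range(sb, eb)))
    if aligned_cols == 0:
        return PairAlignment(a.parent_id, b.parent_id, 0.0, 0.0, 0.0, 0)
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    cols = aligned_cols
    for k in range(1, len(blocks_a)):
        cols += (blocks_a[k][0] - blocks_a[k - 1][1]) + (blocks_b[k][0] - blocks_b[k - 1][1])
    cov_a = span_a / len(pa)
    cov_b = span_b / len(pb)
    if len(pa) <= len(pb):
        cov_small, cov_large = cov_a, cov_b
    else:
        cov_small, cov_large = cov_b, cov_a
    identity = matches / aligned_cols
    return PairAlignment(a.parent_id, b.parent_id, identity, cov_small, cov_large, cols)


def longest_orfs(
    seqs: Sequence[CodingSequence], min_codons: int = 30
) -> tuple[dict[str, Orf], list[str]]:
    """Longest ORF per sequence; sequences without one are dropped and
    their ids returned for logging."""
    orfs: dict[str, Orf] = {}
    dropped: list[str] = []
    for s in seqs:
        try:
            orfs[s.id] = longest_orf(find_orfs(s, min_codons))
        except (NoOrfError, ValueError):
            dropped.append(s.id)
    return orfs, dropped


def _kmer_candidates(orfs: dict[str, Orf], k: int) -> set[tuple[str, str]]:
    index: dict[str, list[str]] = defaultdict(list)
    for sid in sorted(orfs):
        prot = orfs[sid].protein
        for seen in {prot[i : i + k] for i in range(len(prot) - k + 1)}:
            index[seen].append(sid)
    cands: set[tuple[str, str]] = set()
    for ids in index.values():
        if len(ids) > 1:
            cands.update(combinations(ids, 2))
    return cands


def all_alignments(
    seqs: Sequence[CodingSequence],
    min_codons: int = 30,
    prefilter: bool = True,
    prefilter_k: int = 8,
) -> list[PairAlignment]:
    """Pairwise alignments for every candidate pair (all-against-all, or
    k-mer-prefiltered), in a canonical id order independent of input
    order."""
    orfs, _ = longest_orfs(seqs, min_codons)
    if prefilter:
        candidates = sorted(_kmer_candidates(orfs, prefilter_k))
    else:
        candidates = list(combinations(sorted(orfs), 2))
    return [align_proteins(orfs[x], orfs[y]) for x, y in candidates]


def detect_pairs(
    seqs: Sequence[CodingSequence],
    policy: StringencyPolicy | str,
    min_codons: int = 30,
    prefilter: bool = True,
    alignments: Iterable[PairAlignment] | None = None,
) -> list[PairAlignment]:
    """Every unordered pair passing the stringency policy.

    Precomputed ``alignments`` may be supplied so several stringency levels
    share one all-vs-all pass.
    """
    if isinstance(policy, str):
        policy = POLICIES[policy]
    if alignments is None:
        alignments = all_alignments(seqs, min_codons, prefilter)
    return [a for a in alignments if policy.passes(a)]


def build_clusters(
    pairs: Iterable[PairAlignment],
) -> tuple[list[Cluster], list[Cluster]]:
    """Connected components of the passing-pair graph.

    Returns (retained, excluded): components of exactly two sequences are
    paralog pairs; larger components are multi-gene families, reported but
    excluded from downstream analysis.
    """
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(*p.key)
    retained: list[Cluster] = []
    excluded: list[Cluster] = []
    for comp in nx.connected_components(graph):
        cluster = Cluster(frozenset(comp))
        (retained if cluster.is_pair else excluded).append(cluster)
    retained.sort(key=lambda c: sorted(c.members))
    excluded.sort(key=lambda c: sorted(c.members))
    return retained, excluded


def pairs_table(
    alignments: Iterable[PairAlignment],
) -> pd.DataFrame:
    rows = []
    for a in alignments:
        row = {
            "id_a": a.id_a,
            "id_b": a.id_b,
            "identity": a.identity,
            "cov_small": a.cov_small,
            "cov_large": a.cov_large,
            "aln_length": a.aln_length,
        }
        for name, pol in POLICIES.items():
            row[f"passes_{name}"] = pol.passes(a)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "identity", "cov_small", "cov_large", "aln_length",
                 "passes_low", "passes_medium", "passes_high"],
    )
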