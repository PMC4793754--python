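"""Classification of paralog pairs against a genome annotation.

Transcript-derived paralog pairs are cross-referenced with gene models
(GMs) on an assembly: each transcript is matched to the spliced sequence
of every gene model (exon concatenation per GFF3) by local nucleotide
alignment, keeping hits with more than 75 % identity and more than 75 %
coverage (on both the transcript and the gene model by default). The
matched loci of the two members then decide the scenario:

* A — exactly two distinct loci on one supercontig: tandem duplication;
* B — exactly two distinct loci on different supercontigs: dispersed or
  segmental duplication;
* C — more than two distinct loci: annotation in excess of transcripts;
* D — a single distinct locus: a collapsed gene model covering both copies;
* E — either member matches no gene model: unannotated duplicate.

Two matches count as the same locus when their genomic intervals overlap
by at least one base on the same seqid and strand (robust to small
alignment-extent differences). Strand is recorded in the output for manual
inspection. Matching is against spliced gene-model sequences, not raw
genomic windows, so no spliced aligner is needed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq

from .seqs import CodingSequence

__all__ = [
    "GeneModelLocus",
    "GenomeMatch",
    "ScenarioAssignment",
    "load_gene_models",
    "match_tc_to_gm",
    "classify_scenario",
    "summarize_scenarios",
    "MATCH_MIN_IDENTITY",
    "MATCH_MIN_COVERAGE",
]

MATCH_MIN_IDENTITY = 0.75
MATCH_MIN_COVERAGE = 0.75


@dataclass(frozen=True)
class GeneModelLocus:
    gm_id: str
    seqid: str
    start: int  # 0-based half-open
    end: int
    strand: str
    spliced_seq: str


@dataclass(frozen=True)
class GenomeMatch:
    tc_id: str
    gm_id: str
    identity: float
    coverage: float  # fraction of the transcript aligned
    gm_coverage: float
    seqid: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class ScenarioAssignment:
    tc_pair_id: str
    scenario: str  # A..E
    distinct_gm_loci: int
    same_supercontig: bool | None  # None when not applicable


def load_gene_models(genome_fasta: str | Path, gff3: str | Path) -> list[GeneModelLocus]:
    """Gene loci and spliced (exon-concatenated) sequences from GFF3.

    Coordinates are converted from 1-based inclusive GFF3 to 0-based
    half-open. A gene without exon children contributes its full span.
    """
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }
    db = gffutils.create_db(
        str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    loci: list[GeneModelLocus] = []
    for gene in db.features_of_type("gene"):
        exons = sorted(db.children(gene, featuretype="exon"), key=lambda e: e.start)
        contig = contigs[gene.seqid]
        if exons:
            spliced = "".join(contig[e.start - 1 : e.end] for e in exons)
        else:
            spliced = contig[gene.start - 1 : gene.end]
        if gene.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        loci.append(
            GeneModelLocus(gene.id, gene.seqid, gene.start - 1, gene.end,
                           gene.strand, spliced)
        )
    return loci


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _nt_aligner()


def _shares_kmer(a: str, b: str, k: int = 12) -> bool:
    kmers = {a[i : i + k] for i in range(0, len(a) - k + 1, k)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def match_tc_to_gm(
    tc: CodingSequence,
    gms: Sequence[GeneModelLocus],
    min_identity: float = MATCH_MIN_IDENTITY,
    min_coverage: float = MATCH_MIN_COVERAGE,
    require_gm_coverage: bool = True,
) -> list[GenomeMatch]:
    """Gene models matching a transcript above the identity/coverage rule.

    Both orientations of the transcript are tried; the best match per gene
    model is retained. ``require_gm_coverage`` applies the coverage
    threshold to the gene-model side as well as the transcript side.
    """
    matches: list[GenomeMatch] = []
    tc_fwd = tc.seq.upper()
    tc_rev = str(Seq(tc_fwd).reverse_complement())
    for gm in gms:
        best: GenomeMatch | None = None
        for query in (tc_fwd, tc_rev):
            if not _shares_kmer(query, gm.spliced_seq):
                continue
            aln = _ALIGNER.align(query, gm.spliced_seq)[0]
            blocks_q, blocks_t = aln.aligned
            if len(blocks_q) == 0:
                continue
            matches_n = 0
            cols = 0
            for (sq, eq), (st, et) in zip(blocks_q, blocks_t):
                cols += eq - sq
                matches_n += sum(
                    query[i] == gm.spliced_seq[j]
                    for i, j in zip(range(sq, eq), range(st, et))
                )
            if cols == 0:
                continue
            identity = matches_n / cols
            cov_tc = (blocks_q[-1][1] - blocks_q[0][0]) / len(query)
            cov_gm = (blocks_t[-1][1] - blocks_t[0][0]) / len(gm.spliced_seq)
            if identity <= min_identity or cov_tc <= min_coverage:
                continue
            if require_gm_coverage and cov_gm <= min_coverage:
                continue
            cand = GenomeMatch(tc.id, gm.gm_id, identity, cov_tc, cov_gm,
                               gm.seqid, gm.start, gm.end, gm.strand)
            if best is None or cand.identity > best.identity:
                best = cand
        if best is not None:
            matches.append(best)
    return matches


def _distinct_loci(matches: Iterable[GenomeMatch]) -> list[tuple[str, str, int, int]]:
    """Merge overlapping same-seqid, same-strand match intervals."""
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for m in matches:
        by_key.setdefault((m.seqid, m.strand), []).append((m.start, m.end))
    loci: list[tuple[str, str, int, int]] = []
    for (seqid, strand), ivals in by_key.items():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s < cur_e:  # >= 1 bp overlap
                cur_e = max(cur_e, e)
            else:
                loci.append((seqid, strand, cur_s, cur_e))
                cur_s, cur_e = s, e
        loci.append((seqid, strand, cur_s, cur_e))
    return loci


def classify_scenario(
    tc_pair_id: str,
    matches_a: Sequence[GenomeMatch],
    matches_b: Sequence[GenomeMatch],
) -> ScenarioAssignment:
    """Scenario from the distinct loci matched by the two members.

    E: a member with zero matches; D: one distinct locus; A: two loci on
    one seqid; B: two loci on different seqids; C: more than two loci.
    """
    if not matches_a or not matches_b:
        return ScenarioAssignment(tc_pair_id, "E", 0, None)
    loci = _distinct_loci(list(matches_a) + list(matches_b))
    n = len(loci)
    if n == 1:
        return ScenarioAssignment(tc_pair_id, "D", 1, True)
    if n == 2:
        same = loci[0][0] == loci[1][0]
        return ScenarioAssignment(tc_pair_id, "A" if same else "B", 2, same)
    seqids = {l[0] for l in loci}
    return ScenarioAssignment(tc_pair_id, "C", n, len(seqids) == 1)


def summarize_scenarios(
    assignments: Iterable[ScenarioAssignment],
) -> pd.DataFrame:
    """Counts per scenario plus the fraction of pairs matching >= 1 gene
    model (everything but scenario E)."""
    assignments = list(assignments)
    counts = Counter(a.scenario for a in assignments)
    total = len(assignments)
    rows = [
        {"scenario": s, "count": counts.get(s, 0),
         "fraction": counts.get(s, 0) / total if total else 0.0}
        for s in "ABCDE"
    ]
    df = pd.DataFrame(rows, columns=["scenario", "count", "fraction"])
    df.attrs["fraction_matching_gms"] = (
        (total - counts.get("E", 0)) / total if total else 0.0
    )
    return df
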