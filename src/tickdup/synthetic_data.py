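"""Synthetic coding-sequence, paralog-family and toy-genome simulator.

Every downstream stage of the pipeline (ORF finding, paralog detection,
Ka/Ks, Ks-mixture dating, genome scenario classification) is exercised on
data from this module, which plants known ground truth:

* singleton genes (independent random ancestors, uniform over the 61 sense
  codons — no codon-usage bias is modelled);
* paralog pairs grouped into duplication "events": each event is a cluster
  of pairs whose target Ks is drawn lognormally around the event mean, so
  the resulting ln(Ks) distribution is a mixture of approximately normal
  components, one per event;
* a per-pair selection regime omega (= Ka/Ks): a configurable fraction of
  pairs evolves under positive selection (omega > 1), the rest under
  purifying selection (omega < 1);
* multi-copy families (clusters of more than two members, which the
  paralog-detection stage must exclude);
* a toy annotated genome with planted tandem (A), dispersed (B), extra
  annotation (C), collapsed annotation (D) and unannotated (E) cases.

The substitution process is sequential single-nucleotide proposals with an
omega-dependent acceptance rule rather than a rate-matrix CTMC: a proposal
creating a stop codon is rejected outright, a nonsynonymous proposal is
accepted with probability min(1, omega) and a synonymous proposal with
probability min(1, 1/omega). Evolution stops when the pathway-counted
synonymous divergence (true events at synonymous sites / synonymous sites,
summed over the two copies) first reaches the target Ks. The realized (not
the target) Ks and Ka are recorded as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import GENETIC_CODE, NUCLEOTIDES, SENSE_CODONS, SYN_SITES, is_stop
from .seqs import CodingSequence, write_fasta

__all__ = [
    "EventSpec",
    "SimulationConfig",
    "GenomeConfig",
    "PairTruth",
    "SyntheticTruth",
    "SaturationError",
    "simulate_ancestral_cds",
    "evolve_pair",
    "simulate_transcriptome",
    "simulate_genome",
    "GenomeSim",
]

SCENARIOS = ("A", "B", "C", "D", "E")


class SaturationError(RuntimeError):
    """Raised when the requested divergence cannot be reached within the
    proposal budget (the sequence is effectively saturated)."""


@dataclass(frozen=True)
class EventSpec:
    """One duplication event: a burst of pairs sharing similar Ks."""

    n_pairs: int
    ks_mean: float  # substitutions per synonymous site
    ks_sd_ln: float = 0.2  # dispersion of ln(Ks) around ln(ks_mean)

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.ks_mean <= 0:
            raise ValueError("ks_mean must be > 0")
        if self.ks_sd_ln < 0:
            raise ValueError("ks_sd_ln must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults plant a ~1,000-gene transcriptome with two duplication events
    (Ks 0.1 and 0.45, 75 pairs each), 20 % of pairs under positive
    selection (omega 3 vs 0.1), and five three-member families.
    """

    n_singletons: int = 665
    events: tuple[EventSpec, ...] = (
        EventSpec(n_pairs=75, ks_mean=0.1),
        EventSpec(n_pairs=75, ks_mean=0.45),
    )
    n_multigene_families: int = 5
    family_size: int = 3
    cds_length_codons: int = 300
    omega_positive_fraction: float = 0.2
    omega_negative: float = 0.1
    omega_positive: float = 3.0
    family_ks: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_singletons, self.n_multigene_families) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_multigene_families > 0 and self.family_size < 3:
            raise ValueError("family_size must be >= 3")
        if self.cds_length_codons < 30:
            raise ValueError("cds_length_codons must be >= 30")
        if not 0.0 <= self.omega_positive_fraction <= 1.0:
            raise ValueError("omega_positive_fraction must be in [0, 1]")
        if not self.omega_negative < 1.0 < self.omega_positive:
            raise ValueError("need omega_negative < 1 < omega_positive")
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class PairTruth:
    pair_id: str
    member_a: str
    member_b: str
    event_index: int  # -1 for family-derived records
    target_ks: float
    true_ks: float
    true_ka: float
    omega: float


@dataclass
class SyntheticTruth:
    """Ground truth for every planted pair, family and genome scenario."""

    pairs: dict[str, PairTruth] = field(default_factory=dict)
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)
    scenarios: dict[str, str] = field(default_factory=dict)  # tc_pair_id -> A..E

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair_id": t.pair_id,
                "member_a": t.member_a,
                "member_b": t.member_b,
                "event_index": t.event_index,
                "target_ks": t.target_ks,
                "true_ks": t.true_ks,
                "true_ka": t.true_ka,
                "omega": t.omega,
            }
            for t in self.pairs.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["pair_id", "member_a", "member_b", "event_index",
                     "target_ks", "true_ks", "true_ka", "omega"],
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pairs_frame().to_csv(outdir / "pair_truth.tsv", sep="\t", index=False)
        fam = pd.DataFrame(
            [{"family_id": f, "members": ",".join(m)} for f, m in self.families.items()],
            columns=["family_id", "members"],
        )
        fam.to_csv(outdir / "family_truth.tsv", sep="\t", index=False)
        if self.scenarios:
            sc = pd.DataFrame(
                sorted(self.scenarios.items()), columns=["tc_pair_id", "scenario"]
            )
            sc.to_csv(outdir / "scenario_truth.tsv", sep="\t", index=False)


def simulate_ancestral_cds(length_codons: int, seed: int) -> CodingSequence:
    """Random ancestral CDS: ATG + ``length_codons`` uniform sense codons +
    one stop codon. Deterministic in ``seed``; no internal stops by
    construction."""
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    rng = np.random.default_rng(seed)
    body = "".join(rng.choice(SENSE_CODONS, size=length_codons))
    stop = rng.choice(("TAA", "TAG", "TGA"))
    return CodingSequence(f"anc{seed}", "ATG" + body + stop, source="ancestor")


def _codon_list(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


class _EvolvingCopy:
    """One descendant copy under the proposal/acceptance process."""

    __slots__ = ("codons", "syn_sites", "syn_events", "nonsyn_events")

    def __init__(self, codons: list[str]):
        self.codons = list(codons)
        self.syn_sites = sum(SYN_SITES[c] for c in self.codons)
        self.syn_events = 0
        self.nonsyn_events = 0

    @property
    def ks(self) -> float:
        return self.syn_events / self.syn_sites

    @property
    def ka(self) -> float:
        nonsyn_sites = 3 * len(self.codons) - self.syn_sites
        return self.nonsyn_events / nonsyn_sites

    def propose(self, rng: np.random.Generator, omega: float) -> None:
        pos = int(rng.integers(3 * len(self.codons)))
        ci, off = divmod(pos, 3)
        codon = self.codons[ci]
        old_nt = codon[off]
        new_nt = NUCLEOTIDES[int(rng.integers(4))]
        if new_nt == old_nt:
            return
        new_codon = codon[:off] + new_nt + codon[off + 1 :]
        if is_stop(new_codon):
            return  # coding constraint: stop-creating proposals rejected
        synonymous = GENETIC_CODE[new_codon] == GENETIC_CODE[codon]
        p_accept = min(1.0, 1.0 / omega) if synonymous else min(1.0, omega)
        if p_accept < 1.0 and rng.random() >= p_accept:
            return
        self.codons[ci] = new_codon
        self.syn_sites += SYN_SITES[new_codon] - SYN_SITES[codon]
        if synonymous:
            self.syn_events += 1
        else:
            self.nonsyn_events += 1


def _evolve_copies(
    coding_codons: list[str],
    n_copies: int,
    per_copy_ks: list[float],
    omega: float,
    rng: np.random.Generator,
    max_proposals: int | None = None,
) -> list[_EvolvingCopy]:
    copies = [_EvolvingCopy(coding_codons) for _ in range(n_copies)]
    if max_proposals is None:
        max_proposals = int(2000 * 3 * len(coding_codons) * (max(per_copy_ks) + 1.0))
    n_prop = 0
    for copy, target in zip(copies, per_copy_ks):
        while copy.ks < target:
            if n_prop >= max_proposals:
                raise SaturationError(
                    f"divergence target not reached within {max_proposals} proposals"
                )
            copy.propose(rng, omega)
            n_prop += 1
    return copies


def evolve_pair(
    ancestor: CodingSequence,
    target_ks: float,
    omega: float,
    seed: int,
    max_proposals: int | None = None,
) -> tuple[CodingSequence, CodingSequence, PairTruth]:
    """Evolve two descendant copies of ``ancestor`` until their summed
    synonymous divergence first reaches ``target_ks``.

    Proposals alternate between the two copies; the realized (pathway
    counted) Ks and Ka are returned as truth. The terminal stop codon is
    held fixed. Raises :class:`SaturationError` if the proposal budget is
    exhausted before the target is reached.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    coding = _codon_list(ancestor.seq)
    if is_stop(coding[-1]):
        stop = coding[-1]
        coding = coding[:-1]
    else:
        stop = ""
    rng = np.random.default_rng(seed)
    a = _EvolvingCopy(coding)
    b = _EvolvingCopy(coding)
    if max_proposals is None:
        max_proposals = int(2000 * 3 * len(coding) * (target_ks + 1.0))
    n_prop = 0
    turn = 0
    while a.ks + b.ks < target_ks:
        if n_prop >= max_proposals:
            raise SaturationError(
                f"target_ks={target_ks} not reached within {max_proposals} proposals"
            )
        (a if turn == 0 else b).propose(rng, omega)
        turn ^= 1
        n_prop += 1
    true_ks = a.ks + b.ks
    true_ka = a.ka + b.ka
    seq_a = CodingSequence(ancestor.id + "_a", "".join(a.codons) + stop, "pair")
    seq_b = CodingSequence(ancestor.id + "_b", "".join(b.codons) + stop, "pair")
    truth = PairTruth(ancestor.id, seq_a.id, seq_b.id, -1, target_ks,
                      true_ks, true_ka, omega)
    return seq_a, seq_b, truth


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[CodingSequence], SyntheticTruth]:
    """Emit singletons, event-structured paralog pairs and multi-member
    families per ``config``; every pair/family has exactly one truth record."""
    rng = np.random.default_rng(config.seed)
    seqs: list[CodingSequence] = []
    truth = SyntheticTruth()
    L = config.cds_length_codons

    for i in range(config.n_singletons):
        anc = simulate_ancestral_cds(L, int(rng.integers(2**31)))
        seqs.append(CodingSequence(f"SG{i:05d}", anc.seq, "singleton"))

    for ev_idx, event in enumerate(config.events):
        for p in range(event.n_pairs):
            target = float(rng.lognormal(np.log(event.ks_mean), event.ks_sd_ln))
            omega = (
                config.omega_positive
                if rng.random() < config.omega_positive_fraction
                else config.omega_negative
            )
            anc = simulate_ancestral_cds(L, int(rng.integers(2**31)))
            pair_id = f"EV{ev_idx}P{p:04d}"
            a, b, t = evolve_pair(anc, target, omega, int(rng.integers(2**31)))
            a = CodingSequence(f"{pair_id}A", a.seq, "pair")
            b = CodingSequence(f"{pair_id}B", b.seq, "pair")
            seqs.extend([a, b])
            truth.pairs[pair_id] = PairTruth(
                pair_id, a.id, b.id, ev_idx, target, t.true_ks, t.true_ka, omega
            )

    for f in range(config.n_multigene_families):
        anc = simulate_ancestral_cds(L, int(rng.integers(2**31)))
        coding = _codon_list(anc.seq)
        stop = coding[-1] if is_stop(coding[-1]) else ""
        coding = coding[:-1] if stop else coding
        per_copy = [config.family_ks / 2.0] * config.family_size
        copies = _evolve_copies(coding, config.family_size, per_copy,
                                config.omega_negative,
                                np.random.default_rng(int(rng.integers(2**31))))
        members = []
        for m, copy in enumerate(copies):
            sid = f"FAM{f:02d}M{m}"
            seqs.append(CodingSequence(sid, "".join(copy.codons) + stop, "family"))
            members.append(sid)
        truth.families[f"FAM{f:02d}"] = tuple(members)

    return seqs, truth


# ---------------------------------------------------------------------------
# toy genome with planted annotation scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    """Planted annotation cases per scenario.

    A: two annotated copies adjacent on one supercontig (tandem);
    B: annotated copies on different supercontigs (dispersed/segmental);
    C: more gene-model records than transcript copies (extra annotation);
    D: two physical copies but one collapsed gene-model record;
    E: transcript pair with no gene-model record at all.
    """

    n_per_scenario: dict[str, int] = field(
        default_factory=lambda: {s: 1 for s in SCENARIOS}
    )
    gene_length_codons: int = 200
    divergence_ks: float = 0.05
    intron_length_range: tuple[int, int] = (100, 500)
    intergenic_length: int = 300
    n_exons: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for s, n in self.n_per_scenario.items():
            if s not in SCENARIOS or n < 0:
                raise ValueError(f"bad scenario count {s}={n}")


@dataclass
class GenomeSim:
    """A simulated assembly: supercontigs, gene-model GFF3, transcripts."""

    contigs: list[tuple[str, str]]  # (seqid, sequence)
    gff_lines: list[str]
    transcripts: list[CodingSequence]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [CodingSequence(sid, seq) for sid, seq in self.contigs],
            outdir / "genome.fa",
        )
        (outdir / "genes.gff3").write_text("\n".join(self.gff_lines) + "\n")
        write_fasta(self.transcripts, outdir / "tcs.fa")
        self.truth.write(outdir)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(4, size=n)])


def _gene_structure(
    cds: str, rng: np.random.Generator, cfg: GenomeConfig
) -> tuple[str, list[tuple[int, int]]]:
    """Split a CDS into exons separated by random introns.

    Returns (genomic sequence, exon intervals 0-based half-open on it).
    Intron termini (GT..AG) are not enforced; nothing downstream inspects
    splice sites.
    """
    n_exons = min(cfg.n_exons, max(1, len(cds) // 60))
    cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    pieces = []
    prev = 0
    for c in list(cuts) + [len(cds)]:
        pieces.append(cds[prev:int(c)])
        prev = int(c)
    lo, hi = cfg.intron_length_range
    seq_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for i, piece in enumerate(pieces):
        if i > 0:
            intron = _random_nt(rng, int(rng.integers(lo, hi + 1)))
            seq_parts.append(intron)
            pos += len(intron)
        exons.append((pos, pos + len(piece)))
        seq_parts.append(piece)
        pos += len(piece)
    return "".join(seq_parts), exons


def _gff_gene(seqid: str, gene_id: str, offset: int, gene_seq: str,
              exons: list[tuple[int, int]]) -> list[str]:
    lines = [
        "\t".join([seqid, "tickdup_sim", "gene", str(offset + 1),
                   str(offset + len(gene_seq)), ".", "+", ".", f"ID={gene_id}"])
    ]
    for i, (s, e) in enumerate(exons):
        lines.append(
            "\t".join([seqid, "tickdup_sim", "exon", str(offset + s + 1),
                       str(offset + e), ".", "+", ".",
                       f"ID={gene_id}.e{i};Parent={gene_id}"])
        )
    return lines


def simulate_genome(config: GenomeConfig) -> GenomeSim:
    """Build supercontigs with planted scenario A–E cases (genes with
    introns and intergenic spacers), their GFF3 gene models, and the
    transcript (spliced) sequences."""
    rng = np.random.default_rng(config.seed)
    contigs: list[tuple[str, str]] = []
    gff = ["##gff-version 3"]
    tcs: list[CodingSequence] = []
    truth = SyntheticTruth()
    contig_no = 0

    def new_contig_id() -> str:
        nonlocal contig_no
        contig_no += 1
        return f"supercontig{contig_no:03d}"

    for scenario in SCENARIOS:
        for case in range(config.n_per_scenario.get(scenario, 0)):
            case_id = f"{scenario}{case:02d}"
            anc = simulate_ancestral_cds(config.gene_length_codons,
                                         int(rng.integers(2**31)))
            c1, c2, _ = evolve_pair(anc, config.divergence_ks, 0.1,
                                    int(rng.integers(2**31)))
            copies = [c1.seq, c2.seq]
            if scenario == "C":
                # one extra annotated locus beyond the two transcripts
                coding = _codon_list(anc.seq)
                stop = coding[-1]
                extra = _evolve_copies(coding[:-1], 1, [config.divergence_ks / 2],
                                       0.1,
                                       np.random.default_rng(int(rng.integers(2**31))))[0]
                copies.append("".join(extra.codons) + stop)

            tc_a = CodingSequence(f"TC_{case_id}_1", copies[0], "tc")
            tc_b = CodingSequence(f"TC_{case_id}_2", copies[1], "tc")
            tcs.extend([tc_a, tc_b])
            pair_id = f"TCPAIR_{case_id}"
            truth.scenarios[pair_id] = scenario
            truth.pairs[pair_id] = PairTruth(pair_id, tc_a.id, tc_b.id, -1,
                                             config.divergence_ks,
                                             config.divergence_ks, 0.0, 0.1)

            spacer = lambda: _random_nt(rng, config.intergenic_length)
            if scenario == "E":
                contigs.append((new_contig_id(), spacer()))
                continue

            genes = []
            for gi, cds in enumerate(copies):
                gseq, exons = _gene_structure(cds, rng, config)
                genes.append((f"GM_{case_id}_{gi + 1}", gseq, exons))

            if scenario == "B":
                for gene_id, gseq, exons in genes:
                    sid = new_contig_id()
                    left = spacer()
                    contigs.append((sid, left + gseq + spacer()))
                    gff.extend(_gff_gene(sid, gene_id, len(left), gseq, exons))
            else:
                sid = new_contig_id()
                parts = [spacer()]
                offset = len(parts[0])
                annotate = genes if scenario != "D" else genes[:1]
                annotated_ids = {g[0] for g in annotate}
                for gene_id, gseq, exons in genes:
                    if gene_id in annotated_ids:
                        gff.extend(_gff_gene(sid, gene_id, offset, gseq, exons))
                    parts.append(gseq)
                    sp = spacer()
                    parts.append(sp)
                    offset += len(gseq) + len(sp)
                contigs.append((sid, "".join(parts)))

    return GenomeSim(contigs, gff, tcs, truth)
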