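"""Simulator ground truth: determinism, coding constraints, divergence
targeting, bookkeeping, and the planted genome scenarios."""

import io

import numpy as np
import pytest

import oracles
from tickdup.kaks import build_codon_alignment, compute_kaks
from tickdup.synthetic_data import (
    EventSpec,
    GenomeConfig,
    SaturationError,
    SimulationConfig,
    evolve_pair,
    simulate_ancestral_cds,
    simulate_genome,
    simulate_transcriptome,
)


def _no_internal_stops_frame0(seq: str) -> bool:
    coding = seq[:-3]  # trailing stop codon
    return "*" not in oracles.translate(coding)


class TestAncestralCds:
    def test_minimal_length(self):
        cds = simulate_ancestral_cds(1, seed=5)
        assert len(cds.seq) == 9
        assert cds.seq.startswith("ATG")
        assert oracles.CODE[cds.seq[-3:]] == "*"

    def test_seed_determinism(self):
        assert simulate_ancestral_cds(100, 7).seq == simulate_ancestral_cds(100, 7).seq
        assert simulate_ancestral_cds(100, 7).seq != simulate_ancestral_cds(100, 8).seq

    def test_no_internal_stops(self):
        cds = simulate_ancestral_cds(100, 7)
        assert _no_internal_stops_frame0(cds.seq)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            simulate_ancestral_cds(0, 1)


class TestEvolvePair:
    def test_zero_divergence_returns_identical_copies(self):
        anc = simulate_ancestral_cds(50, 3)
        a, b, truth = evolve_pair(anc, 0.0, 0.5, seed=4)
        assert a.seq == anc.seq == b.seq
        assert truth.true_ks == 0.0

    def test_seed_determinism(self):
        anc = simulate_ancestral_cds(100, 3)
        r1 = evolve_pair(anc, 0.2, 0.1, seed=9)
        r2 = evolve_pair(anc, 0.2, 0.1, seed=9)
        assert r1[0].seq == r2[0].seq and r1[1].seq == r2[1].seq

    def test_copies_remain_coding(self):
        anc = simulate_ancestral_cds(100, 3)
        a, b, _ = evolve_pair(anc, 0.4, 0.1, seed=10)
        assert _no_internal_stops_frame0(a.seq)
        assert _no_internal_stops_frame0(b.seq)

    def test_truth_reaches_target(self):
        anc = simulate_ancestral_cds(200, 3)
        _, _, truth = evolve_pair(anc, 0.25, 0.1, seed=11)
        assert truth.true_ks >= 0.25
        assert truth.true_ks == pytest.approx(0.25, rel=0.1)

    def test_saturation_error_on_tiny_budget(self):
        anc = simulate_ancestral_cds(50, 3)
        with pytest.raises(SaturationError):
            evolve_pair(anc, 5.0, 0.1, seed=1, max_proposals=10)

    def test_invalid_arguments(self):
        anc = simulate_ancestral_cds(50, 3)
        with pytest.raises(ValueError):
            evolve_pair(anc, -0.1, 0.5, 1)
        with pytest.raises(ValueError):
            evolve_pair(anc, 0.1, 0.0, 1)

    def test_ng86_concordance_at_large_length(self):
        """Pathway-counted divergence and the downstream NG86 estimate agree
        within 10 % on average at L = 3000 codons."""
        errs = []
        for rep in range(20):
            anc = simulate_ancestral_cds(3000, 100 + rep)
            a, b, _ = evolve_pair(anc, 0.3, 0.1, 200 + rep)
            r = compute_kaks(build_codon_alignment("p", a.seq[:-3], b.seq[:-3]))
            errs.append(abs(r.Ks - 0.3) / 0.3)
        assert np.mean(errs) <= 0.10


class TestSimulateTranscriptome:
    def test_singletons_only(self):
        cfg = SimulationConfig(n_singletons=10, events=(),
                               n_multigene_families=0, seed=1)
        seqs, truth = simulate_transcriptome(cfg)
        assert len(seqs) == 10
        assert truth.pairs == {} and truth.families == {}

    def test_pair_bookkeeping(self):
        cfg = SimulationConfig(n_singletons=0, events=(EventSpec(50, 0.2, 0.1),),
                               n_multigene_families=0, cds_length_codons=60, seed=2)
        seqs, truth = simulate_transcriptome(cfg)
        assert len(seqs) == 100
        assert len(truth.pairs) == 50
        members = [m for t in truth.pairs.values() for m in (t.member_a, t.member_b)]
        assert sorted(members) == sorted(s.id for s in seqs)

    def test_truth_partitions_members(self, small_transcriptome):
        seqs, truth = small_transcriptome
        seen: dict[str, int] = {}
        for t in truth.pairs.values():
            for m in (t.member_a, t.member_b):
                seen[m] = seen.get(m, 0) + 1
        for members in truth.families.values():
            for m in members:
                seen[m] = seen.get(m, 0) + 1
        assert all(v == 1 for v in seen.values())
        ids = {s.id for s in seqs}
        assert set(seen) <= ids

    def test_no_internal_stops_in_emitted_sequences(self, small_transcriptome):
        seqs, _ = small_transcriptome
        for s in seqs:
            assert _no_internal_stops_frame0(s.seq)

    def test_two_events_make_bimodal_lnks(self):
        cfg = SimulationConfig(
            n_singletons=0,
            events=(EventSpec(60, 0.1, 0.1), EventSpec(60, 0.45, 0.1)),
            n_multigene_families=0, cds_length_codons=60, seed=3)
        _, truth = simulate_transcriptome(cfg)
        lnks = np.log([t.true_ks for t in truth.pairs.values()])
        counts, _ = np.histogram(lnks, bins=3,
                                 range=(np.log(0.1), np.log(0.45)))
        assert counts[1] < counts[0] and counts[1] < counts[2]

    def test_fasta_output_is_deterministic(self):
        cfg = SimulationConfig(n_singletons=5, events=(EventSpec(3, 0.1),),
                               n_multigene_families=1, cds_length_codons=40,
                               seed=12)
        outs = []
        for _ in range(2):
            seqs, _ = simulate_transcriptome(cfg)
            buf = io.StringIO()
            from Bio import SeqIO
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord
            SeqIO.write([SeqRecord(Seq(s.seq), id=s.id, description="")
                         for s in seqs], buf, "fasta")
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(omega_positive_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(omega_negative=2.0)
        with pytest.raises(ValueError):
            SimulationConfig(cds_length_codons=10)
        with pytest.raises(ValueError):
            EventSpec(5, -0.1)


class TestSimulateGenome:
    def test_tandem_case_structure(self):
        sim = simulate_genome(GenomeConfig(
            n_per_scenario={"A": 1, "B": 0, "C": 0, "D": 0, "E": 0}, seed=4))
        genes = [l for l in sim.gff_lines if "\tgene\t" in l]
        assert len(genes) == 2
        assert len({l.split("\t")[0] for l in genes}) == 1  # one seqid
        assert len(sim.transcripts) == 2

    def test_unannotated_case_has_no_gene_records(self):
        sim = simulate_genome(GenomeConfig(
            n_per_scenario={"A": 0, "B": 0, "C": 0, "D": 0, "E": 1}, seed=5))
        assert not any("\tgene\t" in l for l in sim.gff_lines)
        assert len(sim.transcripts) == 2
        assert len(sim.truth.scenarios) == 1

    def test_collapsed_case_has_single_gene_record(self):
        sim = simulate_genome(GenomeConfig(
            n_per_scenario={"A": 0, "B": 0, "C": 0, "D": 1, "E": 0}, seed=6))
        assert sum("\tgene\t" in l for l in sim.gff_lines) == 1

    def test_determinism(self):
        cfg = GenomeConfig(seed=7)
        s1, s2 = simulate_genome(cfg), simulate_genome(cfg)
        assert s1.contigs == s2.contigs
        assert s1.gff_lines == s2.gff_lines
        assert [t.seq for t in s1.transcripts] == [t.seq for t in s2.transcripts]
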