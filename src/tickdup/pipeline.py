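"""End-to-end orchestration: simulate -> ORFs -> pairs -> Ka/Ks ->
Ks-mixture -> dating -> genome scenarios, with one config and one seed.

Every stage is a pure function of (inputs, config, seed); the single
global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).generate_state`` so each stage is
independently reproducible. All intermediates are persisted as TSV/FASTA
and the consolidated report as JSON + Markdown.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clock_dating, genome_scenarios, kaks, ks_mixture, paralog_detect
from .clock_dating import DROSOPHILA_RATE, RateCalibration
from .kaks import KaKsResult, build_codon_alignment, compute_kaks
from .paralog_detect import POLICIES, all_alignments, build_clusters, detect_pairs
from .seqs import CodingSequence, read_fasta, write_fasta
from .synthetic_data import (
    EventSpec,
    GenomeConfig,
    SimulationConfig,
    simulate_genome,
    simulate_transcriptome,
)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_all",
    "summarize_selection",
    "child_seeds",
]


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    genome: GenomeConfig | None = None
    input_fasta: str | None = None  # analyse an external FASTA instead of simulating
    stringency: str = "low"
    min_codons: int = 30
    prefilter: bool = True
    k_max: int = 6
    n_restarts: int = 20
    bootstrap: bool = False
    rates: tuple[RateCalibration, ...] = (DROSOPHILA_RATE,)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = dict(raw.get("simulation", {}))
        if "events" in sim_raw:
            # events given as mappings {n_pairs, ks_mean, ks_sd_ln}
            sim_raw["events"] = tuple(EventSpec(**e) for e in sim_raw["events"])
        sim = SimulationConfig(**sim_raw)
        genome = None
        if "genome" in raw:
            gen_raw = dict(raw["genome"])
            if "intron_length_range" in gen_raw:
                gen_raw["intron_length_range"] = tuple(gen_raw["intron_length_range"])
            genome = GenomeConfig(**gen_raw)
        rates = tuple(
            RateCalibration(r["species_label"], float(r["rate_per_site_per_year"]),
                            r.get("note", ""))
            for r in raw.get("rates", [])
        ) or (DROSOPHILA_RATE,)
        keys = {"input_fasta", "stringency", "min_codons", "prefilter",
                "k_max", "n_restarts", "bootstrap"}
        return cls(simulation=sim, genome=genome, rates=rates,
                   **{k: raw[k] for k in keys if k in raw})


@dataclass
class RunReport:
    seed: int
    n_sequences: int
    pair_counts_by_stringency: dict[str, int]
    n_retained_pairs: int
    n_excluded_families: int
    selection_percent: dict[str, float]
    n_excluded_pairs: int
    best_k: int
    lrt_p: float | None
    events: list[dict[str, Any]]
    date_histogram_total: int
    scenario_counts: dict[str, int] | None
    software: str = "tickdup 0.1.0"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    def to_markdown(self) -> str:
        lines = [
            "# tickdup run report",
            f"- software: {self.software}, seed: {self.seed}",
            f"- sequences analysed: {self.n_sequences}",
            "- pairs passing stringency: "
            + ", ".join(f"{k}={v}" for k, v in self.pair_counts_by_stringency.items()),
            f"- retained paralog pairs (clusters of 2): {self.n_retained_pairs}",
            f"- excluded multi-gene families (clusters > 2): {self.n_excluded_families}",
            "- selection among classified pairs: "
            + ", ".join(f"{k} {v:.1f}%" for k, v in self.selection_percent.items()),
            f"- pairs excluded from Ka/Ks: {self.n_excluded_pairs}",
            f"- best mixture: k = {self.best_k}"
            + (f" (LRT p = {self.lrt_p:.3g})" if self.lrt_p is not None else ""),
        ]
        for e in self.events:
            age = e.get("age_my")
            lines.append(
                f"  - event {e['event']}: median Ks {e['ks_median']:.4f}, "
                f"{e['n_members']} pairs"
                + (f", {age:.2f} MY ({e['rate_label']})" if age is not None else "")
            )
        if self.scenario_counts is not None:
            lines.append(
                "- genome scenarios: "
                + ", ".join(f"{s}={c}" for s, c in self.scenario_counts.items())
            )
        return "\n".join(lines) + "\n"


def child_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage child seeds below 2**31."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def summarize_selection(results: Sequence[KaKsResult]) -> dict[str, float]:
    """Percent positive/negative/neutral among classified (non-excluded)
    pairs. Raises ValueError when nothing is classified."""
    classified = [r for r in results if not r.excluded]
    if not classified:
        raise ValueError("no classified pairs: every pair was excluded")
    n = len(classified)
    out = {}
    for label in ("positive", "negative", "neutral"):
        out[label] = 100.0 * sum(r.label == label for r in classified) / n
    return out


def _pair_results(
    seqs: Sequence[CodingSequence],
    retained: Sequence[paralog_detect.Cluster],
    min_codons: int,
) -> list[KaKsResult]:
    orfs, _ = paralog_detect.longest_orfs(seqs, min_codons)
    by_id = {s.id: s for s in seqs}
    results = []
    for cluster in retained:
        a, b = sorted(cluster.members)
        nt_a = orfs[a].nucleotides(by_id[a].seq)
        nt_b = orfs[b].nucleotides(by_id[b].seq)
        results.append(compute_kaks(build_codon_alignment(f"{a}|{b}", nt_a, nt_b)))
    return results


def run_all(
    config: PipelineConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> RunReport:
    """Execute every stage in order; deterministic given (config, seed)."""
    s_sim, s_mix, s_gen, _ = child_seeds(seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # stage 1: inputs
    if config.input_fasta is not None:
        seqs = read_fasta(config.input_fasta)
        truth = None
    else:
        sim_cfg = SimulationConfig(**{**asdict(config.simulation),
                                      "events": config.simulation.events,
                                      "seed": s_sim})
        seqs, truth = simulate_transcriptome(sim_cfg)
        if out is not None:
            write_fasta(seqs, out / "transcriptome.fa")
            truth.write(out)

    # stage 2-3: ORFs + all-vs-all detection at every stringency
    alignments = all_alignments(seqs, config.min_codons, config.prefilter)
    pair_counts = {
        name: len(detect_pairs(seqs, pol, alignments=alignments))
        for name, pol in POLICIES.items()
    }
    passing = detect_pairs(seqs, config.stringency, alignments=alignments)
    if out is not None:
        paralog_detect.pairs_table(alignments).to_csv(
            out / "pairs.tsv", sep="\t", index=False)

    # stage 4: clusters of exactly two
    retained, excluded = build_clusters(passing)

    # stage 5: Ka/Ks per retained pair
    results = _pair_results(seqs, retained, config.min_codons)
    if out is not None:
        kaks_table(results).to_csv(out / "kaks.tsv", sep="\t", index=False)

    # stage 6: selection summary
    selection = summarize_selection(results)
    n_excluded_pairs = sum(r.excluded for r in results)

    # stage 7: Ks mixture
    ks_vals, ks_ids = ks_mixture.filter_ks(results)
    selection_model = ks_mixture.select_model(
        np.log(ks_vals), seed=s_mix, k_max=config.k_max,
        n_restarts=config.n_restarts, bootstrap=config.bootstrap,
    )
    best = selection_model.best
    assignment = ks_mixture.assign_membership(best, ks_vals)

    # stage 8: dating
    event_ks: dict[int, list[float]] = {ev: [] for ev in range(1, best.k + 1)}
    for ks_val, ev in zip(ks_vals, assignment):
        if ev is not None:
            event_ks[ev].append(ks_val)
    dated = clock_dating.date_events(event_ks, config.rates)
    ages = [clock_dating.date(v, config.rates[0]) for v in ks_vals]
    bins = clock_dating.bin_dates(ages)
    if out is not None:
        clock_dating.events_table(dated).to_csv(
            out / "dated_events.tsv", sep="\t", index=False)
        bins.table().to_csv(out / "date_bins.tsv", sep="\t", index=False)
        pd.DataFrame({"pair_id": ks_ids, "ks": ks_vals,
                      "event": [e if e is not None else "ambiguous"
                                for e in assignment]}).to_csv(
            out / "memberships.tsv", sep="\t", index=False)

    # stage 9: optional genome scenarios
    scenario_counts = None
    if config.genome is not None:
        gen_cfg = GenomeConfig(**{**asdict(config.genome), "seed": s_gen})
        sim = simulate_genome(gen_cfg)
        if out is not None:
            sim.write(out / "genome")
        gms = _gene_models_from_sim(sim)
        tc_by_id = {t.id: t for t in sim.transcripts}
        tc_pairs = detect_pairs(sim.transcripts, "low")
        assignments = []
        for p in tc_pairs:
            ma = genome_scenarios.match_tc_to_gm(tc_by_id[p.id_a], gms)
            mb = genome_scenarios.match_tc_to_gm(tc_by_id[p.id_b], gms)
            assignments.append(
                genome_scenarios.classify_scenario(f"{p.id_a}|{p.id_b}", ma, mb))
        summary = genome_scenarios.summarize_scenarios(assignments)
        scenario_counts = dict(zip(summary["scenario"], summary["count"].astype(int)))
        if out is not None:
            summary.to_csv(out / "scenario_summary.tsv", sep="\t", index=False)

    report = RunReport(
        seed=seed,
        n_sequences=len(seqs),
        pair_counts_by_stringency=pair_counts,
        n_retained_pairs=len(retained),
        n_excluded_families=len(excluded),
        selection_percent=selection,
        n_excluded_pairs=n_excluded_pairs,
        best_k=best.k,
        lrt_p=selection_model.lrt_p,
        events=[
            {"event": e.event_index, "ks_median": e.ks_stat,
             "rate_label": e.rate.species_label, "age_my": e.age_my,
             "n_members": e.n_members}
            for e in dated
        ],
        date_histogram_total=int(bins.counts.sum()),
        scenario_counts=scenario_counts,
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(report.to_markdown())
    return report


def _gene_models_from_sim(sim) -> list[genome_scenarios.GeneModelLocus]:
    """Gene models from an in-memory simulation, via temporary files so the
    same GFF3 reader is exercised."""
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        sim.write(tmp)
        return genome_scenarios.load_gene_models(
            Path(tmp) / "genome.fa", Path(tmp) / "genes.gff3")


def kaks_table(results: Sequence[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": r.pair_id, "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
                "Ka": r.Ka, "Ks": r.Ks, "ratio": r.ratio, "label": r.label,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in results
        ],
        columns=["pair_id", "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio", "label",
                 "exclusion_reason"],
    )
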