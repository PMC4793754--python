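# Methods

## Overview

`tickdup` identifies paralogous sequence pairs in a set of coding/transcript
sequences, estimates per-pair synonymous (Ks) and nonsynonymous (Ka)
substitution rates, models the Ks distribution as a mixture of duplication
events, dates those events with a synonymous molecular clock, and classifies
pairs against a genome annotation. A codon-evolution simulator generates
study data with planted ground truth so that each stage's recovery can be
quantified.

## Sequence comparison and pair definition

Each input sequence is represented by its longest open reading frame, taken
over all six frames with the stop-to-stop convention (maximal codon runs
between stops or sequence boundaries; minimum 30 codons by default;
ambiguous bases translate to X and never act as stops). Stop-to-stop rather
than ATG-initiated ORFs maximize recovered coding length from transcript
fragments, whose true 5' ends are often missing.

Candidate pairs are aligned locally at the protein level (BLOSUM62, gap
open −11, extend −1). "Similarity" is the fraction of identical residues
over aligned non-gap columns — deliberately matrix-independent, so the
75 % threshold means the same thing regardless of scoring scheme. Coverage
is the local-alignment span on each member divided by its length, measured
including internal gaps (extent of match). The three stringency levels
share the 75 % identity threshold and differ in required coverage of the
smaller/larger member: low 75/50 %, medium 85/70 %, high 95/80 %. These
are component-wise ordered, so the detected sets are always nested
(high ⊆ medium ⊆ low). Because the pairwise alignment is symmetric,
reciprocality of a hit is automatic and not separately enforced.

Exhaustive all-against-all alignment is correct at desk scale (up to a few
thousand sequences). An optional prefilter aligns only pairs sharing at
least one exact 8-mer peptide; at ≥ 75 % identity and realistic protein
lengths the probability of no shared 8-mer is negligible, and the test
suite verifies the prefilter is lossless on planted data. Passing pairs are
clustered as connected components; only components of exactly two sequences
continue to Ka/Ks — larger components are multi-gene families, reported but
excluded, since within-family pair values are not independent.

## Ka/Ks estimation

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor correction,
chosen over maximum-likelihood codon models because it is deterministic,
dependency-free, and exactly checkable against a brute-force enumerator
(the test suite holds agreement to 1e−12).

* Sites: at each codon position, the synonymous fraction is the number of
  synonymous non-stop alternatives divided by the number of non-stop
  alternatives; s + n = 3 per codon. Site counts are averaged over the two
  sequences.
* Differences: codons differing at d positions are resolved by enumerating
  all d! orderings of single-nucleotide steps, discarding orderings that
  pass through a stop codon, and averaging synonymous/nonsynonymous step
  counts over the survivors with equal weights (classic NG86, no
  transition/transversion weighting). Columns whose every ordering crosses
  a stop are skipped and counted.
* Correction: p = D/S (or D/N) is corrected as d = −(3/4) ln(1 − 4p/3).
  The correction is undefined at p ≥ 3/4; such pairs are excluded as
  saturated — beyond this divergence multiple hits per site make the count
  uninformative, which is also why old duplications are undercounted by
  any similarity-based pipeline.
* Exclusions: identical sequences and pairs lacking synonymous
  substitutions (Ks = 0, ratio undefined) are excluded with reasons.
  Ka/Ks > 1 is labelled positive selection, < 1 negative; a ratio within
  1e−9 of 1 is reported separately as neutral.

The codon alignment is built by globally aligning the two longest-ORF
proteins and back-translating, dropping any column with a gap, stop or
ambiguous base. The universal genetic code is hard-coded; alternative codes
are out of scope.

## Mixture modelling of duplication events

Pairs with 0.05 < Ks < 1 (strict) enter the event analysis. The lower cut
removes alleles, haplotypes and assembly artifacts masquerading as very
young duplicates; the upper cut removes near-saturated estimates. Ks is
log-transformed, which makes within-event spread approximately normal and
comparable across events, and the ln(Ks) sample is modelled as a
k-component normal mixture, each component one duplication event.

Fitting is EM with 20 seeded restarts: the first initialization places
component means at the k interior sample quantiles with the pooled standard
deviation and uniform weights; the rest jitter the quantile means.
Convergence is a log-likelihood improvement below 1e−8 or 500 iterations;
component variances are floored at 1e−4. Restarts whose solution contains a
degenerate component — variance pinned at the floor, or fewer than two
effective members — are rejected in favour of the best non-degenerate
restart: these are spikes of the unbounded mixture likelihood sitting on a
few near-identical values, a known pathology of mixture MLE, and do not
represent duplication events. The EM inner loop is JIT-compiled (numba) so
the 20-restart, k ≤ 6 search stays interactive at n in the thousands.

Model count: models with k = 1..6 are fitted (k is skipped when n < 3k).
A k-component model is admitted only while each one-component increment is
statistically significant at p ≤ 0.05, assessed by a randomization test: a
parametric bootstrap (B = 100) of the likelihood-ratio statistic under the
smaller model. A chi-square reference with 5 degrees of freedom
short-circuits the bootstrap away from the decision boundary (below its 5 %
critical value the heavier-tailed bootstrap null could only be less
significant; at p < 1e−5 it could only be more). Among admitted models the
smallest AIC = −2 logL + 2(3k−1) wins, ties to the smaller k; parameters
are k means, k standard deviations and k−1 free weights. The significance
gate matters: with an exhaustive restart search, the maximized likelihood
of an overparameterized mixture always gains a little over the true model —
typically just past AIC's penalty — so bare argmin-AIC systematically
overfits (measured: the correct k = 2 chosen in only 6/20 planted samples,
and one component claimed for a pure normal sample in only 65 % of cases;
with the gate, 20/20 and ~97 % respectively). The chi-square(5) p-value of
the winning step is always reported alongside.

Pairs are assigned to the component with posterior membership > 0.75
(components indexed by ascending mean, so event 1 is the youngest);
anything less certain is ambiguous and excluded from event medians.

## Molecular-clock dating

Event ages come from T = Ks / (2r): divergence accrues at rate r on each of
the two lineages. The event statistic is the median Ks of assigned member
pairs — robust to the skew that the Ks window and membership thresholding
induce — with the back-transformed fitted means also reported. The shipped
calibration is the *D. melanogaster* genome-wide synonymous rate,
r = 1.6×10⁻⁸ substitutions/site/year (equivalently 0.016/site/MY); it is
stored in substitutions/site/year, and user-supplied TSV calibrations
produce a range of dates per event. Pair-level ages are histogrammed in
0.1-MY bins on [0, 6) MY and non-linear bins with edges 6, 7, 11, 16, 36,
176 MY plus an overflow bin, left-closed right-open.

## Genome scenario classification

Transcripts are matched against spliced gene-model sequences (exon
concatenation per GFF3; both orientations tried) by local nucleotide
alignment, keeping hits with identity and coverage above 75 % — coverage is
required on both the transcript and the gene model by default
(configurable). Matching spliced sequences avoids implementing a spliced
genome aligner and is exact for the simulator's gene structures. Two
matches are the same locus when their genomic intervals overlap by ≥ 1 bp
on the same seqid and strand, which absorbs small alignment-extent
differences. A transcript pair is then classified by its distinct matched
loci: E when either member matches nothing; D for one locus (collapsed
annotation); A for two loci on one supercontig (tandem); B for two loci on
different supercontigs (dispersed/segmental); C for more than two loci
(annotation in excess of transcripts). Strand is recorded for manual
inspection. The classification is total and deterministic.

## The simulator

The generator plants everything the pipeline is asked to recover.
Ancestral coding sequences are ATG + L uniform sense codons + stop; no
codon-usage bias is modelled. A paralog pair evolves by sequential uniform
single-nucleotide proposals applied alternately to two copies: proposals
creating stops are rejected; nonsynonymous proposals are accepted with
probability min(1, ω) and synonymous ones with min(1, 1/ω); evolution stops
when the pathway-counted synonymous divergence — accepted synonymous events
over NG86 synonymous sites of the current copies, summed over both copies —
first reaches the target Ks. The realized Ks and Ka (event counts, not the
targets) are recorded as truth. This yields controllable divergence with
exactly known ground truth without committing to a named rate-matrix codon
model; a consequence is that realized Ka ≈ ω·Ks by construction.

Defaults define the study conditions: ~1,000 sequences (665 singletons),
two events of 75 pairs at Ks 0.1 and 0.45 with ln-dispersion 0.2 (the
dispersion is a modelling choice; no empirical per-event value was
available), ω = 0.1 for purifying pairs, ω = 3 for the 20 % of pairs under
positive selection, 300-codon sequences, and five three-member families at
low divergence. The toy genome plants a configurable number of cases per
scenario A–E: genes are split into up to three exons with uniform-random
introns of 100–500 nt (GT..AG termini are not enforced — nothing inspects
splice sites) and separated by 300-nt intergenic spacers; GFF3 coordinates
are 1-based inclusive, all internal coordinates 0-based half-open.

What the simulator does not emulate — and hence what passing tests do not
show about real data: indels and frameshifts, codon-usage and GC bias,
transposable-element and tandem-repeat background, rate variation among
sites and lineages, alternative splicing and haplotype redundancy in
transcript sets, and assembly/annotation error beyond the five stylized
scenarios.

## Known limitations and biases

* **Selection-detection interaction.** A similarity threshold biases
  discovery against positively selected paralogs: with Ka = ω·Ks, a pair
  with ω = 3 at Ks = 0.1 is only ~50 % identical at the protein level and
  fails any 75 % filter; at Ks = 0.45 it is unrecognizable even at the
  nucleotide level (a pair at that Ks would need ω ≤ ~0.6 to stay above
  75 % nucleotide identity). Under the default study conditions the
  pipeline therefore reports a positive-selection share near 0 % despite
  the planted 20 % — the end-to-end recovery test states the planted value
  and is expected to flag this bias. Real surveys are affected the same
  way; their positively selected pairs are the subset whose absolute Ka is
  small.
* Saturation excludes old duplications (p ≥ 3/4), and the Ks < 1 window is
  stricter still; event counts are lower bounds for ancient events.
* NG86 is slightly downward-biased at moderate divergence relative to the
  pathway-counted truth (~5 % at Ks 0.3); the mixture medians inherit this.
* Clock ages are point estimates under a strict clock and a borrowed
  calibration; no uncertainty intervals are produced.
* The EM restart search is stochastic in initialization but fully
  deterministic given the seed; all pipeline stages derive child seeds from
  one global seed via `numpy.random.SeedSequence`.

## Numerical and degenerate-input conventions

Ties in longest-ORF selection break to the + strand, then the smallest
start. AIC ties break to the smaller k (compared after rounding at 1e−12 to
absorb float noise). Empty survivor sets (no Ks in the window, no classified
pairs, no ORFs in a sequence) raise explicit errors or drop-and-log rather
than propagating NaNs. Mixture events with no assigned members produce
flagged rows with undefined age. Saturation in the simulator (a divergence
target unreachable within the proposal budget) raises an error rather than
looping.
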