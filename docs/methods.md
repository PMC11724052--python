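# Methods

## The signal model

`tailcomp`'s simulator emulates nanopore direct RNA sequencing (DRS) at
the level the analysis actually consumes: a per-read current trace with a
known segmentation into adapter, poly(A) tail and transcript body, and
known non-adenosine residues planted in the tail.

**Pore model.** One current event is emitted per k-mer (default k = 5) of
the emitted base sequence. Event levels come from a synthetic table:

    level(kmer) = A0 + sum_i effect(base_i) * w_i + eps(kmer)

with `A0 = 90 pA` (the poly(A) plateau), base effects 0 (A),
+2.5·s (C), −2.5·s (G), +5·s (U) for separation `s` (default 10 pA),
per-position context weights `w_i` a seeded permutation of k evenly spaced
multipliers in [1.0, 1.4], and a per-k-mer jitter `eps` within ±0.1·s.
Only level *contrasts* matter to the method, so no vendor table is used.
Two deliberate design properties:

* the three residue classes occupy **disjoint amplitude bands**
  (C: +[25, 35] pA, G mirrored below, U: +[50, 70] pA at the default
  separation), so class identity is decidable from a single resolved
  event;
* the context-weight permutation is chosen so that the expected
  adapter-junction event levels stay at least 0.5·s away from every
  single-substitution level — the segmenter's junction model must never
  alias a genuine 3'-terminal residue anomaly. The adapter ends in G
  because its final junction k-mer (G + A^(k−1)) is *physically*
  indistinguishable from a guanosine at the extreme tail end; G is the
  rarest residue class, which minimises the cost of that degeneracy.

**Dwell clock.** Per-event dwell times are i.i.d. geometric with mean
`translocation_rate` (default 30 samples/nt); Gaussian noise (default
sd 2 pA) is added per sample. The geometric clock has relative sd ≈ 1
per event, which gives any tail-length or position estimate an
irreducible relative error of about 1/sqrt(L) — see *Known limitations*.

**Generator defaults** describe a testis-like condition: 2 000 reads per
sample in the benchmark configuration, tails uniform on 20–250 nt, a 10%
decorated-read fraction, residue weights U 0.6 / C 0.25 / G 0.15, and a
terminal bias of 0.7 (with probability 0.7 a residue is placed in the
3'-terminal 10% of the tail, otherwise uniformly). Three resolvability
constraints are built in, fixed before any benchmarking: planted residues
sit at least 3k nt apart (closer residues share k-mers and merge into one
excursion under dwell jitter), at least k−1 nt from the tail's 5' end, and
at position ≥ 2 from the 3' end (position 1's k-mer context overlaps the
ligated adapter and is not resolvable in signal space). Synthetic
transcripts end in exactly k−1 adenosines (annotated 3' ends abut the
tail) and contain no internal A-homopolymer of length k, which would
recreate the poly(A) pore state inside the body and make the tail
boundary — and hence the generator's own ground truth — ill-defined.

## Segmentation

The tail is found as the longest run of 25-sample windows whose variance
is below 2·sigma² (sigma = robust per-read noise from the median absolute
first difference, capped at 4 pA) and whose mean lies within a
noise-adaptive tolerance of the all-A level. Runs separated by short gaps
are merged only when the gap looks like a genuine residue excursion: its
window means stay below the largest single-substitution deviation, its
smoothed samples plateau only at single-substitution levels, and it
contains no stretch matching the aligned transcript's junction k-mer
levels (see below). Boundaries are refined per sample and, on noise-free
signals, recovered exactly.

Two pieces of prior knowledge sharpen the 3' and 5' boundaries:

* **Adapter side.** The adapter sequence is a known constant, so the
  expected levels of its last events and of the k−1 adapter/tail junction
  k-mers are known. A backward scan from the refined tail start marks a
  contiguous block that those levels cannot explain as a 3'-terminal
  residue anomaly and pulls the boundary back to its start; a second rule
  rescues anomalies degenerate with the final junction k-mer by looking
  for *novel plateaus* while passing through junction-level runs that lack
  their expected predecessor event.
* **Transcript side.** When the read's transcript assignment and sequence
  are available (the stand-in for the alignment stage), the levels of
  early body k-mers with ≥ 2 non-A bases — levels a genuine tail can never
  produce — serve as *body evidence* that stops boundary extension and
  trims bleed into the body.

The read rate is the transcript-segment length in samples divided by its
k-mer event count (`transcript_nt − k + 1`); without a known transcript
length a changepoint-counting fallback is used. `polya_length_nt` is
`(transcript_start − polya_start) / read_rate`. Reads whose transcript
segment is shorter than `min_transcript_samples` (default 3 000) are
tagged `SUFFCLIP`; unloadable/NaN signals `READ_FAILED_LOAD`; signals
without a qualifying low-variance run `NOREGION`; signals without an
adapter-like prefix `ADAPTER`; everything else `PASS`. Only `PASS` and
`SUFFCLIP` reads are analysed downstream.

## Residue detection

Moves are flagged where consecutive one-translocation-step window means
differ by more than `tau` (default 3) robust scales of the tail signal;
the scale is the smaller of the tail MAD and the per-read noise estimate
(the MAD alone is inflated on short, heavily decorated tails). Moves are
grouped generously and split at interior all-A plateaus of at least 1.5
translocation steps — the plateau, not the move gap, is what separates two
residues. Each excursion must contain a *novel* plateau (a stable stretch
at a level the junction model cannot explain), must move the window's mean
absolute deviation past the gate (3 robust scales, floored at 1 pA), and
must not be dominated by out-of-range samples (saturation, default
90 pA).

Accepted excursions are resampled to a fixed W = 30 samples across their
span — capturing the full k-event anomaly shape regardless of dwell
times — normalised against the all-A level on a fixed 80 pA scale, and
encoded as a Gramian angular summation field (GASF):
phi_i = arccos(x_i), M_ij = cos(phi_i + phi_j). Because the GASF is
invariant under a global sign flip, the classifier's features are the
flattened GASF plus the normalised window and four up-weighted extremal
summaries (max, min, mean, median), which keep C (level up) separable
from G (level down) and encode the disjoint class amplitude bands. The
classifier is a multinomial logistic regression trained on windows
extracted through the production path from simulated single-residue reads
(120 per class by default, stratified 70/30 held-out split, residues with
a signal footprint under 6 samples excluded as unlabel-able); its held-out
confusion matrix and macro recall are stored on the model. A
*level vote* — the rightmost deviant plateau of the excursion matched
against the 3k single-substitution levels — overrides the shape classifier
when it lands unambiguously on another base's level; the rightmost plateau
is used because corrupted junction k-mers can only flank a 3'-terminal
excursion on the left.

The reported position is `round(centroid/rate + 1 + (k−1)/2)` (the
excursion centres about half a k-mer before the residue), clamped into
[1, ceil(tail length)]. Calls closer than 1.2·k translocation steps are
collapsed to the most 3'-ward one (fragments of one excursion), and under
noise excursions flush against the segment's 5' end are discarded as
boundary artefacts (the last k−1 tail events are always plain adenosine
context). Read classes follow the five-way scheme: `qc_failed` (tag
outside PASS/SUFFCLIP), `blank` (no moves), `move_issue` (moves but no
gated window), `signal_issue` (saturated or otherwise rejected windows),
`decorated` (at least one call).

## Statistics

Composition frequencies use decorated + blank reads as the denominator;
both per-read frequencies and per-instance shares are reported since bar
heights in the field's figures could be either. The terminal-enrichment
statistic is the median over a transcript's calls of
r = position / ceil(tail length); the p-value is Monte-Carlo, drawing each
call's position uniformly on {1..ceil(tail)} of its own read
(999 permutations by default) with the add-one correction
(count + 1)/(n_perm + 1); transcripts with fewer than 10 calls are
declined (NA) rather than tested. Concordance matrices are pairwise
Spearman correlations (average ranks, pairwise-complete transcript
intersection, NA below 3 shared transcripts) over per-transcript counts or
mean tail lengths.

## Differential expression

The DE stage is a deliberately transparent analogue of the standard
count-based workflow, not a re-implementation of any packaged numerics.
Size factors are median-of-ratios against the per-gene geometric mean,
normalised to geometric mean 1. Per-gene NB dispersions are
method-of-moments estimates from within-condition residuals, floored at
1e-8 and shrunk on the log scale towards the trimmed across-gene mean with
prior weight 20 (the per-gene moment estimator is so skewed at 2–3
replicates that its median badly underestimates the common dispersion).
The Wald statistic on the condition log2 fold change is referred to a
t distribution whose df is the residual df plus the moderation weight; a
plain normal reference is measurably anticonservative at n = 3 + 3 and
pushes the null false-positive fraction to the edge of its acceptance
band, so the t reference is the package's own calibration choice.
Fold-change shrinkage is empirical-Bayes normal: prior variance = observed
lfc variance minus mean sampling variance (floored), posterior mean
`lfc·tau²/(tau²+se²)`; it contracts every gene and contracts noisier genes
more. Benjamini–Hochberg adjustment uses statsmodels and is tested against
a brute-force step-up oracle. The terminal-U overlay flags transcripts
passing the terminal test at alpha = 0.05 and computes a one-sided Fisher
exact test on terminal-U × downregulated (padj < 0.05 and lfc < 0); a
degenerate table's infinite odds ratio is reported as a capped sentinel
with the exact p-value intact.

## Problem sizes and determinism

The shipped benchmarks use 500–2 000 simulated reads per sample with
transcripts of 300–500 nt, 500 profiles × 999 permutations for test
calibration, 2 000 genes × 3 + 3 replicates for DE calibration, and 50
replicates of the joint terminal-U/expression simulation; these sizes give
binomial standard errors comfortably inside every stated tolerance. All
stochastic steps take explicit seeds; identical configurations reproduce
outputs bit-exactly.

## What the synthetic study does and does not show

The generator reproduces the features the method depends on — a flat
A plateau, k-mer-scale anomalies with class-specific amplitudes, a
stochastic translocation clock, adapter/tail/body structure, a decorated
minority with U > C ≥ G composition and 3'-terminal uridine bias — but not
real-pore systematics: homopolymer slippage, low-frequency drift (a hook
exists but is off by default), non-Gaussian noise, basecaller-dependent
read rates, or the true spectrum of tail lengths and residue multiplets.
Passing benchmarks therefore demonstrates the internal consistency and
calibration of the algorithms under the stated signal model, not
performance on any particular sequencing dataset.

## Known limitations

* **Translocation-clock floor.** With i.i.d. geometric dwells the tail's
  sample-length has relative sd ≈ 1/sqrt(L), so even a perfect boundary
  and rate estimate leave a median relative tail-length error around
  0.67/sqrt(L) — about 6–7% over the 20–250 nt range, which the benchmark
  reports honestly. Positional estimates inherit the same sqrt(q) jitter,
  which is why truth matching in the benchmarks happens in sample space,
  where the detector's localisation is exact at zero noise.
* **Junction degeneracies.** A guanosine at tail position 1–2 is partly
  degenerate with the adapter's final junction k-mer, and cytidine's
  amplitude band lies closest to typical corrupted-junction levels; C
  precision at default noise runs a few points below the other classes.
  Residues whose entire resolvable footprint dwells for only 1–2 samples
  (probability ≈ 0.1% under the default clock) are physically
  undetectable and remain as rare misses.
* **Interop readers** for the external TSV dialects are exercised only on
  synthetic data by design.
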