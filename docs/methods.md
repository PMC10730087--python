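# Methods

`markdyn` implements the downstream statistics used to characterise how a
gene-body histone mark (the motivating case is H2B monoubiquitylation,
H2Bub1) redistributes across cell-state transitions, and how its loss
affects transcript integrity. All analyses run on standard text inputs
(BED/broadPeak peaks, bedGraph coverage, BED12/GTF gene models, TSV
abundance tables) and, for testing, on seeded synthetic data with planted
ground truth.

## Coordinate and signal conventions

Everything internal is 0-based half-open (BED). GTF input is shifted on
read. Coverage is a stepwise function; positions outside recorded spans read
as 0, which makes interval means, binned means and RPM scaling well defined
everywhere. RPM normalization scales a track so that its integral (value ×
span length summed over spans) equals 10^6; it removes library-depth
differences and is exactly depth-invariant by construction.

## Compartment enrichment

Peaks are assigned to A/B compartment intervals (A: positive eigenvector
score, B: negative; zero scores are rejected at load because the sign rule
does not cover them) when they overlap an interval by at least 20 bp; among
several qualifying intervals the largest overlap wins. The expected %B under
random placement resamples compartment *rows* with replacement until the
resample matches the peak-file row count, repeated for 1000 bootstrap
replicates; mean, SD and SEM are taken over replicates. Row resampling
deliberately ignores interval length — it mirrors the row-level procedure
the analysis is modelled on — and a length-weighted variant is available but
off by default.

Two p-values are computed per replicate:

- empirical: p = (1 + #{E_i ≥ O}) / (n + 1), floored at 1/(n+1);
- normal: z = (O − Ē)/SD(E) referred to the standard normal tail.

The normal form is the default because reported significance levels below
10⁻⁵ are unreachable with 1000 empirical replicates; the exact parametric
form used by the original analysis is not recoverable from its description,
so both are provided and neither is asserted as *the* original equation.
A stage is called significant only when **every** ChIP replicate has
p < 0.05. Between-stage percentages are compared with
z = (p₁ − p₂)/√(SE₁² + SE₂²). SEM over bootstrap replicates and over ChIP
replicates are both reported, since the original description does not say
which spread its expected values carry.

## Co-occurrence of marks

Gene-level presence (1/0) of each peak set is recorded over the gene body
plus the ±3 kb promoter window (configurable to body only; the span the
original analysis used is unstated). For a pair of marks the 2×2 table
(both / first only / second only / neither) gets fixed-margin expected
values e_ij = k_i·m_j/N, a plain Pearson χ² with 1 df (no continuity
correction), and per-replicate observed/expected ratios compared between
stages with Welch's unequal-variance two-tailed t test.

## TSS occupancy and clustering

The TSS window is (−2 kb, +10 kb), binned at 50 bp (240 bins), strand-aware
so every row reads 5′→3′; windows that run off the chromosome zero-pad.
Replicate matrices are averaged before clustering. Gene profiles are
clustered with k-means (seeded, 10 restarts). The number of clusters is
selected by an elbow rule: the maximum second difference of **log** WCSS
over k = 1..10, ties toward smaller k. The curvature is taken on the log
scale deliberately: on the raw scale the k=1 term dominates the curve and
the second difference degenerately selects k=2 for any level-separated
occupancy data, whereas the relative-drop curvature recovers the planted
k=4 structure robustly (raw-scale curvature remains available via
`elbow_scale="raw"`). Genes with zero signal are kept — they form the
"no mark" cluster.

## Differential consensus

Calls survive at q ≤ 0.05 and |log₂ FC| ≥ log₂ 1.5 (both boundaries
inclusive), must be supported in ≥ 2 of 3 replicates at the region level,
and a gene is differential only when both independent mutant lines carry a
surviving call in the same direction. "Maintained" genes are those occupied
at both flanking stages and absent from the decreased set; occupancy at both
stages (rather than the later stage alone) is the stricter reading of
maintenance and the default, with the membership sets exposed so the
alternative is one set operation away. Proportion enrichment between two
gene sets uses the pooled two-proportion z test, one-sided by default.
The per-region Welch-t + Benjamini–Hochberg differential test included in
the package is plumbing for self-contained synthetic runs, not an affinity
or likelihood model.

## Matched random gene sets and the length test

A reference set's lengths are fitted by a Poisson rate (MLE: the mean, in
bp; at rates ~10⁴–10⁵ the distribution is effectively its normal limit, so
the unit choice only affects the dispersion of drawn targets). Each random
set draws |reference| target lengths from that fit and matches every target
with a uniformly random gene whose length is within ±10% and that carries
the required regulation class (up/down/non) in **both** mutant conditions.
On exhaustion the tolerance widens in +5-point steps to 25% with a logged
warning, then errors. Sampling is without replacement within a set (no
duplicate genes) and with replacement across sets. The gene-length
enrichment test instead draws plain quantity-matched sets (uniform, without
replacement) and reports p as the exact fraction of 10,000 random sets whose
mean length exceeds the observed mean; the default candidate pool is all
annotated transcripts, configurable to expressed-only.

## Metagenes, central accumulation, windowed ratios

Gene bodies (no flanks) are scaled to 100 bins, 5′→3′, RPM-normalized,
averaged over genes and then replicates; genes shorter than the bin count
are excluded with a warning. The central-accumulation score quantifies what
is usually judged from plots by eye: mean of bins 40–60 minus the linear
interpolation of the bin 10–30 mean to the bin 70–90 mean evaluated at the
centre. It is zero for any linear profile, shift-invariant, and recovers a
planted rectangular central bump's amplitude exactly in noise-free data.
Length-quartile metagenes split genes by length rank with a stable
(length, gene_id) tie-break.

The full-length-transcript analysis computes log₂((mut + c)/(wt + c)) in
100 windows per gene (c = 1 RPM-unit pseudo-count, configurable), averaged
per replicate and then across replicates. The tail-loss statistic is the
mean of the last 20 windows minus the mean of the first 80 on the gene-set
trace; its one-sided p-value permutes window labels within each gene
(n = 1000 by default), so the null preserves per-gene value distributions
while destroying positional structure.

## What the generators emulate — and what they do not

The synthetic coverage model is a linear 5′→3′ declining baseline (high 5′
end), an optional rectangular central bump of known amplitude A over a known
width, and truncated-at-0 additive Gaussian noise on binned values.
Truncation is a hard stop at 80% of gene length affecting a known fraction
f of transcripts, which makes the expected last-20% log₂ ratio exactly
log₂(1 − f) and keeps the tail-loss oracle closed-form. Compartment
scenarios tile one chromosome with equal-size intervals, a known B fraction
and a placement bias b mixing uniform placement (b = 0) with B-only
placement (b = 1). Genes sit on one synthetic chromosome with ≥ 10 kb gaps
so nearest-gene annotation is unambiguous.

Not modelled: read-level sampling noise (counts are continuous), fragment
size and GC effects, overlapping or nested genes, multi-isoform structure,
chromosome-scale covariation of compartments and expression. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under the stated model, not robustness to every artefact of real libraries.

Two constraints matter when designing scenarios:

- **Resolution.** The window-permutation null assumes the 100 window values
  of a gene are exchangeable. Coverage generated (or binned) coarser than
  one window makes adjacent windows block-correlated and inflates the
  type-I error (we measured ~25% at nominal 5% with 50 bp bins on 1 kb
  genes); generators therefore take a `bin_size` that should not exceed the
  window width.
- **Pseudo-count scale.** With c = 1 RPM-unit, a planted 50% truncation
  reads as a last-20% ratio of −1 only when per-base RPM signal is well
  above c; the recovery scenarios use a compact covered footprint (tens of
  kb) so RPM values are ~25–50.

## Default parameters

| parameter | default | unit | role |
| --- | --- | --- | --- |
| q_max | 0.05 | – | differential q-value ceiling |
| min_fold | 1.5 | linear FC | differential fold-change floor |
| min_support | 2 (of 3) | replicates | region-level support |
| min_overlap | 20 | bp | peak-to-compartment assignment |
| n_reps (bootstrap) | 1000 | replicates | expected %B distribution |
| promoter window | ±3000 | bp | annotation / presence span |
| TSS window | (−2000, +10000) | bp | occupancy matrix |
| bin size (TSS) | 50 | bp | occupancy matrix columns (240) |
| metagene bins | 100 | – | scaled gene body |
| tolerance | 0.10 | fraction | length matching window |
| n_sets (length test) | 10000 | sets | length-enrichment null |
| pseudo-count c | 1 | RPM-unit | windowed log₂ ratio |
| tail fraction | 0.2 | – | tail-loss statistic |
| n_perm | 1000 | – | tail-loss permutation |

## Problem sizes used in the shipped checks

Calibration suites use 200 seeded runs each (compartment null, truncation
null, length-test null), 100-interval compartment tracks with 200–600
peaks, 1000 bootstrap replicates, 15–60 genes per coverage scenario at 1–2
kb, 10,000-set length tests over pools of 200–600 genes, and a 400-gene ×
240-bin archetype matrix for clustering recovery. These sizes keep the
whole suite in well under half an hour on one core while leaving every
statistical check at its stated tolerance.

## Known limitations

- The bootstrap expectation resamples compartment rows, not base pairs, so
  long and short intervals are weighted equally (by design; a
  length-weighted option exists).
- The elbow rule, like any k selector, is only meaningful when cluster
  separation exceeds the noise floor; at high noise it degrades toward
  smaller k.
- The per-region differential stand-in is intentionally simple; for real
  data the thresholds and consensus rules should be applied to the output
  of a dedicated differential-binding or transcript-level tool.
- The central-accumulation score and tail-loss permutation test are this
  package's own quantifications of behaviours that the motivating analyses
  assessed by inspection of plots; output headers label them as such.
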