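# Methods

`rcakit` models the computational core of a rolling-circle-amplification
(RCA) consensus sequencing workflow for cell-free DNA (cfDNA): building
error-reduced consensus reads from concatemeric nanopore reads, and
estimating the tumor fraction (TF) of a cfDNA sample from tumor-informed
SNVs and from fragment-length signatures, plus an in-silico
limit-of-detection (LoD) study.  Everything runs on synthetic data
produced by `rcakit.synth`; all stochastic operations take an explicit
seed and are bit-reproducible.

## Consensus model

A concatemer carries `r` copies (subreads) of one template fragment.
The error model is substitution-only: each subread base is wrong
independently with probability `e`, and a wrong base is uniform over the
three alternatives.  Subreads are therefore column-aligned to template
coordinates by construction; alignment itself is out of scope.

Consensus is a per-column plurality vote.  Ties are broken by highest
summed subread quality, then by the template base if it is among the
tied candidates, then alphabetically.  Consensus quality per column is
the summed Phred quality of agreeing subreads minus that of disagreeing
ones, floored at 2 and capped at 60.  Reads with fewer than 3 repeats
are rejected: with `r = 2` a single error already forces a tie, so no
error reduction is possible.

`consensus_error_theory(e, r)` enumerates all multinomial outcomes of
`r` subread bases and returns the exact per-column miscall probability
(a column is miscalled iff some single wrong base strictly outnumbers
the correct one, because quality ties resolve toward the template).
For `e = 0.00674, r = 3` it gives `4.54e-5`, a ~150-fold reduction; the
Monte Carlo consensus path is checked against this enumeration over
10^6 columns.

Backbone trimming matches the read's prefix against the backbone's tail
and the read's suffix against the backbone's head (the orientations
adjacent to the insert in a concatemer), removing the longest
end-anchored match with at most 10% mismatches.  A minimum anchored
overlap of 5 bp prevents spurious 1–2 bp trims on flank-free reads.
Deduplication single-links reads whose starts and ends both agree
within ±1 bp and keeps the member with the most repeats (ties: earliest
timestamp); output is coordinate-sorted, making the operation
idempotent.

## Error-rate protocol

The measured error rate is substitutions / mapped read length, indels
excluded.  Before counting: reads below MAPQ 60 are dropped, reads
overlapping any germline-mask position are dropped, a maximal set of
mutually non-overlapping reads is kept (seeded random priority, then a
per-chromosome left-to-right greedy sweep), and at most 400,000 reads
are retained.  Phred conversion truncates: `Q = floor(-10 log10 e)`,
so 0.00674 → Q21 and 0.00072 → Q31; the unrounded value is exposed
separately.

## SNV tumor-fraction estimator

Each observation is one read overlapping one tumor-informed variant
site and is classified REF, MUT or ERR (an alternative allele that is
not the tumor's ALT).  A tumor-derived read at site `i` is MUT with
probability `P_i = purity × VAF_i` (the biopsy VAF folds in copy number
and heterozygosity; purity corrects for normal contamination of the
biopsy).  A healthy-derived read is MUT only through a sequencing error
hitting the site's specific ALT base, probability `e/3`; errors to the
two other bases are recorded ERR.  Setting `e = 0` recovers the pure
mixture model.

The estimator varies TF over 100 linear steps on [0, 1].  At each grid
TF it simulates the MUT count of the observed number of observations
10,000 times and scores the grid point by the fraction of trials whose
count equals the observed MUT count (the match window widens to ±k with
the smallest k giving nonzero mass, needed only for very large
observation counts).  The best-aligned TF is the point estimate.  If it
falls below 0.05, the search repeats on a fine grid of 0 plus 99
log-spaced points on [1e-4, 0.10].

Two numerical choices matter:

* **Sampling identity.**  With observations assigned to sites uniformly
  and independently, the total MUT count is exactly
  `Binomial(n_obs, mean_i(tf·P_i + (1−tf)e/3))`.  The simulator draws
  from this identity rather than looping over observations; a
  per-observation brute-force sampler is kept in the test suite and the
  two routes are compared distributionally.
* **Interval construction.**  The 95% CI spans the 2.5%/97.5% quantiles
  of the alignment profile *integrated over TF*: each grid point's
  weight is multiplied by its grid-cell width before normalization.
  Without this, the log grid's point density acts as an implicit 1/TF
  prior and the interval systematically misses high at low TF
  (measured 85% coverage at TF = 0.01, restored to ≥92% with the
  width correction).  The point estimate remains the raw argmax.

The grid resolution bounds the estimator's precision: once the MUT-count
distributions of adjacent grid TFs no longer overlap (roughly
n_obs ≳ 2,000 on the linear grid for these panels), the weight profile
collapses onto a single grid point and the CI degenerates to that
point.  TF differences smaller than one grid step are not resolvable by
construction.

## Fragmentomics estimator

Fragment lengths are histogrammed at 1 bp on 30–220 bp and normalized
to sum 1.  The profile is decomposed against two fixed nonnegative
signatures by nonnegative least squares (the single-step equivalent of
NMF with a frozen basis): Signature 1, healthy-dominant; Signature 2,
tumor-indicative.  TF = w2/(w1+w2), capped at 1.0 — both profile and
signatures are normalized, so the weights sum near 1 and the cap is a
true boundary.  Exact signature mixtures are recovered to ≤1e-6.

The packaged signatures are parametric stand-ins built from the
fragment-length model below (healthy density, and tumor-shifted density
with 10 bp periodicity amplitude 0.5, each renormalized on 30–220 bp);
externally derived signatures can be supplied as TSV and override them.

The AFM calibration `L_bp = (L_nm + 10)/0.341` converts traced fiber
lengths from atomic-force-microscopy images to base pairs.

## Synthetic-data generator

The generator defines the study conditions; its defaults are not tuned
per experiment.

* **Fragment lengths**: discrete two-component truncated normal mixture
  on 30–700 bp.  Healthy: modes 167 (mono-nucleosomal) and 332 bp
  (di-nucleosomal), weights 0.85/0.15, sds 12/10 bp.  The di-component
  sd of 10 bp keeps the secondary mode resolvable as a histogram argmax
  at 10^5 fragments (with a much wider component the argmax wanders by
  ~±10 bp at that depth, i.e. the mode would not be a measurable
  quantity at the sample sizes used here).  Tumor: both modes shifted
  down 4.5 bp; the sub-170 bp density is multiplied by
  `1 + amp·cos(2π(len − shifted_mode)/10)` and renormalized.  The
  cosine is phased on the shifted mono mode so the tumor mode stays at
  162–163 bp; a side effect of modulating a sloped envelope is that
  individual peak spacings compress to 9–10 bp, so periodicity is
  asserted spectrally (dominant period 10 ± 1 bin), not by raw
  autocorrelation argmax.
* **Variant panels**: VAFs from a normal truncated to (0, 1]
  (default mean 0.3, sd 0.15 — mid-range for the 10–582-SNV panels the
  workflow targets), positions globally unique, one purity per panel.
* **Concatemers**: repeat counts `1 + Poisson(5)` (median 6, minimum 1);
  iid substitutions at the chosen error rate; constant per-base quality
  equal to the Phred value of that rate; timestamps uniform over a 72 h
  run.
* **Allele observations**: per-site read counts Poisson(coverage) — the
  standard shallow-WGS assumption; tumor/healthy origin Bernoulli(tf);
  calls as in the estimator's model; timestamps uniform over the run.
* **Admixtures**: tumor records kept with probability `fraction`,
  healthy with `1 − fraction`, so size is preserved in expectation and
  MUT content scales linearly.

What the generator does **not** emulate: alignment and mapping
artifacts, indels, strand effects, GC bias, FFPE artifacts, clonal
hematopoiesis, site-to-site coverage correlation, and real
fragment-length fine structure beyond the two modes plus periodicity.
Passing tests therefore demonstrate correctness of the algorithms under
the stated statistical model, not performance on real sequencing data.

## Limit-of-detection simulation

Platform presets (coverage ×, per-base error): raw-minion (0.25,
0.00674), raw-promethion (3, 0.00674), consensus-minion (0.04, 0.00072),
consensus-promethion (0.8, 0.00072).  For each TF on a grid of 0 plus 50
log-spaced values on [0.001, 1], each of 10,000 trials draws
`n_obs ~ Poisson(coverage × n_sites)` and a MUT count from the marginal
model above.  Detection declares tumor when the MUT count reaches the
smallest integer threshold whose true-negative rate on the TF = 0
trials exceeds 0.68; the LoD is the smallest grid TF with true-positive
rate > 0.95.  The detection statistic (count exceedance over a
null-calibrated threshold) is the simplest one consistent with
count-based SNV detection; other statistics would shift absolute LoDs.

Known consequence of that statistic: at matched device, consensus
calling does *not* always win.  On MinION the coverage cost of
consensus (0.25× → 0.04×) outweighs the ~9.4× error-rate improvement,
so raw MinION reaches lower TFs than consensus MinION, while consensus
PromethION (0.8×, Q31) clearly beats raw MinION.  Lower error rate and
higher throughput each help; the simulation quantifies their trade-off
rather than assuming consensus dominates.

Monotonicity checks (LoD nonincreasing in coverage, nondecreasing in
error rate) use common random numbers — the same seed per grid cell —
as variance reduction, so the comparison is not blurred by Monte Carlo
noise at 2,000 trials.

## Problem sizes and tolerances

Test problem sizes were chosen so the full suite runs in about a
minute: 10^5 fragments for mode checks, 10^6 consensus columns, 200
replicates × 3 TFs × ~1,000 observations for estimator calibration,
2,000 trials per LoD grid cell.  Monte Carlo assertions use 3–4
binomial/empirical SDs; exact arithmetic uses 1e-6 to 1e-12.  The
degenerate inputs each operation rejects (empty templates, ragged
subread stacks, zero observations, all-zero profiles, out-of-range
probabilities) raise `ValueError` with a named cause rather than
propagating NaNs.
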