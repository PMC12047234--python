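# rcakit

Rolling-circle consensus calling and multimodal tumor-fraction
estimation for nanopore cell-free DNA (cfDNA) sequencing — as a tested,
fully synthetic-data-driven toolkit.

Liquid biopsies contain a small fraction of tumor-derived DNA (ctDNA)
whose mutant alleles occur at frequencies comparable to sequencing
errors.  Rolling-circle amplification (RCA) turns each cfDNA fragment
into a concatemer of linked copies; a per-position plurality vote over
those copies collapses random errors (raw error ~0.00674 ≈ Q21 →
consensus ~0.00072 ≈ Q31, a ~9.4× reduction), making genome-wide
tumor-informed SNV detection feasible on a nanopore device.  `rcakit`
implements the computational side of that workflow for methods
developers and bioinformaticians:

* **`rcakit.synth`** — seeded generators for every input: bimodal
  cfDNA fragment lengths (modes ~167/~332 bp; tumor profiles ~4–5 bp
  shorter with 10-bp periodicity), tumor-informed variant panels,
  concatemer reads with iid substitution errors, per-read allele
  observations, and in-silico admixtures.
* **`rcakit.consensus`** — plurality-vote consensus over subread
  stacks (reads with <3 repeats rejected), quality aggregation,
  backbone trimming, ±1 bp coordinate deduplication, and an exact
  enumeration of the per-column consensus error probability.
* **`rcakit.errors`** — the substitution error-rate protocol
  (germline masking, MAPQ ≥ 60, non-overlapping 400,000-read
  subsample; mismatches excluding indels / mapped length) and Phred
  conversions.
* **`rcakit.snv`** — allele counting (REF/MUT/ERR), real-time
  cumulative MUT-ratio tracking, Fisher enrichment testing, and a
  Monte Carlo tumor-fraction estimator: a tumor-derived read at site
  *i* is mutant with probability *P*ᵢ = purity × VAF*ᵢ*; TF is found by
  grid search over simulated MUT-count distributions, with a 95% CI
  from the alignment profile and a fine log-grid refinement below
  TF = 0.05.
* **`rcakit.fragments`** — fragment-length profiles on 30–220 bp and a
  fixed-signature NMF decomposition: TF = w₂/(w₁+w₂) for nonnegative
  weights of a healthy and a tumor length signature, capped at 1.0.
* **`rcakit.lod`** — limit-of-detection simulation across platform
  presets (MinION/PromethION × raw/consensus), with detection
  thresholds calibrated to >68% true-negative rate and LoD defined by
  >95% true-positive rate.
* **`rcakit.io`** — VCF panels (pysam), FASTQ consensus reads
  (Biopython), TSV tables, YAML run configs; plus a `rcakit` CLI with
  `simulate`, `consensus`, `error-rate`, `tf-snv`, `tf-frag`, `lod`
  and `admix` subcommands.

See `docs/methods.md` for the models, assumptions and numerical
choices.

## Worked example

```python
import numpy as np
from rcakit import synth, snv, fragments as frg, lod

# A tumor-informed panel and a cfDNA sample at true TF = 0.10.
panel = synth.generate_variant_panel(n_sites=120, vaf_mean=0.3, purity=0.8, seed=7)
obs = synth.generate_allele_observations(panel, tf=0.10, coverage=25,
                                         error_rate=0.00072, seed=8)
counts = snv.count_alleles(obs, panel)
print(counts)
est = snv.estimate_tf_snv(counts, panel, error_rate=0.00072, seed=9)
print(f"SNV TF = {est.tf_point:.3f} (95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")

# Fragmentomics on the same sample's length distribution.
model = synth.FragmentLengthModel(periodicity_amp=0.5)
lengths = synth.generate_fragment_lengths(100_000, model, tumor_fraction=0.10, seed=10)
tf_frag = frg.nmf_tf(frg.build_length_profile(lengths), frg.default_signatures())
print(f"fragmentomics TF = {tf_frag:.3f}")

# How low can each platform go on a 5,000-site panel?
p5k = synth.generate_variant_panel(5000, vaf_mean=0.3, vaf_sd=0.0, purity=1.0, seed=11)
for name in ("raw-minion", "consensus-promethion"):
    r = lod.run_lod(p5k, lod.PRESETS[name], n_trials=2000, seed=12)
    print(name, "LoD =", round(r.lowest_detectable_tf, 4))
```

Output:

```
AlleleCounts(n_ref=2909, n_mut=61, n_err=1)
SNV TF = 0.081 (95% CI 0.071-0.101)
fragmentomics TF = 0.100
raw-minion LoD = 0.0146
consensus-promethion LoD = 0.0036
```

Of 2,971 reads overlapping panel sites, 61 carry the tumor allele
(about 2%); given mean purity × VAF ≈ 0.24, the estimator places the
TF near 0.08 with the truth (0.10) inside the confidence interval.
The fragmentomics decomposition recovers the 10% tumor admixture from
the length profile alone.  In the LoD simulation the consensus
PromethION preset (0.8× at Q31) detects tumor fractions four times
lower than raw MinION reads (0.25× at Q21): both error rate and
throughput matter.

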