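# Methods

This note documents the statistical models, the synthetic-data generator,
and the design choices behind `helptag-dm`, in the order the pipeline runs.

## Scoring model

A two-enzyme tag-count experiment yields, for each CCGG locus and sample, a
HpaII (methylation-sensitive) count and an MspI (methylation-insensitive)
count. The MspI signal is methylation-independent, so the package pools
MspI counts across all samples into a per-locus reference density —
mirroring the practice of scoring HpaII libraries against a pre-built MspI
reference — and scores each sample as

    score = 100 * min(1, (hpaii / hpaii_library_total) / (mspi_ref / mspi_ref_total))

Library totals are the sample's full sequencing totals, not the column
sums of tabulated loci, so the score is an unbiased density ratio. The
ratio is clipped at 1 because sampling noise lets HpaII density exceed the
reference; the score scale is bounded by construction (0 = fully
methylated, 100 = unmethylated). Loci with zero reference coverage are
unscorable and reported as missing.

### Confidence and filtering

No closed form exists in the literature for the confidence of a two-enzyme
score, beyond the requirement that it grow with both enzymes' read depth.
The package uses

    confidence = (mspi_ref / mspi_ref_total) * mean_library_total
                 * (1 - exp(-(hpaii + mspi_ref)))

which is monotone non-decreasing in both counts: the first factor is the
reference density (the dominant depth term), the exponential damping
penalizes loci where both counts are near zero. A locus is excluded from
between-group comparisons when any sample's confidence falls below
`threshold_factor` (default 0.5) times the locus's expected confidence,
defined as the across-sample mean at that locus; a global-mean variant is
available (`per_locus=False`). The per-locus rule is idempotent: filtering
a filtered matrix changes nothing.

Sample-level QC targets zero-inflated libraries (failed digests or
low-complexity libraries produce an overrepresentation of zero scores): a
sample is flagged when its zero-score fraction exceeds the across-sample
median by more than 3 robust MADs. A MAD rule was chosen over a fixed
cutoff because the natural zero fraction depends on the methylome's
baseline distribution.

## Differential testing

Per locus, a pooled-variance two-sided t-test compares an exposed group to
control (the classical `rowttests` formulation; Welch is available via
`welch=True`). `delta` is exposed-minus-control mean score, so `delta < 0`
means hypermethylation. Loci with fewer than two values per group, or with
zero variance and equal means, are flagged untestable rather than dropped.

Candidates ("loci of interest") require strictly `|delta| > 30` **and**
`p < 0.005`. Direction enrichment among candidates is a two-sided Fisher
exact test on {candidate, non-candidate} x {hyper, hypo}; a zero cell in
the candidate row yields an infinite odds ratio by the documented
convention.

### Permutation correction

Group labels are permuted across the pooled samples `n_perm = 400` times
(the identity assignment is included once as the first draw, so the
observed p-values are reproduced by construction). The per-locus permuted
p-values are pooled into a single distribution: with only 400 permutations
a per-locus null cannot resolve p < 0.005, while the pooled distribution
is estimated from n_perm x n_loci values. A candidate is
corrected-significant when its observed p lies at or below the 2.5th
percentile of the pooled distribution — more extreme than 97.5% of
permuted values, a two-tailed 5% criterion. On pure-null data ~2.5% of
loci fall below the threshold, and on spiked data every candidate
(p < 0.005 « threshold ≈ 0.024) survives. The correction can only demote:
non-candidates are never promoted.

### Power calibration

`power_simulation` draws `n_sim` two-group normal datasets (means
differing by `delta`, common `sd`) and reports the rejection fraction of
the pooled t-test at level `alpha`, with the binomial Monte-Carlo SE. The
exact counterpart is the noncentral-t tail probability with
`df = n_a + n_b - 2` and `ncp = delta / (sd * sqrt(1/n_a + 1/n_b))`.

At the stated design (5 per group, sd 10, delta 30, alpha 0.005) the
analytic power is **0.7747** (df 8, ncp 4.743) — marginally below the
often-quoted 80% — while the study-realistic 5 vs 6 design gives
**0.8498** (df 9, ncp 4.954). The package therefore reports both; the
acceptance script emits the 5v5 simulation as the headline value with the
5v6 value alongside.

## DMR calling

A DMR is a maximal run of candidate loci that are consecutive in the
ordering of all testable loci, with adjacent locus starts at most
`max_gap = 10000` bp apart, uniform direction of change, and at least
`min_loci = 4` members; coordinates span first-member start to last-member
end (0-based half-open). Interpretation choices, all configurable:

- *Consecutive* is read literally: a tested-but-non-candidate locus
  between two candidates breaks the run (`break_on_noncandidate=False`
  gives a gap-only mode). Untestable loci never break runs.
- Direction uniformity is required (`require_uniform_direction=False`
  relaxes it); a direction flip starts a new run at the flipping locus.
- Input must arrive coordinate-sorted; the caller is never silently
  re-sorted.

All break conditions are pairwise-adjacent, so maximal runs are well
defined and a linear scan finds exactly the maximal valid windows. An
independent exhaustive enumerator (`dmr_oracle`) checks every contiguous
window for validity and maximality; equivalence is asserted on thousands
of randomized fixtures in the test suite.

## Gene mapping

Windows run from `upstream` (10 kb) before the TSS to `downstream` (10 kb)
past the TES in transcription orientation, clipped at the chromosome
start; `mode="methods"` sets the downstream extension to zero (window ends
at the gene body). Overlap is half-open; a locus maps to **every** gene
whose window overlaps it (multi-mapping allowed), and a DMR maps through
its member loci. Internally all coordinates are BED-style 0-based
half-open; GTF is converted on read/write. The overlap engine is a
binary-search sweep over start-sorted tracks, validated against an
all-pairs brute-force scan in tests.

## Enrichment with site-count bias correction

Genes carrying more assayed HpaII sites are more likely to contain a
candidate locus by chance alone. The correction estimates
P(differentially methylated | site count) by quantile-binning the
universe's site counts (default 10 bins; rank-based binning so ties cannot
collapse the binning) and assigns each gene its bin's empirical DM rate as
a sampling weight, floored at a pseudo-rate of 0.5/|universe| so no gene is
unsampleable. A spline-based weighting function would add nothing at this
scale; binned rates preserve the bias-removal intent and are directly
testable. With no site-count variation the weights degrade to uniform with
a warning.

Null draws take |DM| genes from the universe without replacement with
probability proportional to the weights, via the Gumbel top-k trick
(equivalent to sequential weighted sampling without replacement, and
vectorizable). Tail probabilities use the add-one estimator

    p_over  = (1 + #{draws with overlap >= observed}) / (n_samples + 1)

and analogously `p_under` with <=, so the smallest attainable p is
1/(n_samples+1) and both tails include the observed value (hence
p_over + p_under >= 1). With uniform weights the sampled tails converge to
the closed-form hypergeometric tails, which serve as the test oracle. No
multiple-testing correction is applied across sets; raw enrichment
p-values are reported. `enrich_all` shares one sampling pass across sets
for efficiency; this leaves each set's p-values within Monte-Carlo
tolerance of independent runs.

## Expression (2^-ΔΔCt)

Per animal, replicate Ct values are averaged per gene (no outlier
rejection by default; a configurable warning flags replicate spreads above
a given cycle count), the reference gene's mean Ct is subtracted (ΔCt),
and the calibrator group's mean ΔCt subtracted again (ΔΔCt);
fold = 2^-ΔΔCt. Because the arithmetic mean of per-animal folds exceeds 1
for the calibrator group itself (Jensen's inequality), the group-level
fold is reported as 2^-mean(ΔΔCt) — the geometric-mean fold, which pins
the calibrator at exactly 1 — while the SEM is taken over per-animal folds
and per-animal values are also emitted. Group testing (one-way ANOVA, then
Tukey's HSD via the studentized range) runs on the ΔCt/ΔΔCt scale, where
normality is far more defensible than on the exponentiated fold scale;
folds are reported on the 2^-ΔΔCt scale.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for recovery testing. What it models:

- **Loci**: exponential inter-locus gaps with mean 2000 bp (the average
  CCGG spacing in a mammalian genome), 4-bp sites, multiple chromosomes.
- **Groups**: Con (n=5), UN (n=6), ON (n=5), Old (n=6) by default.
- **Baseline methylation**: a two-component mixture centred at scores 15
  and 85 (CpG-like bimodality: most sites are either strongly methylated
  or unmethylated), jitter SD 5.
- **Counts**: per-locus reference depth is negative-binomial across loci
  (mean 800, dispersion 5 — over-dispersion typical of tag counting);
  MspI counts are Poisson around depth x library-size factor; HpaII counts
  are Poisson with expectation scaled by the sample's realized score.
  Sample library totals are drawn uniformly from `library_size_range`.
  The default depth keeps counting noise (~2-3 score units at mid-scale)
  well below the biological SD; depth is a free knob, not a literature
  value.
- **Effects**: spiked loci shift the group mean by ±`effect_size` (30);
  UN spikes are hypermethylating (score decrease), Old hypomethylating,
  ON mixed with no net shift. Spiked-locus baselines are (re)drawn inside
  bands that keep both the baseline and the shifted mean ≥ ~1.5 noise SDs
  from the scale boundaries — a 30-point shift is only physically
  realizable at mid-scale loci on a bounded scale, and without this the
  clipping would silently attenuate the designed effect and SD.
- **DMR blocks**: per exposed group, `n_dmr_blocks` runs of
  `dmr_block_span` (≥4) consecutive loci with adjacent gaps ≤ 10 kb,
  spiked with one direction per block.
- **Shared spikes**: `n_shared_spikes` loci spiked in *every* exposed
  group, supporting overlap bookkeeping across comparisons.
- **Per-sample scores**: group mean + normal noise of SD `score_sd` (10),
  clipped to [0,100].
- **Zero inflation**: an optional named sample has a fraction (default
  0.35) of its HpaII counts zeroed, emulating a failed library for QC
  testing.
- **Annotation**: non-overlapping genes with log-uniform lengths
  (2-100 kb) so per-gene site counts span over an order of magnitude —
  the bias the enrichment stage corrects. Gene sets are random subsets.
- **Ct tables**: target Ct = baseline − log2(group fold) + plate and
  replicate noise; the reference gene has fold 1 everywhere; triplicates
  per animal. Default target folds (10x/4x/6x in UN/ON/Old) exercise a
  strongly regulated gene.

What it does **not** model, and hence what passing tests do not show about
real data: read-level artifacts (adapters, mapping bias, PCR duplicates),
locus-specific enzyme efficiency, batch effects, correlated methylation
between nearby loci outside spiked blocks, cell-composition drift between
groups, and biological fold variation between animals in the qPCR stage
beyond plate/replicate noise.

## Numerical and procedural choices

- All randomness flows through `numpy.random.Generator` seeded from
  configuration; pipeline stages derive per-stage seeds from the run seed
  by fixed offsets so removing a stage never perturbs another stage's
  stream (stage isolation is asserted in tests).
- Candidate gates are strict inequalities; boundary values are excluded.
- The candidate list is sorted by p, ties broken by larger |delta|.
- Fisher's exact test, t and noncentral-t distributions, hierarchical
  clustering (Euclidean distance, average linkage) come from scipy;
  Tukey's HSD from statsmodels.
- Degenerate inputs fail loudly: unsorted DMR input, empty post-filter
  matrices, all-zero libraries, missing reference genes, zero-variance
  ANOVA all raise typed errors rather than returning silent results.
- Test problem sizes: the recovery and type-I-error checks run at
  100,000 loci (matching the default simulation scale); DMR and
  enrichment oracle equivalences run on 1,000 and 20 randomized
  configurations respectively.

## Known limitations

- The confidence formula is a principled reconstruction (monotone in both
  enzymes' depth with a per-locus adaptive threshold), not a published
  form; at deep coverage it filters almost nothing, which is the intended
  behaviour but means the filter's realism is untested against shallow
  real libraries.
- The pooled permutation null assumes exchangeability of samples across
  the two groups under the null; unmodelled batch structure would break
  it.
- The run-based DMR definition carries no region-level error control;
  DMR p-values are the minimum member p, for ranking only.
- Enrichment p-values are raw (no across-set correction), matching the
  reporting convention of the emulated workflow.
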