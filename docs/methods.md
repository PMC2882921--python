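# Methods

## Data model and preprocessing

The pipeline consumes MAS5/GCOS-style condensed microarray data: a probe-set
× sample matrix of non-negative signals and a parallel matrix of detection
calls (`P`resent / `M`arginal / `A`bsent), plus one population label per
sample drawn from {MB, PPC, BMPC, MMC, WBM, CD3, CD14, PMN, BMSC, OC}.
Matrices are reconciled by identifier, never by position, so every result is
invariant to row or column permutations of the input files.

Each sample is scaled so that its mean signal equals `scale_target`
(default 100, arbitrary scanner units), after which values below
`signal_floor` (default 1) are raised to the floor.  The scaling statistic is
the plain arithmetic mean; a symmetric `trim_fraction` is available for data
conditioned like MAS5 trimmed means.  Scaling precedes flooring because
flooring first would bias the mean.  Scaling is idempotent wherever the floor
is inactive; when flooring does raise values, the per-sample mean ends up
marginally above the target, which is the standard behaviour of this kind of
normalisation.

A probe set is **non-informative** when its not-present fraction across all
samples is at least `noninformative_absent_frac` (default 0.95).  Marginal
calls count as not-present throughout (conservative; the published analysis
speaks only of present/absent).  This screen is a *catalog curation* step:
the shipped 51-gene catalog already reflects it, and the classification run
does not re-apply it by default — a weakly expressed gene must stay in the
analysis to be classifiable as not-expressed.  (`informative_probesets`
applies only the absent-fraction rule; no separate intensity cut-off is
layered on top, since the absent calls already encode low signal.)

When several probe sets interrogate one gene, the representative is the one
with the highest present-call fraction over all samples; ties (including the
all-present case) go to the higher signal variance, and any remaining tie to
the lexicographically smallest probe identifier, so selection is
deterministic.

## Contrast engine

A contrast compares two disjoint sample groups (each ≥ 2 samples, never
containing whole-bone-marrow samples, which mix tumor and environment cells).
Per gene it computes:

* a two-sided Student t-test with pooled variance on **log2** signal
  (log-scale testing stabilises the variance of MAS5-like intensities, and
  the floor at 1 makes the logarithm well defined); Welch and linear-scale
  variants are configuration options.  Degenerate inputs follow a fixed
  convention: zero pooled variance with equal means gives (t = 0, p = 1),
  with unequal means (t = ±∞, p = 0).
* Benjamini–Hochberg step-up adjustment (via
  `statsmodels.stats.multitest.multipletests`) across exactly the genes of
  the contrast — each supervised comparison is its own multiple-testing
  family, mirroring how the supervised analyses are run separately.
* the fold change as the ratio of **linear-scale group means** (medians are
  reported alongside).  Whether published fold changes are ratios of means
  or medians is not decidable from the text; means are consistent with the
  printed examples and make the swap symmetry exact (swapping groups maps
  FC to 1/FC and negates t).
* `significant_over_b` = (p_adj ≤ α) ∧ (FC ≥ min fold change) ∧ ¬(100%
  absent calls in the winning group).  Defaults: α = 0.05, fold ≥ 2.

## Rule cascade

Each gene receives exactly one category; the first matching rule wins, and
the evidence (the supporting contrasts) is recorded:

1. **NOT_EXPRESSED** — presence < 5% in tumor cells and in each marrow
   subpopulation (CD3/CD14/PMN), and zero present calls in stromal cells and
   osteoclasts.  "Not expressed" in the niche populations is implemented as
   strictly zero presence (stronger than < 5%), configurable.  This rule
   precedes the significance rules: a gene below the presence floor cannot
   be classified by contrasts.
2. **MYELOMA** — tumor cells significant over each of CD3, CD14, PMN, BMSC
   and OC (a conjunction of five contrasts).
3. **NICHE_BMSC / NICHE_OC** — the niche population significant over tumor
   cells and the three marrow subpopulations.  The two niche populations are
   *not* contrasted against each other by default (matching how the niche
   comparisons are defined); `require_niche_cross_contrast` adds that
   requirement.  BMSC is evaluated before OC, a fixed order that matters only
   if both rules fire.
4. **ENVIRONMENT** — at least one marrow subpopulation significant over
   tumor cells, stromal cells and osteoclasts; subpopulations are evaluated
   in the fixed order CD3, CD14, PMN and the first winner is recorded.
   Niche is checked before environment; on data where a gene satisfied both,
   the cascade order decides.
5. **MYELOMA_RESCUED** — presence in tumor cells above
   `rescue_min_present_frac` (default 0, i.e. at least one present call)
   with zero present calls in every other population.  "Some of the tumor
   samples" is not quantified in the source; at-least-one is the default and
   the threshold is exposed.
6. **SHARED** — the explicit residual: expressed in tumor cells and at least
   one environment population without a significant winner.

No rule models the published "probe sets without signal change between
present and absent calls" caveat; that distinction is a probe-quality
judgement, not an expression rule.

## Differentiation analysis

Three contrasts per gene: memory B cells vs pooled plasmablasts + normal
bone-marrow plasma cells; plasmablasts vs normal plasma cells; tumor cells
vs normal plasma cells.  Direction is `up_in_first` / `up_in_second` when the
corresponding one-sided reading of the contrast is significant under the same
α/fold/absent-call rules, else `none`.  A gene is **aberrantly expressed** in
tumor cells when it is absent in every normal plasma-cell sample yet present
in more than 10% (strict) of tumor samples.

## Receptor summary

Per receptor, over tumor-cell samples only: median signal, (min, max) range,
and the present-call percentage rounded half-up to an integer.  Bucket
counting over that percentage reproduces the published headline statements;
"at least half the patients" is implemented as ≥ 50 because the printed
accounting includes a receptor at exactly 50%, and "more than 90%" as
90 < p < 99 because the 99% and 100% receptors are counted in their own
statements.  The packaged transcription of the published table is verbatim:
one printed median (ErbB3) lies outside its printed range, and three
presence cells blurred by the table rendering are stored as unknown and
excluded (and counted separately) by the bucket operations.  Computed rows
are validated against the median-within-range invariant; the verbatim
transcription is not.

## Synthetic data generator

The generator emulates the study design so every stage is testable offline:

* **Sample sizes** (defaults): 131 tumor-cell samples; 5 each of CD3, CD14,
  PMN and stromal-cell samples; 7 osteoclast samples; 6 memory-B, 7
  plasmablast and 7 normal plasma-cell samples; whole-bone-marrow samples
  (a 0.3 tumor / 0.7 environment mixture by default) only on request, since
  their only role is to be excluded.
* **Signals**: log-normal, 2^N(μ, 0.5²) with μ = log2(100) for expressing
  populations, +log2(8) for the planted winner population, −5 for silent
  populations.  The log-normal/log2-t pairing makes the test well calibrated
  by construction; calibration itself is checked under the null.
* **Detection calls**: Bernoulli, present with probability 0.95 (expressing)
  / 0.02 (silent), independent of the drawn signal so that presence rates
  are exactly controllable in property tests; a signal-linked option
  (present iff signal ≥ threshold) exists for realism.
* **Background block**: 2,000 ubiquitously expressed probe sets stand in for
  the tens of thousands of other genes on a real chip.  They anchor the
  per-sample scaling; without them the planted genes themselves dominate the
  sample means and scaling compresses the planted folds (samples of the
  population with many elevated genes would be shrunk).
* **Decoy probe sets**: genes may carry extra probe sets with halved
  presence probability, exercising the probe-selection rule.
* The default planted panel has 51 genes mirroring the study's headline
  accounting: 3 tumor-compartment, 11 stromal-niche, 3 osteoclast-niche, 8
  environment (with the published winner populations), 9 silent, 5
  rescue-class and 12 shared genes.

Everything is reproducible from a single integer seed.

**What passing recovery tests do and do not show.**  Categories decided by
planted significance (MYELOMA, NICHE_*, ENVIRONMENT) are recovered
essentially always at the default effect size.  Categories decided by strict
zero-presence rules are intrinsically noise-limited: with a 2% spurious
present-call rate, the probability that all 27 silent environment samples
are absent is 0.98²⁷ ≈ 0.58, so NOT_EXPRESSED and MYELOMA_RESCUED recall
sit near 0.6–0.8 and 0.2–0.6 respectively, and the genes drift into SHARED.
This is a property of the published rules under call noise, not an
implementation defect; the recovery report's per-category recall makes it
visible, and the headline recovery metric is the mean recall over the five
categories driven by planted signal or silence.  The generator also does not
emulate real-data features such as probe-level saturation, correlated
calls/signals (unless the signal-linked option is on), batch effects or
patient heterogeneity, so passing tests demonstrate correctness of the
pipeline's logic, not performance on real arrays.

## Problem sizes used in checks

The shipped checks run the full study-shaped design: 20 generator seeds for
planted-category recovery and 200 seeds for the global-null false-positive
rate (51 genes, 131-vs-5 contrast), which completes in well under a minute
on one CPU.

## Known limitations

* The exact published gene memberships (supplementary tables) require the
  deposited accession data and are out of scope; the package reproduces the
  printed catalog counts and receptor buckets, and the procedure itself.
* MAS5/GCOS condensation, CEL parsing, and repository queries are out of
  scope; calls are inputs.
* Two printed bucket claims for the receptor table (14/36 between 10 and
  50%, 4/36 below 10%) cannot be reconciled with the rendered table and are
  not asserted anywhere.
* The t-test assumes approximate log-normality within populations; no
  moderated (empirical-Bayes) variance shrinkage is provided, which matters
  for 5-vs-5 contrasts on real data.
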