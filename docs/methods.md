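# Methods

## Overview

`cansplice` implements a screen-and-characterize workflow for
cancer-associated alternative splicing (AS).  The input is a per-cancer
matrix of PSI (Percent Spliced In) values — the fraction of a gene's
transcripts that include an alternative region — over AS events of four
geometries: skipped exon (SE), retained intron (RI), and alternative 3'/5'
splice sites (A3SS/A5SS).  PSI estimation itself (read alignment, isoform
inference) is out of scope; matrices arrive as TSV with explicit missing
values for events not quantifiable in a sample.

## Differential-splicing screen

An event is called significant in a cancer type when all three criteria
hold:

1. **Detection** — a PSI estimate in at least `min_detected` (default 10)
   tumor and 10 normal samples.  Detection means a non-missing PSI value;
   whether both isoforms were observable is the upstream estimator's
   responsibility.
2. **Distributional difference** — two-sided Welch t-test p < 0.05 on the
   non-missing PSI values.  The unequal-variance form is deliberate: tumor
   PSI variance is systematically inflated relative to normal tissue (see
   the variability analysis), which violates the pooled-variance
   assumption.  Whether a pooled or Welch test, one- or two-sided, is the
   "right" convention is genuinely open; two-sided Welch is the
   conservative and assumption-light choice.
3. **Effect size** — |ΔPSI| > 0.1, where ΔPSI = mean(tumor) − mean(normal).

p-values are uncorrected by design: the cross-cancer intersection is the
specificity device (an event must pass in every cancer independently).  A
Benjamini–Hochberg flag exists for single-cancer use.  Degenerate events
(both groups constant and equal) get p = 1 — no evidence, rather than an
error.

## Cross-cancer core set and its null

The core set is the intersection of per-cancer significant sets on event
identity.  Its size is benchmarked against a permutation null: each of
`n_replicates` (default 1000) replicates draws, per cancer, a uniform
random subset of that cancer's *detectable* events (those passing criterion
1) with the same size as that cancer's significant set, and counts the
k-way intersection.  Significance is the rank p with pseudo-count,
(#{replicates ≥ observed} + 1) / (R + 1), so the minimal attainable p is
1/(R+1).  On a shared universe of size N the expected overlap has the
product form N·∏(nᵢ/N), which the test suite verifies within Monte-Carlo
error.

Direction consistency asks whether the sign of ΔPSI agrees in every cancer;
an exact zero in any cancer counts as inconsistent (with a warning).
Overlap between core genes and a user-supplied list of frequently mutated
cancer genes is a hypergeometric upper tail; the gene universe size is an
explicit argument because no single "number of genes" is canonical.

## Sequence features (SE events)

* **Phase**: alternative-exon length mod 3; phase 0 preserves the
  downstream reading frame when the exon is toggled.  Enrichment of phase-0
  exons in the core set versus control SEs is a one-sided Fisher exact test
  on the 2×2 (phase-0 vs not) × (core vs control) table.
* **Conservation meta-profile**: per-position mean of a phastCons-like
  per-base score over four windows — 150-nt upstream intron, first and last
  50 nt of the exon, 150-nt downstream intron — in transcript orientation
  (minus-strand windows reversed).  Window widths follow common practice
  for mapping splicing-regulatory elements and are parameters; nothing
  downstream depends on the exact widths.
* **5-mer enrichment**: every overlapping 5-nt word (stride 1) is counted
  in target windows (200-nt intronic flanks plus the exon) and in control
  windows around non-core SEs.  With p_w the background frequency and N the
  total number of valid target windows, E_w = p_w·N and
  Z_w = (O_w − E_w)/√(E_w(1−p_w)) — a binomial approximation.  Words with
  E_w = 0 are reported with missing Z.  Windows containing non-ACGT
  characters are skipped.
* **Motif clustering**: 5-mers with Z > 2.5 are single-linkage clustered,
  linking two words when some offset in {−1, 0, +1} aligns ≥ 4 identical
  positions; the cluster consensus is the per-position majority over
  members aligned to the highest-Z seed, with IUPAC degenerate codes on
  ties.  This replaces an external multiple-alignment step with a
  self-contained rule that preserves the intent (grouping shift-related
  words into one candidate motif).

## PSI variability with matched controls

Mean PSI mechanically bounds PSI variance (a ratio near 0 or 1 cannot
vary), so SD comparisons must control for the mean.  Controls are sampled
to match the target set's mean-PSI histogram: events are binned by mean PSI
(over the same samples, both conditions pooled) into `n_bins` (default 20)
equal-width bins, and controls are drawn without replacement bin-by-bin
with exactly the target's counts — the binned histograms are identical by
construction.  A bin with too few candidates raises an error naming the
deficient bins; the remediation is fewer bins.

SD comparisons (target vs control per condition; tumor vs normal within the
target set) use one-sided Mann–Whitney U on the per-event SDs — a rank test
avoids distributional assumptions on SDs.  The exact null distribution is
used when both sides have ≤ 30 events, the normal approximation otherwise.
One calibration caveat: in the tumor-vs-normal comparison the two SD
samples come from the *same* events and are positively correlated, which
makes the unpaired test conservative (observed null rejection ≈ 1–4% at
α = 5%).  It never overstates significance.

## PCA classification

Samples are vectors of core-event PSI.  Missing values are mean-imputed per
event (the imputed fraction is reported per event), columns are centered
but not scaled — PSI already shares the [0, 1] scale — and the
decomposition is a plain SVD.  Component signs are fixed by making each
component's largest-magnitude loading positive, so outputs are reproducible
across BLAS implementations.  Group separation on the first two components
is quantified with silhouette scores and centroid distances rather than by
eye.

## Survival screen

Patients with survival annotation are split per event at the median PSI
(ties to the low group; the quantile is a parameter — no canonical cut
point exists for "high vs low" inclusion) and compared with the standard
1-df log-rank test: observed vs hypergeometric-expected deaths per distinct
death time, chi-square = (O−E)²/V.  Events whose split leaves fewer than 5
patients on a side are skipped.  Both the product-limit estimator and the
log-rank statistic are implemented directly for speed (the replicate-based
calibration runs thousands of event-level tests); the test suite verifies
both against lifelines to 1e-8.

## Correlation screen for candidate regulators

Every (core event, gene) pair is tested with tie-corrected Spearman rank
correlation on pairwise-complete samples (≥ 30 required), pooling samples
across cancers.  Pairs with |ρ| ≥ 0.4 and p ≤ 0.005 (two-sided
t-approximation, uncorrected) count as highly correlated; genes correlated
with strictly more than 30 core events ("more than 30" read strictly) are
reported as regulator candidates.  The screen is vectorized: per event, the
expression matrix restricted to that event's non-missing samples is
rank-transformed once and all gene correlations come from one matrix
product, so the full screen (≈150 events × 2000 genes × 240 samples) takes
seconds.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
every planted feature recorded for parameter-recovery testing:

* **PSI**: Beta(μκ, (1−μ)κ).  κ (default 100) controls spread; tumor
  variance inflation divides κ (default factor 4) for planted events.
  Background events draw μ per event *and* per cancer from U(0.05, 0.95) —
  independent baselines across cancers model tissue-specific splicing, the
  main noise source the cross-cancer design exists to remove.  Planted
  events draw baselines from U(0.15, 0.85) so the planted shift
  (±δ, default 0.25, tumor mean clamped to [0.02, 0.98]) is actually
  realized rather than absorbed by the clamp.  Cells go missing i.i.d.
  (default rate 0.10).
* **Planted structure**: 150 shared events (directions consistent across
  cancers for 85%, one cancer sign-flipped for the rest; RI directions
  biased 80% toward intron retention), plus 50 cancer-specific events per
  cancer.  Planted-event counts are allocated across modes proportionally.
* **Expression / regulators**: log2 expression is Gaussian per gene
  (log-normal on the natural scale).  Each planted regulator couples to the
  direction-aligned mean PSI of a 40-event subset of the planted shared
  events (aligning by direction is essential: the raw mean of a
  mixed-direction subset cancels the shared tumor/normal component).  The
  signal-to-noise mixing weight is calibrated by bisection on the realized
  vectors so the regulator-signal Spearman correlation meets the configured
  coupling (default 0.6) — the analytic Gaussian-copula relation
  under-delivers because the signal is a tumor/normal mixture.
* **Survival**: tumor samples get exponential survival with log-hazard
  linear in each coupled event's PSI, standardized within cancer and scaled
  by 0.7 per tumor-PSI SD (hazard ratio ≈ 2 per SD — a strong prognostic
  biomarker, chosen by an a-priori power calculation for ~65 deaths).
  Independent exponential censoring yields ~30% censoring.
* **Sequences / conservation**: each event sits on its own contig with
  200-nt flanks.  Flank sequence is i.i.d. uniform; planted shared SE
  events receive Poisson(3) extra copies of the planted 5-mer (default
  TGTGT) in their flanks.  Conservation is Beta(1,3) noise, replaced by
  Beta(5,1) (mean ≈ 0.83) across planted windows.
* **Phase**: alternative-exon lengths are adjusted so the phase-0 fraction
  is 0.53 for planted shared events and 0.42 for background.
* **Subtypes**: tumors of the first cancer split into two subtypes; one
  subtype receives an extra +0.15 shift on 50 planted events.

One global seed drives everything through deterministically spawned child
streams; identical config + seed gives byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level noise and coverage-dependent PSI
uncertainty (PSI is drawn directly, not inferred), correlated event
structure within genes, batch effects, non-exponential survival, real
splice-site sequence composition, and realistic linkage between expression
and splicing beyond the planted regulators.  Recovery rates on the
synthetic cohort are upper bounds on real-data performance.

## Problem sizes and defaults

The default synthetic study is 3 cancers × (40 tumor + 40 normal) samples,
2800 events (2000 SE), 2000 genes, 240 samples pooled — large enough that
every calibration band is meaningful and the full acceptance run completes
in about a minute on one CPU.  Replicate-based checks (variance-inflation
power, survival power and calibration) use 100 seeded replicates of reduced
single-cancer cohorts.

## Numerical choices and degenerate inputs

* Welch p on zero-variance identical groups = 1; differing constant groups
  = 0.
* Rank-p pseudo-count convention throughout permutation tests.
* Median split sends ties to the low-PSI group; deterministic given the
  vector.
* Spearman pairs with a constant vector are skipped (ρ undefined).
* Mean imputation for PSI missingness in PCA only; all test statistics use
  complete or pairwise-complete observations, never imputed values.
* The Fisher test, hypergeometric tail, Mann–Whitney and t distributions
  come from scipy; exact-enumeration oracles in the test suite pin the
  Fisher/hypergeometric tails to ≤1e-12.

## Known limitations

* The screen tests events independently; no shrinkage or sharing across
  events.
* The matched-control sampler matches marginal mean PSI only, not the
  joint (mean, missingness) distribution.
* The log-rank screen is univariate; no adjustment for clinical
  covariates.
* The permutation null treats events as exchangeable within a cancer's
  detectable universe; structured detectability (e.g. expression-linked)
  would narrow the null.
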