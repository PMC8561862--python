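# Methods

This note documents the models and numerical choices behind `gutload`: the
measurement chain that converts dPCR + amplicon data into absolute taxon
loads, the analysis operations built on top of it, and the synthetic
cohort generator that the test suite and acceptance script exercise.

## Measurement chain

**Total load.** A dPCR record carries the reaction concentration
(copies/µL), the dilution factor applied to the extract, the elution
volume of the extract (µL, default 100), and the collected sample volume
(mL). The total load is `C · d · V_e / V_s` copies/mL. Missing collected
volumes are imputed with the arithmetic mean of the non-missing volumes of
the same sample type (duodenum, saliva, blank) and flagged; imputation can
mis-scale an individual sample's load by up to ~4× (the spread of observed
duodenal collection volumes), which is small against the ~5 orders of
magnitude the loads span.

**Blank filter.** Water blanks measure the reagent/contamination floor.
The exclusion threshold is the upper bound of a 95% interval on the log₁₀
blank loads, `10^(mean + 1.96·SD)` with the population SD (the two-point
closed form `10^(3.5 + 1.96·0.5)` for blanks {10³, 10⁴} is the reference
case). Samples at or below the threshold are dropped; the comparison is
strict (`load > threshold` passes).

**Limit of detection.** Sequencing involves two Poisson sampling steps.
(1) Library input: a taxon is reliably detected when ≈3 copies enter the
library reaction, since P(X ≥ 1 | λ = 3) = 1 − e⁻³ ≈ 0.95; the
corresponding relative abundance is `3 / (extract copies/µL × template
µL)` with a 3.5 µL template default. Zero-input samples saturate at LOD 1
and are flagged. (2) Read depth: the empirical power law
`7.115 · depth^−0.115`. Its raw value at common rarefaction depths
(≈2.07 at 45,386 reads) exceeds 1 and is therefore interpreted as a
percentage and divided by 100; this is the only interpretation that keeps
the filter non-degenerate, and a `lod_depth_units` switch preserves the
raw-fraction reading for sensitivity analyses. The effective LOD is the
minimum of the two. Filtering zeroes entries whose relative abundance is
*strictly* below the effective LOD; relative abundance is always taken
against the sample's anchored total load (not the filtered row sum), which
makes the filter idempotent. Filtering happens at the resolution of the
input table; genus-level tables are filtered at genus level.

**Rarefaction.** Multivariate hypergeometric subsampling (without
replacement) to the minimum sample depth by default, one draw per sample
from a single seeded generator; the seed is recorded in the run manifest.

**qPCR.** Cq values convert to copies/µL through a single-point anchor
(Cq 22.4 = 1000 copies/µL) with perfect-efficiency doubling by default;
amplification efficiency is a parameter. "No amplification" within the
40-cycle run maps to zero. Marker-gene loads divide by the rRNA operon
copy number to reach genomes/mL (8 copies/genome for Enterobacteriaceae
16S, 1 for the single-copy citrate-synthase gene), putting the two assays
on a common scale.

## Analysis operations

* **Load distribution.** `fit_lognormal` reports the sample mean and SD
  (n−1) of log₁₀ loads; `qq_points` places sorted data against normal
  quantiles at positions (i − 0.5)/n using the fitted parameters, so
  normal data sits on y = x.
* **Diversity and anaerobe partition.** Shannon entropy uses natural log
  (base-2 available). The partition sums loads by curated oxygen class
  (strict anaerobe / facultative anaerobe / aerobe / unknown; unknowns are
  excluded and reported). Companion correlations (log₁₀ strict vs log₁₀
  facultative with a pseudo-load of 1 copy/mL to admit zeros; fraction
  strict vs Shannon) are reported on both scales.
* **Disruptor ranking.** `max − mean` per taxon on linear copies/mL: a
  taxon present once at load L in n samples scores L(1 − 1/n), so
  rare-but-dominant taxa outrank ubiquitous ones. The scale is
  configurable but linear is the default precisely because it favors the
  bloom pattern.
* **Signature clustering.** Average-linkage hierarchical clustering on
  1 − Spearman ρ of the top-16 taxon loads, cut into two clusters. The
  candidate disruptor signature is the cluster containing the
  highest-scored Enterobacteriaceae-family taxon (falling back to the
  higher-mean-score cluster); the final set removes the exclusion list
  (default {Lactobacillus}, whose host relationship is more nuanced than
  the other bloomers'). The linkage/distance choice is ours; it is
  order-invariant and recovers separable anti-correlated blocks exactly.
* **Co-correlation motifs.** Pairwise Spearman among the top-20 most
  abundant taxa plus total load, BH-corrected within the matrix
  (q < 0.1). A taxon is *mutually exclusive* when its significant links
  (including the total-load link) cover < 25% of the other taxa;
  *pair-coupled* when some significant taxon partner exceeds its
  total-load correlation; *total-load-coupled* when the total-load link is
  significant, positive, and largest. Precedence: exclusive > pair >
  total. Counting the total-load link among significant correlations keeps
  a pure total-load tracker out of the exclusive class; the 25% threshold
  is configurable (the qualitative description is "almost all other taxa").
* **Multiple testing.** One BH family per analysis (co-correlation matrix,
  each volcano, symptom correlations, cytokine correlations, subgroup
  flags), never pooled across analyses. Thresholds: q < 0.1 for
  co-correlation and site volcanos, q < 0.01 for the SIBO volcano,
  q < 0.05 for axis–metadata correlations.
* **Ordination.** X[s,t] = log₁₀(((count + 0.1)/depth) · load): the 0.1
  pseudo-read is added to counts before forming relative abundances
  (equivalent to adding 0.1/depth to the relative abundance). Columns are
  mean-centered, not variance-scaled. PCA is an exact SVD; signs are fixed
  so the largest-|loading| taxon on each axis is positive. Ranked loadings
  scale each eigenvector by the maximum |score| on that axis. Default 10
  components.
* **Clinical.** Culture SIBO: aerobic CFU ≥ 10³/mL (inclusive). Sequencing
  SIBO: summed disruptor load ≥ 10⁴ copies/mL — the operating point echoes
  the per-taxon 10⁴ rule used for disruptor counting (strictly greater
  for the count). Severe symptom = score strictly above the cohort median
  for that symptom (ties non-severe). Burden bins on summed disruptor load
  (Lactobacillus excluded): zero, (0,10⁴], (10⁴,10⁵], (10⁵,10⁶],
  (10⁶,10⁷], >10⁷ copies/mL. ROC curves sweep all thresholds with tied
  scores grouped, trapezoidal AUC. The Klebsiella comparison runs on
  samples with ≥ 10⁵ copies/mL of family-level 16S load and treats
  Cq ≥ 40 as undetected.
* **Oral link.** Presence is nonzero load after LOD filtering, at the
  resolution of the input table (genus by default). Paired overlap is
  |D ∩ S| / |D|; the non-paired baseline is the mean of the same fraction
  against every other subject's saliva (n − 1 comparisons). Site
  enrichment delegates to the volcano machinery on relative abundances.

## Synthetic cohort generator

The generator emulates the cross-sectional structure the analyses assume.
Each subject receives:

1. **Membership.** A 60-genus pool: 44 oral-capable genera (9 "core"
   genera with elevated carriage, 0.80 inclusion, and a long tail at
   ≈0.74, giving a pool-mean saliva inclusion of 0.75) and 16 gut-resident
   genera. Saliva-present oral taxa transmit to the duodenum with
   probability 0.88; Poisson(2.8) gut-resident commensals are added as
   duodenum-unique taxa; the 8 disruptor genera are carried at baseline
   with probability 0.04 each; gut genera also appear in saliva at a low
   carriage rate (0.26) without seeding the duodenal community.
2. **Composition.** Present taxa draw log-normal intensities around a
   steep rank-abundance hierarchy (Streptococcus ≈ 2.2 log₁₀ intensity
   units down to ≈ −1 for the rarest tail genera) and are normalized to
   proportions.
3. **Load.** The baseline load is 10^truncN(5.80, 1.15) on
   [log₁₀(5×10³), 9]. With probability 0.2 a disruptor bloom is added:
   one primary disruptor (propensities follow the relative frequencies of
   the bloom genera, Lactobacillus and the Enterobacteriaceae variants
   most often) at 10^N(6.5, 1.0) copies/mL, plus each other disruptor as
   a secondary with probability 0.45 at 10^−U(0.1, 0.5) of the primary.
   Strict anaerobes not themselves blooming are multiplied by
   exp(−8 · bloom fraction). Totals are capped at 10⁹ copies/mL. The
   baseline parameters (5.80, 1.15) were calibrated once, numerically, so
   that the *marginal* distribution of log₁₀ total load — blooms included,
   which is what a cohort histogram shows — has mean ≈ 6.13 and
   SD ≈ 1.12 (measured 6.133 / 1.133 at n = 16,000).
4. **Measurement.** Reads are multinomial at depth ≈ N(50,000, 1,500)
   (min 46,000); dPCR concentrations carry 0.05 log₁₀ measurement noise
   plus the dilution/volume bookkeeping; collection volumes are log-normal
   matching the observed 95% CIs (duodenum 0.18–1.93 mL, saliva
   0.36–1.28 mL) with missing-volume fractions 11/250 and 10/21; ten
   water blanks at 10^N(3.5, 0.15) copies/mL.
5. **Clinical layers.** Saliva total load = the subject's duodenal log₁₀
   load + N(2.5, 0.35). Aerobic/anaerobic CFU are the plate-subset genome
   loads with 0.5 / 1.2 log₁₀ plating noise. Six symptom scores are
   Beta-mixture draws whose severe component follows a per-subject
   logistic link in log₁₀ disruptor load (intercept −1.0, slope 0.5,
   subject random effect SD 2.5). Thirteen cytokines are log-normal; IL8
   alone carries a 0.08 log₁₀-per-unit disruptor-load effect. Klebsiella
   qPCR records are emitted for Enterobacteriaceae-rich samples (≥ 10⁵
   copies/mL), detected with probability 16/22 at half the
   Enterobacteriaceae genome load with 0.3 log₁₀ noise.

Every latent variable (true loads, bloom membership and primaries, true
severe states, true volumes, membership lists) is stored in a ground-truth
ledger so recovery tests never need re-simulation.

### Design choices made under genuine ambiguity

* **Saliva coupling.** The saliva offset is applied per subject rather
  than drawn independently around the population mean; at n = 21 this
  makes the planted 2.5-order site offset identifiable (an independent
  draw would leave the paired-difference estimator dominated by duodenal
  sampling noise). The cost is that paired site loads correlate in the
  generator, whereas real paired data show no significant correlation —
  a deliberate trade-off, and the reason the "independent sites give
  ρ ≈ 0" behavior is tested on constructed inputs instead.
* **Pool split and overlap calibration.** With a single oral pool, the
  non-paired overlap would equal the saliva inclusion rate (~75%); the
  observed ~66% requires duodenum-unique taxa absent from other subjects'
  saliva. Hence the 44/16 oral/gut split, gut-sourced unique taxa, and the
  unique rate (Poisson 2.8) calibrated so that the detected paired overlap
  lands near 89% and non-paired near 66% after LOD effects.
* **Co-blooming disruptors.** Pure one-bloom-per-sample exclusivity would
  anti-correlate the disruptors with each other, and no 2-cut of the
  co-correlation matrix could group them into one signature. Secondary
  blooms (probability 0.45 at 10^−U(0.1,0.5) of the primary) mirror the
  correlated Enterobacteriaceae variants seen in real data and give the
  signature its internal cohesion.

### What the generator does and does not reproduce

Passing tests demonstrate that the *pipeline* recovers what the generator
plants under realistic measurement noise — they are not evidence about any
real cohort. Emulated and verified end-to-end (measured over ≥ 20 seeds):
the load marginal (fitted means 6.02–6.20, SDs 1.02–1.18 at n = 250);
the 8-taxon candidate / 7-taxon final disruptor signature (≈ 90% of
seeds); paired ≈ 85–94% vs non-paired ≈ 64–72% overlap; the 2.5-order
site offset (2.3–2.7); PC1 tracking log total load (|ρ| ≈ 0.93–0.97);
culture concordance higher on the aerobic than the anaerobic side; severe
symptom burden rising with disruptor load; IL8 as the only axis-associated
cytokine.

Two published real-data effect sizes are *qualitatively* but not
quantitatively reached under these conditions: the fraction-strict vs
Shannon correlation (real data ≈ 0.7; generator 0.31–0.45, because one
fifth of blooms are mild — magnitude 10^N(6.5,1) against baselines near
10^5.8 — and a minority of blooms are themselves strict anaerobes, both of
which dilute the linear correlation) and the disruptor-axis vs Shannon
correlation (real ≈ 0.74; generator ≈ 0.25–0.55). The corresponding tests
assert the planted direction at the level the generator delivers (> 0.25
and > 0.2 respectively). Per-genus abundance shapes (e.g. bimodality of
Porphyromonas) are emulated only qualitatively; age/medication structure
is present but carries no planted effects beyond a weak low-load
propensity for current antibiotic use.

## Problem sizes

Defaults everywhere match the study design the generator emulates: 250
duodenal samples, 21 paired saliva samples, a 60-genus pool, ~50,000 reads
per sample. The test suite runs the full pipeline on these sizes directly
(a complete run takes a few seconds), so no scaled-down shadow
configurations are needed; property checks use small constructed fixtures
where exhaustive oracles (pair counting, step-up enumeration,
hypergeometric moments) are cheap.

## Known limitations

* Droplet-level dPCR Poisson statistics are out of scope; instrument
  concentrations are consumed as given.
* The blank model is a single log-normal floor; reagent-specific
  contaminant *composition* (and hence per-taxon decontamination) is not
  modeled.
* Oxygen-class annotations are a curated genus-level table; genera outside
  it default to "unknown" and drop out of anaerobe partitions.
* The symptom link is a single logistic in summed disruptor load; no
  symptom-specific effects are planted, so symptom-level contrasts on
  synthetic data are noise.
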