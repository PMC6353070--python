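# Methods

This note documents the models, parameter choices and known limitations
behind the package, in the order data flows through the pipeline.

## The synthetic experiment

The generator (`metaproteo.simulate`) emulates a two-diet cecal
metaproteome study: 18 animals (9 digestible-starch, animals 7–15; 9
resistant-starch, animals 16–24), a protein catalog mixing host proteins
with a bacterial community resolved to species, and three measurement
channels (spectral counts, precursor intensities, TMT reporter blocks).
One integer seed determines every byte of output.

**Abundance model.** Baseline protein abundances are log-normal with
natural-log sd `abundance_sigma = 2.0` (≈ 2.9 log2 units, i.e. proteomes
spanning roughly four orders of magnitude — typical of shotgun data).
Each sample multiplies every protein by a per-animal, per-taxon
log-normal factor (`taxon_sigma = 0.5` ln units): gut communities vary
substantially between animals, and this between-animal taxon dispersion
is what the moderated t must overcome at the taxon level. Host proteins
are scaled so the expected host:bacteria spectral mass ratio equals
`host_mass_ratio` (default 0.2 — a free parameter; the true value for
cecal content is not established, so it is a config knob, not a claim).

**Counts.** Spectral counts per sample are a single multinomial draw of
`depth_per_sample` (default 30 000) over proteins with probabilities
proportional to abundance × length. The fixed-budget multinomial (rather
than independent Poissons) makes the compositional NSAF scale exact:
column totals equal the depth by construction.

**Intensities and MNAR.** Precursor intensities are abundance × length ×
log-normal noise (`intensity_sigma = 0.35`). Missingness is
missing-not-at-random: detection probability is a logistic function of
log2 intensity, centered at the `missing_model` quantile (default 0.2)
with steepness 1.5. This is the mechanism that justifies downshifted-
normal imputation downstream.

**PSMs and decoys.** Counts are split over each protein's tryptic
peptides (sequences are random over the 20-letter alphabet with K/R at
~11%, so digests are non-degenerate). Target scores are normal(35, 5) on
the −10·log10 P scale; decoy PSMs (fraction 0.1) share the family with a
−12 location shift, giving a realistic, tunable score-FDR curve.

**Community structure.** Species get full seven-rank lineages. Three
species are always present in one family (Ruminococcaceae): the
amylolytic *Ruminococcus bromii* and the fibrolytic *R. albus* and
*R. flavefaciens*. By default *R. bromii* starts at one tenth of the
community-average per-species mass (rare before the dietary
intervention), while the fibrolytic species start at the average share —
they can only decrease 10–20× because they start abundant. This matters
quantitatively: it makes the planted community shift nearly mass-neutral,
so the compositional "closure" shift imposed on null taxa stays small
relative to between-animal noise. With an abundant planted increase, the
closure term alone (~0.5 log2 units) would make many null taxa
significant — a real property of compositional data, not an artifact.

**Planted truth.** `effect_table` entries name a protein accession or a
species; species effects are inherited by every member protein. The
`GroundTruth` object records per-protein true log2FC, species
assignments, the per-sample true host:bacteria mass ratio, and the GO
terms planted as enriched (terms that preferentially annotate
effect-carrying proteins). `study_config(seed)` assembles the full
emulated scenario: the three Ruminococcus shifts, a guild of six rare
starch-product utilizers up ~5× from near the detection limit (the
species-level mechanism behind an alpha-diversity increase), a mild
Bacteroidetes expansion, 100 protein-level effects of |log2FC| = 2
stratified 30:70 host:bacterial, and two grossly host-dominated samples
(animals 9 and 21) destined for QC exclusion.

**What the generator does not emulate:** spectrum-level structure (m/z,
retention time, fragment ions), sequence homology and shared peptides
between related proteins, protein-inference ambiguity, batch drift in
label-free runs, and ecological dynamics. Passing tests therefore show
the statistical pipeline is correct and calibrated under this generative
model, not that any specific biological dataset will behave identically.

## QC and filtering

The FDR estimator is the plain #decoys/#targets ratio at or above a
score threshold; the returned threshold is the smallest (most permissive)
score whose estimate stays at or below the target, which guarantees
retained sets are nested as the target tightens. The (d+1)/t variant and
engine-specific fused-decoy corrections are deliberately not used —
transparent and monotone beats marginally less biased here.

"Unique peptide" means a peptide sequence (I and L equated, matching
common practice in taxonomic peptide assignment) whose every PSM maps to
exactly one accession. Protein quantifiability requires ≥ 2 unique
peptides and ≥ 3 non-zero abundances in at least one diet group.

Sample exclusion codifies an "exclude the most extreme host:bacteria
ratios" judgement as a reproducible rule: robust z on the log ratio,
|z| > 3 with z = (log r − median) / (1.4826 · MAD). It is scale-invariant
and, with MAD = 0, flags nothing rather than everything. Between-animal
ratio spread is naturally wide (roughly ±0.8 natural-log units at the
default dispersion), so only samples whose spectra are ~90% host — i.e.
genuinely degraded — clear the threshold.

## Quantification

All three scales are compositional; rescaling one sample's raw data by
any constant leaves its column unchanged (tested). Zeros in count
matrices become missing after log2 transform rather than −∞: a zero
spectral count at finite depth is censoring, not absence, and this
routes zeros into the imputation path.

The iBAQ denominator counts fully-tryptic peptides of length 7–30 with
zero missed cleavages and the KP rule. These are conventional defaults;
the tool chain the design mirrors does not publish its exact digest
parameters, so the values are explicit config rather than claims.

TMT channel normalization equalizes per-channel column sums within each
batch, computed over the features observed in every channel of that
batch, then takes ratios to the pooled channel. The upstream "normalized
summed reporter intensities" convention is not specified anywhere
authoritative; this contract is documented as this package's choice
(median-centering would be a reasonable alternative and changes ratios
only by a per-channel constant).

Imputation draws from N(μ − shift·σ, (width·σ)²) per sample (column-wise
by default), with shift = 2 and width = 0.3 of the observed values'
moments. Observed cells are never modified; the imputed mask is carried
with the matrix; draws are deterministic given the policy seed. With
σ = 0 the imputation degenerates to the mean, with a warning.

## Differential abundance

The empirical-Bayes prior is fitted by moment-matching log s²_g to its
theoretical scaled-log-chi-square distribution: solve
trigamma(d₀/2) = var(e) − trigamma(d_g/2) with
e = log s² − digamma(d_g/2) + log(d_g/2), then
s₀² = exp(mean(e) + digamma(d₀/2) − log(d₀/2)). When the observed spread
is no larger than chi-square sampling explains, d₀ = ∞ and all features
share s₀². The trigamma inversion is Newton's method on the convex
branch; a bisection oracle validates it in tests. Total degrees of
freedom are capped at the pooled residual df so the d₀ = ∞ limit keeps a
proper reference distribution. The whole path reproduces limma's
`lmFit`/`eBayes` to ~1e-9 on shared inputs (cross-checked against
Rscript in the suite).

P-values are two-sided (both directions of change are of interest).
BH adjustment is the standard step-up, validated against brute-force
enumeration. The cross-method consensus matrix z-scores each sample
column per method before averaging, since NSAF, riBAQ and TMT ratios
live on different log scales; features absent from any method are
dropped and recorded.

## Taxonomy

Rollup divides taxon-summed counts by the per-sample total, making taxon
tables compositional with an explicit "unassigned" remainder; columns
sum to 1 exactly and the rollup is hierarchically consistent (a family's
abundance equals the sum of its genera's). A protein maps to exactly one
taxid from the catalog; peptide-level lowest-common-ancestor assignment
is out of scope because the final quantification is protein-based.

Taxon-level testing reuses the protein machinery: log2, downshifted
imputation with the same policy, moderated t, BH across taxa at the
tested rank. Whether taxon zeros should be imputed at all is genuinely
unclear for this kind of data; it is a config knob, defaulting to the
same treatment as proteins. The "unassigned" bucket is never tested.

Alpha diversity reports richness (taxa above a detection floor,
default 0) and Shannon entropy (natural log, renormalized over detected
taxa). At desk scale the simulated community has ~40 species, nearly all
above detection in every sample, so richness saturates and diversity
shifts are muted and noisy across seeds — expect single-digit percent
changes in either direction, not the large increases a community of
hundreds of partly-undetected species can show. The direction becomes
reliable exactly when rare species cross the detection limit under one
diet, which is the planted mechanism in `study_config`.

## GO enrichment

One-sided upper-tail hypergeometric p per term, summed in log space
(gammaln + logsumexp), validated against exact rational-arithmetic
enumeration to 1e-12. The sidedness is pinned by closed-form checks:
a 4-of-128-annotated test row gives
(128·127·126·125)/(1104·1103·1102·1101) = 1.73×10⁻⁴ exactly. BH pools
all tested terms across namespaces within one analysis (one analysis =
one multiple-testing family). Annotation is flat by default — a protein
counts only for its listed terms — with an optional term→descendants map
for DAG-aware counting; under-representation analyses run the same
over-representation test with the complementary list as the test set.

## Problem sizes and numerical choices

Replicate studies in the acceptance checks use 2 000 proteins ×
18 samples at depth 30 000, 200 replicates for protein-effect recovery
and 50 for taxonomic recovery — sizes chosen so the full suite runs on a
laptop-class single core in well under a minute each while leaving
recovery estimates with small standard errors. Compositional closure
biases NSAF-based log2FC estimates of planted effects by roughly the
log2 of the total planted mass change (~0.05 with the balanced default
design); the riBAQ route is nearly unbiased because its planted-mass
shift cancels in the intensity normalization the same way but its
zeros are fewer. Ties in BH are stable; p-values are clipped away from
zero at the float boundary; degenerate inputs (all-zero samples, empty
tables, MAD = 0, σ = 0) raise or warn explicitly rather than propagating
NaN.

## Known limitations

- No protein grouping/parsimony: shared PSMs accrue to every mapped
  accession, and the catalog's protein→taxon assignment is taken as
  given.
- No reporter-ion isotope-impurity correction, match-between-runs, or
  fragment-level roll-up for TMT.
- The count-based overdispersed test families (e.g. Poisson–Tweedie on
  raw unique spectral counts) are intentionally out of scope; the
  moderated t on transformed, imputed values is the primary path.
- FDR values from enrichment are internally consistent but depend on the
  tested-term universe; comparing them across analyses with different
  universes is meaningless.
- Cross-method multiplicity (a protein tested by several quantification
  methods) is reported per method plus an unadjusted minimum; no
  cross-method correction is applied.
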