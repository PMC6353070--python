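# metaproteo

Downstream analysis of mixed host–microbiome shotgun proteomics
(metaproteomics), built around a two-diet animal study design: nine
animals per arm fed digestible starch (DS) or resistant starch (RS),
with cecal-content proteomes measured by spectral counting, precursor
intensities and TMT isobaric labeling. The package implements the whole
post-identification pipeline — target-decoy PSM filtering, protein
quantification on three scales, missing-value imputation, empirical-Bayes
differential abundance, taxonomic rollup with diversity summaries, and GO
term enrichment — together with a synthetic-data generator that plants
known effects so every stage can be validated against ground truth at
desk scale.

It is written for computational proteomics / microbiome researchers who
want a tested, seedable reference implementation of these steps rather
than a chain of spreadsheet operations.

## Methods

**Identification QC.** PSMs are filtered by target-decoy FDR: at score
threshold *t* the estimated FDR is #decoys(≥ *t*) / #targets(≥ *t*);
the retained set uses the most permissive threshold with FDR ≤ 1%.
Proteins need ≥ 2 unique peptides (I/L equated) and ≥ 3 non-zero
abundances in at least one diet group to be quantifiable. Samples whose
host:bacteria spectral-count ratio is a median/MAD robust-z outlier
(|z| > 3 on the log ratio) are excluded.

**Quantification.** Three compositional scales per sample:

- NSAF: `NSAF_i = (SpC_i / L_i) / Σ_j (SpC_j / L_j)` — spectral counts
  weighted by protein length `L_i`, normalized to the sample total;
- relative iBAQ: summed precursor intensity divided by the number of
  theoretically observable fully-tryptic peptides (length 7–30, no missed
  cleavages, no cleavage before proline), normalized to the sample sum;
- TMT ratio-to-pool: per batch, reporter channels are normalized to equal
  sums and divided by the pooled-reference channel.

Values are log2-transformed (zeros become missing) and missing cells are
imputed from a downshifted normal `N(μ − 2σ, (0.3σ)²)` of each sample's
observed values — the standard convention for left-censored proteomics
data.

**Differential abundance.** Per-feature variances are shrunk by empirical
Bayes: `s̃²_g = (d₀s₀² + d_g s²_g) / (d₀ + d_g)` with the prior (d₀, s₀²)
estimated by moment-matching of log s² (trigamma inversion). The moderated
t = log2FC / (s̃_g √(1/n₁ + 1/n₂)) is referred to a t distribution with
d₀ + d_g degrees of freedom, two-sided, with Benjamini–Hochberg control.
log2FC = mean(RS) − mean(DS), so positive means higher with resistant
starch. The implementation agrees with limma's `eBayes` to ~1e-9 (tested).

**Taxonomy.** Protein spectral counts roll up to taxonomic units:
abundance of taxon *t* in sample *s* is the summed counts of proteins
whose lineage resolves to *t* at the chosen rank, divided by the sample
total (columns sum to exactly 1, "unassigned" included). Taxon tables
support the same moderated-t contrast, richness and Shannon alpha
diversity, Bacteroidetes:Firmicutes ratios, and BIOM v1 export.

**GO enrichment.** One-sided Fisher exact test per term — the upper tail
P(X ≥ nr_test) of the hypergeometric distribution, computed in log space —
with BH control across all tested terms, test and reference lists given
explicitly.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic
data (outputs under `results/`):

```
python analysis/01_simulate.py --seed 7
python analysis/02_qc.py
python analysis/03_quantify.py --seed 7
python analysis/04_differential.py
python analysis/05_taxonomy.py --seed 7
python analysis/06_enrichment.py --seed 7
```

Representative output (seed 7):

```
FDR 1%: score threshold 29.83, 32514/38326 target PSMs retained
host:bacteria ratio median 0.218; excluded samples: ['s09', 's21']
quantifiable proteins: 1473/1787
...
species flagged at p_adj<0.05:
  Ruminococcus bromii: log2FC +3.57 (= 11.9x), p_adj 3.12e-14
  Ruminococcus albus: log2FC -3.61 (= 0.1x), p_adj 3.12e-14
  Ruminococcus flavefaciens: log2FC -3.09 (= 0.1x), p_adj 3.33e-11
  ...
species-level shannon: +5.5% in RS vs DS
Bacteroidetes:Firmicutes group-mean ratio, RS/DS: 1.33
```

Reading this: the two samples simulated as degraded (host-dominated
spectra) are excluded by the robust-z rule; the amylolytic
*Ruminococcus bromii* — planted at a 12× increase under resistant
starch — is recovered at 11.9×, while the fibrolytic *R. albus* and
*R. flavefaciens* (planted 20× and 10× decreases) are recovered as the
strongest reductions; community diversity and the
Bacteroidetes:Firmicutes ratio both shift upward in the RS arm.

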