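# skinmb — multi-study skin-microbiome analysis

`skinmb` is a Python library for pooled ("multi-study") analyses of facial
skin 16S amplicon data paired with clinical skin measurements: the grade of
Crow's feet wrinkles (GCFW, an ordinal 1–6 clinical score), transepidermal
water loss (TEWL, g/m²/h) and corneometer hydration readings. Combining
cohorts recruited by different groups buys statistical power but brings
strong study effects; the package's purpose is to make the standard
workflow for that setting — harmonize, describe, rank, reduce — reusable
and testable.

The pipeline has four stages:

1. **Harmonize** — standardize metadata field names across studies, keep
   variables recorded for more than 40 % of pooled samples, keep one sample
   per subject (left cheek when both were swabbed), drop features whose
   lineage contains *Mitochondria* or *Chloroplast*, and collapse amplicon
   sequence variants (ASVs) to species-level lineages.
2. **Describe** — rarefy to 1 000 reads, compute Shannon diversity *H*, and
   test diversity–phenotype associations two ways: pooled Spearman rank
   correlation, and a linear mixed model
   `H = β₀ + β·x + u_study + ε, u_study ~ N(0, σ²)`
   whose random intercept absorbs between-cohort shifts. The overall study
   effect is quantified by a Bray-Curtis PERMANOVA R².
3. **Rank** — fit, per taxon *j*, a Bayesian negative-binomial regression

   `y_ij ~ NB(μ_ij, φ_j),  log μ_ij = log depth_i + x_iᵀ β_j`

   with study dummies, standardized age and the standardized target
   phenotype as covariates and Normal(0, 5) priors on β. Because relative
   abundances carry no absolute scale, the per-covariate coefficients are
   reported mean-centered across taxa ("differentials") and used only to
   *rank* taxa, not to test them. Convergence is checked with the
   Gelman-Rubin R-hat across independent chains; model fit with the log
   pointwise predictive density and posterior-predictive coverage.
4. **Reduce** — scan every (n_top, n_bottom) pair up to `max_n`, score the
   per-sample log-ratio `ln(Σ counts of top n_top / Σ counts of bottom
   n_bottom)` against the target by Spearman correlation, and return the
   maximizing panel. The log-ratio is depth-invariant, which is what makes
   it a usable biomarker score for compositional data.

Because real multi-cohort skin datasets are rarely redistributable, the
package ships a first-class synthetic generator
(`skinmb.generate_multistudy`) that reproduces the structural features the
analysis must survive — 13 cohorts with cohort-specific age windows, an
age-calibrated ordinal wrinkle grade (Spearman ≈ 0.58 by construction),
whole-study missing phenotypes, duplicate left/right cheek samples,
organelle contaminants, uneven depth — plus planted signature taxa with
known effect sizes, so recovery can be scored against ground truth.

## Worked example

```python
import skinmb
from skinmb import diffrank as dr, logratio as lr

cfg = skinmb.SyntheticConfig(
    n_studies=3, samples_per_study=60, n_features=100,
    n_signature_pos=10, n_signature_neg=10, effect_size=1.5,
    duplicate_fraction=0.0,
    phenotype_studies={"gcfw": (0, 1, 2), "tewl": (0, 1, 2), "corneometer": (0, 1, 2)},
    seed=11)
table, meta, taxonomy, truth = skinmb.generate_multistudy(cfg)

design = dr.build_design(meta, ["study_id", "age", "gcfw"])
filtered = dr.prevalence_filter(table.loc[design.sample_ids], 15)
result = dr.fit_nb_differentials(filtered, design, dr.NBModelSpec(seed=5),
                                 depths=table.loc[design.sample_ids].sum(axis=1))
ranked = dr.rank_features(result, "gcfw")
sel = lr.optimize_top_bottom(ranked, filtered, meta.loc[filtered.index, "gcfw"], max_n=30)
print(sel.n_top, sel.n_bottom, round(sel.rho, 2))
```

prints `6 17 0.98`: the best panel puts the 6 highest-ranked taxa over the
17 lowest-ranked, and its per-sample log-ratio rank-correlates 0.98 with
wrinkle grade. On this planted dataset all 10 positive-effect taxa rank in
the top 10 and all 10 negative-effect taxa in the bottom 10
(`examples/04_differential_ranking.py` prints the diagnostics: every
coefficient's R-hat < 1.1, posterior-predictive coverage ≈ 0.96).

The `examples/` directory has one short script per capability (simulation,
harmonization, diversity associations, differential ranking, panel
selection); each prints the numbers it computes and what they mean. A thin
CLI wraps the same functions:

```bash
skinmb simulate --seed 1 --out scratch/sim
skinmb run-all --config examples/pipeline.yaml --out scratch/run
```

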