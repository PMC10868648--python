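# Methods

## Setting and model

The package targets pooled analyses of facial skin 16S amplicon cohorts
with paired clinical measurements: wrinkle grade (GCFW, ordinal 1–6), TEWL
(g/m²/h, higher = weaker barrier) and corneometer hydration (arbitrary
units). Two statistical facts dominate this setting and drive every design
choice below: counts are *compositional* (sequencing depth is arbitrary,
only relative abundances are informative), and pooled cohorts carry a
*study effect* (recruitment, protocol, sequencing) that is typically the
largest source of variation.

### Descriptive branch

Counts are rarefied to a fixed depth (default 1 000 reads; samples below
it are dropped) before alpha- and beta-diversity summaries, so that
richness-sensitive quantities are compared at equal sampling effort.
Shannon diversity is computed in log base 2 (bits), configurable.
Diversity–phenotype association is reported twice: a pooled Spearman rank
correlation (two-sided; exact permutation p-value by full enumeration for
n ≤ 10, t-approximation above; 95 % CI by Fisher z), and a linear mixed
model with a Gaussian random intercept per study, fitted by REML through
statsmodels, with a Wald z p-value on the fixed slope. The contrast
between the two is informative in itself: a pooled correlation driven by
between-study composition differences collapses in the mixed model.

The study effect on overall composition is quantified by a single-term
PERMANOVA on Bray-Curtis distances of the rarefied, species-collapsed
table. The implementation uses the McArdle–Anderson trace identity: with
the Gower-centered matrix G = −½ C D² C, the term sum of squares is
tr(H G) for the hat matrix H of the centered design, giving pseudo-F and
R² = SS_model / tr(G); p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm).
Categorical variables enter as reference-coded dummies (k − 1 df),
continuous variables as one centered column, for which permutations are
evaluated vectorised via a quadratic form. Bray-Curtis is a deliberate,
documented substitution: the package takes no phylogenetic tree as input,
so UniFrac-family distances are out of scope.

### Differential branch

Rarefaction discards counts; the differential model instead uses the
unrarefied table and absorbs depth as a fixed offset. For each taxon j,

    y_ij ~ NB(μ_ij, φ_j),   log μ_ij = log depth_i + x_iᵀ β_j,

NB2 parameterisation (Var = μ + μ²/φ). Covariates are an intercept,
reference-coded study dummies, standardized age, and the standardized
target phenotype; age rides along because wrinkle grade is strongly
age-correlated and age would otherwise confound the target coefficient.
GCFW enters as a continuous covariate (no ordinal link). Priors are
β ~ N(0, 5²) on the log scale and log φ ~ N(0, 1); both configurable in
`NBModelSpec`.

Sampling is per feature, with defaults of 4 chains × (50 warmup + 200
kept) draws. The kernel mixes, with equal probability, (a) an
independence proposal from a widened Laplace approximation N(θ_MAP,
(1.2 L)(1.2 L)ᵀ) — L the Cholesky factor of the inverse Hessian at the
posterior mode found by L-BFGS with analytic gradients — and (b) a
Laplace-preconditioned random walk whose global scale adapts toward ~30 %
acceptance during warmup only. When the Laplace approximation is accurate
(the usual case for this low-dimensional, log-concave-like posterior) the
independence moves give near-independent draws, so short chains mix well;
the random-walk component keeps the sampler valid when it is not.
Per-coefficient convergence is summarised by the Gelman-Rubin statistic
R-hat = sqrt(((n−1)/n·W + B/n)/W); model adequacy by the log pointwise
predictive density and the fraction of observed counts inside 95 %
posterior-predictive intervals, both computed on ~100 thinned draws.

Coefficients are reported as *differentials*: posterior means
mean-centered across taxa within each covariate. Under compositionality an
additive constant per covariate is unidentified (scaling a sample's counts
moves only its offset), so only the ordering and differences of
differentials are meaningful — they feed ranking, never hypothesis tests.

### Panel selection

Given the ranking for a target, the selector scans all (n_top, n_bottom)
pairs up to `max_n` (default 30), forms ln(Σ top counts / Σ bottom counts)
per sample — raw count sums, no pseudocount; samples with a zero sum on
either side are dropped and counted — and keeps the pair maximizing the
*signed* Spearman ρ with the target (ranking orients top taxa toward high
target values; maximizing |ρ| would reward sign flips). Ties go to the
smaller panel, then to the smaller numerator. Because the winning ρ is a
maximum over the grid it is optimistic under the null; the selection
object carries this caveat, and `holdout_fraction > 0` re-evaluates the
chosen panel on samples excluded from the scan. No multiplicity correction
is applied over the grid — the procedure is a screening device, and the
held-out ρ is the honest effect estimate.

## Synthetic data generator

The generator emulates the structure a pooled skin-microbiome analysis
must survive, with defaults chosen as the package's reference study
conditions:

- **Cohorts.** 13 studies, 50 subjects each by default (~650 subjects,
  the scale of a harmonized multi-cohort facial dataset), with per-study
  age windows spanning 18–70 y overall but individually narrow — the
  confounding pattern that makes study adjustment necessary. Phenotypes
  can be missing for whole studies (the default mask mirrors a realistic
  pattern where only ~5 studies grade wrinkles).
- **Phenotypes.** GCFW is generated as clamp(round(a·age + ε), 1..6) with
  the noise SD solved by bisection (on the age mixture of the
  GCFW-recording studies, own RNG stream) so that Spearman(age, GCFW)
  hits a target, default 0.58. TEWL ~ N(17, 4.5²) and corneometer
  ~ N(55, 12²), truncated positive, independent of age.
- **Counts.** Per sample, intensities
  λ_ij = exp(t_i·(b_j + u_{s(i),j}) + β_j·z_i)·Γ(φ, 1/φ) with feature
  intercepts b_j ~ N(0, 2²), study offsets u ~ N(0, study_effect_sd²),
  z the standardized target phenotype and β the planted differentials
  (±effect_size on the signature sets, 0 elsewhere). A uniform random
  depth from `depth_range` is then allocated multinomially over λ —
  independent negative-binomial counts conditioned on the sample total,
  so every row sum lands inside `depth_range` exactly while the planted
  log-fold structure is preserved.
- **Diversity couplings.** The evenness factor t_i = exp(−Σ c_k z_ik)
  flattens (higher diversity) or sharpens a sample's baseline composition
  as a function of phenotype z-scores, planting diversity–phenotype
  slopes of chosen sign without touching the differential structure.
- **Nuisance structure.** A configurable fraction of subjects receives a
  second, independently resampled right-cheek sample; round(contaminant
  _fraction·n_features) features carry Mitochondria/Chloroplast lineages;
  some non-signature features share a species lineage (so collapse merges
  something) or have an empty species rank.

What the generator does *not* emulate: sequence-level error, chimeras,
phylogeny, taxon–taxon interactions, overdispersion heterogeneity across
taxa, or non-monotone phenotype effects. Passing recovery tests therefore
shows the estimators do their job under the stated generative model, not
that real skin datasets satisfy that model.

## Numerical choices and edge cases

- Rarefaction subsamples without replacement
  (`multivariate_hypergeometric`), RNG keyed per sample id (CRC32 mixed
  with the stage seed), so a sample's draw is independent of table order
  and membership.
- Spearman uses mid-ranks for ties; the exact permutation p enumerates
  all n! orderings in vectorised chunks (n ≤ 10).
- Mixed-model fits fall back to OLS with a logged warning when only one
  group is present; a degenerate zero-variance fit reports p = 1.
- The NB log-posterior clips the linear predictor to ±30 before
  exponentiation; the Hessian is regularised before Cholesky, with an
  identity-scaled fallback.
- R-hat on all-constant chains is undefined: NaN sentinel plus a runtime
  warning.
- Completeness filtering uses the pooled sample fraction (a variable
  recorded by few large studies survives; one recorded by many tiny ones
  may not) and drops at exactly the threshold ("more than 40 %" retained).
- Unknown cheek sides deduplicate by lexicographically smallest sample
  id; left < right < unknown otherwise.
- Species collapse keys on the full 7-rank lineage string, so homonymous
  species in different genera stay separate and unassigned species
  survive as truncated-lineage features.
- The prevalence filter is inclusive (present in ≥ 15 samples is kept).
- Pipeline reports round floats to 10 decimal places and serialise
  with sorted keys, making rerun-identity a byte comparison.

## Problem sizes

The test-suite and acceptance-script benchmarks run at 3 studies × 60
samples × 100 features for parameter recovery (20 seeded replicates for
interval coverage), ~600 subjects at the 13-study layout for the
descriptive statistics, and 500 simulations × 999 permutations for the
PERMANOVA null calibration — sizes chosen so the full suite completes in
a few minutes on a single CPU while keeping Monte-Carlo error comfortably
below the asserted margins.

## Known limitations

- The sampler's short default chains rely on the Laplace approximation
  being good; heavy-tailed or multimodal posteriors (e.g. features with
  almost all zeros surviving the prevalence filter) would need longer
  chains, which `NBModelSpec` allows.
- Differentials are per SD of the standardized covariate;
  back-transformation constants are stored in the result but natural-unit
  reporting is left to the caller.
- PERMANOVA supports a single term; sequential (Type-I) multi-term
  decompositions are out of scope.
- The left-cheek dedup rule assumes cheek side is recorded reliably;
  `unknown` sides fall back to an arbitrary but deterministic choice.
- BIOM-format I/O is not provided; tables are exchanged as TSV
  (features × samples).
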