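"""Rank taxa by their association with wrinkle grade, adjusting for study
and age.

Fits the per-feature Bayesian negative-binomial model (depth offset,
study dummies + standardized age + standardized GCFW as covariates) and
checks that the planted signature taxa land at the extremes of the
ranking.
"""

import skinmb
from skinmb import diffrank as dr

cfg = skinmb.SyntheticConfig(
    n_studies=3, samples_per_study=60, n_features=100,
    n_signature_pos=10, n_signature_neg=10, effect_size=1.5,
    duplicate_fraction=0.0,
    phenotype_studies={"gcfw": (0, 1, 2), "tewl": (0, 1, 2), "corneometer": (0, 1, 2)},
    seed=11,
)
table, meta, _, truth = skinmb.generate_multistudy(cfg)

design = dr.build_design(meta, ["study_id", "age", "gcfw"])
filtered = dr.prevalence_filter(table.loc[design.sample_ids], 15)
spec = dr.NBModelSpec(num_iter=200, num_warmup=50, chains=4, seed=5)
result = dr.fit_nb_differentials(
    filtered, design, spec, depths=table.loc[design.sample_ids].sum(axis=1))

print(f"fitted {filtered.shape[1]} features on {len(design.sample_ids)} samples")
print("diagnostics:", result.diagnostics())
# R-hat near 1 for (almost) every coefficient indicates the chains agree;
# ppc_coverage near 0.95 says observed counts fall in the posterior
# predictive intervals at the nominal rate.

ranked = dr.rank_features(result, "gcfw")
hits_top = sum(f in truth.signature_pos for f in ranked[:10])
hits_bottom = sum(f in truth.signature_neg for f in ranked[-10:])
print(f"top 10 of ranking: {hits_top}/10 planted-positive taxa")
print(f"bottom 10 of ranking: {hits_bottom}/10 planted-negative taxa")
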