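# Full-pipeline configuration on a moderate synthetic cohort.
# Any PipelineConfig field can appear here; synthetic/model are nested.
synthetic:
  n_studies: 5
  samples_per_study: 30
  n_features: 120
  n_signature_pos: 8
  n_signature_neg: 8
  effect_size: 1.5
  phenotype_studies:
    gcfw: [0, 1, 2, 3, 4]
    tewl: [0, 1, 2]
    corneometer: [2, 3, 4]
targets: [gcfw]
model:
  num_iter: 200
  num_warmup: 50
  chains: 4
rarefaction_depth: 1000
min_prevalence: 15
max_n: 20
n_permutations: 199
seed: 7
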