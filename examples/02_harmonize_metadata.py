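"""Harmonize heterogeneous per-study metadata and count tables.

Shows the pooled 40%-completeness rule for metadata variables, left-cheek
deduplication, organelle filtering, and species-level collapse.
"""

import numpy as np
import pandas as pd

import skinmb

# two studies with differently-named TEWL columns; study B never measured it
study_a = pd.DataFrame({
    "sample_id": [f"A{i}" for i in range(6)],
    "subject_id": ["u1", "u1", "u2", "u3", "u4", "u5"],
    "study_id": "A",
    "cheek_side": ["left", "right", "left", "left", "left", "left"],
    "TEWL_right_face": [12.0, 12.5, 18.0, 9.5, 14.0, 16.0],
})
study_b = pd.DataFrame({
    "sample_id": [f"B{i}" for i in range(6)],
    "subject_id": [f"v{i}" for i in range(6)],
    "study_id": "B",
    "TEWL_right_cheek": [np.nan] * 6,
})

meta = skinmb.standardize_metadata(
    [study_a, study_b],
    name_map={"TEWL_right_face": "tewl", "TEWL_right_cheek": "tewl"},
)
print("pooled columns:", list(meta.columns))
print(f"tewl recorded for {meta.tewl.notna().mean():.0%} of samples -> retained")

dedup = skinmb.deduplicate_subjects(meta)
print(f"{len(meta)} samples -> {len(dedup)} subjects "
      f"(subject u1 kept sample {dedup[dedup.subject_id == 'u1'].index[0]})")

# organelle filter + species collapse on a toy table
counts = pd.DataFrame(
    [[5, 3, 7, 2]] * len(dedup),
    index=dedup.index, columns=["asv1", "asv2", "asv3", "mito1"],
)
lineages = pd.Series({
    "asv1": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Staph; g__Staphylococcus; s__epidermidis",
    "asv2": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Staph; g__Staphylococcus; s__epidermidis",
    "asv3": "k__Bacteria; p__Actinobacteriota; c__Actinomycetia; o__Micrococcales; f__Micro; g__Kocuria; s__",
    "mito1": "k__Bacteria; p__Proteobacteria; c__Alpha; o__Rickettsiales; f__Mitochondria; g__; s__",
})
filtered = skinmb.filter_features_by_taxonomy(counts, lineages)
species = skinmb.collapse_to_species(filtered, lineages)
print(f"{counts.shape[1]} ASVs -> {filtered.shape[1]} after organelle filter "
      f"-> {species.shape[1]} species-level features")
# the two S. epidermidis ASVs merge into one feature; totals are conserved
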