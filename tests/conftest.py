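import numpy as np
import pandas as pd
import pytest

import skinmb

ALL_STUDIES_3 = {"gcfw": (0, 1, 2), "tewl": (0, 1, 2), "corneometer": (0, 1, 2)}


@pytest.fixture(scope="session")
def planted_dataset():
    """3 studies x 60 samples, 100 features, 10+10 signature taxa at
    |beta| = 1.5 — the standard parameter-recovery fixture."""
    cfg = skinmb.SyntheticConfig(
        n_studies=3, samples_per_study=60, n_features=100,
        n_signature_pos=10, n_signature_neg=10, effect_size=1.5,
        study_effect_sd=1.0, duplicate_fraction=0.0,
        phenotype_studies=ALL_STUDIES_3, seed=11,
    )
    return cfg, skinmb.generate_multistudy(cfg)


@pytest.fixture(scope="session")
def planted_differentials(planted_dataset):
    """NB differentials fitted once on the planted fixture."""
    cfg, (table, meta, tax, truth) = planted_dataset
    design = skinmb.build_design(meta, ["study_id", "age", "gcfw"])
    filtered = skinmb.prevalence_filter(table.loc[design.sample_ids], 15)
    spec = skinmb.NBModelSpec(num_iter=200, num_warmup=50, chains=4, seed=5)
    result = skinmb.fit_nb_differentials(
        filtered, design, spec, depths=table.loc[design.sample_ids].sum(axis=1)
    )
    return design, filtered, result


@pytest.fixture
def toy_table():
    """4 samples x 4 features with hand-checkable counts."""
    return pd.DataFrame(
        [[250, 250, 250, 250],
         [500, 250, 125, 125],
         [1000, 0, 0, 0],
         [0, 0, 900, 100]],
        index=["s1", "s2", "s3", "s4"],
        columns=["fA", "fB", "fC", "fD"],
    )


@pytest.fixture
def toy_taxonomy():
    return pd.Series(
        {
            "fA": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Staphylococcaceae; g__Staphylococcus; s__epidermidis",
            "fB": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Staphylococcaceae; g__Staphylococcus; s__epidermidis",
            "fC": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; f__Mitochondria; g__; s__",
            "fD": "k__Bacteria; p__Actinobacteriota; c__Actinomycetia; o__Micrococcales; f__Micrococcaceae; g__Kocuria; s__",
        },
        name="lineage",
    )
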