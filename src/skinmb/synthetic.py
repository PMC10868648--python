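"""Multi-study synthetic amplicon data with planted phenotype effects.

Emulates the structure of a pooled facial skin-microbiome meta-analysis:
several cohorts ("studies") with study-specific age windows and
compositional baselines, an ordinal wrinkle grade (GCFW, 1-6) that tracks
age, barrier (TEWL) and hydration (corneometer) measures independent of
age, organelle contaminant features, duplicate left/right cheek samples,
and uneven sequencing depth.  A set of signature taxa carries a planted
log-fold effect of the target phenotype so that downstream ranking and
panel-selection stages can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "GroundTruth", "generate_multistudy", "write_dataset"]

# Cohort age windows (years) modelled on a 13-study facial-skin meta-analysis
# spanning 18-70 years with several tightly age-restricted cohorts.
DEFAULT_AGE_RANGES: tuple[tuple[float, float], ...] = (
    (55, 69), (55, 69), (55, 65), (55, 65), (56, 65),
    (19, 43), (19, 44), (18, 45), (19, 44), (25, 45),
    (20, 55), (30, 45), (33, 50),
)

# Which phenotypes are recorded per study in the default 13-study layout
# (others are whole-study missing, mimicking heterogeneous cohort metadata).
DEFAULT_PHENOTYPE_STUDIES: dict[str, tuple[int, ...]] = {
    "gcfw": (0, 1, 3, 9, 12),
    "tewl": (2, 3, 4, 5, 6, 7, 10, 11, 12),
    "corneometer": (5, 7, 8, 9, 10, 11, 12),
}

PHENOTYPES = ("gcfw", "tewl", "corneometer")


def _fail(field_name: str, message: str) -> None:
    raise ValueError(f"invalid SyntheticConfig.{field_name}: {message}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the multi-study generator.

    ``effect_size`` is the log-fold change in a signature taxon's expected
    abundance per standard deviation of the target phenotype;
    ``study_effect_sd`` scales per-study, per-feature log-baseline shifts
    (the "study effect"); ``dispersion`` is the negative-binomial
    inverse-dispersion (large values approach Poisson/multinomial noise).
    ``diversity_couplings`` optionally flattens or sharpens each sample's
    baseline composition as a function of a phenotype, inducing a
    diversity-phenotype association of the configured sign.
    """

    n_studies: int = 13
    samples_per_study: int = 50
    n_features: int = 200
    n_signature_pos: int = 10
    n_signature_neg: int = 10
    effect_size: float = 1.5
    study_effect_sd: float = 1.0
    age_ranges: tuple[tuple[float, float], ...] | None = None
    age_gcfw_rho: float = 0.58
    depth_range: tuple[int, int] = (2000, 50000)
    duplicate_fraction: float = 0.2
    contaminant_fraction: float = 0.05
    dispersion: float = 5.0
    target_phenotype: str = "gcfw"
    diversity_couplings: dict[str, float] = field(default_factory=dict)
    phenotype_studies: dict[str, tuple[int, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            _fail("n_studies", "must be >= 1")
        if self.samples_per_study < 1:
            _fail("samples_per_study", "must be >= 1")
        if self.n_features < 1:
            _fail("n_features", "must be >= 1")
        if self.n_signature_pos < 0:
            _fail("n_signature_pos", "must be >= 0")
        if self.n_signature_neg < 0:
            _fail("n_signature_neg", "must be >= 0")
        if self.n_signature_pos + self.n_signature_neg >= self.n_features:
            _fail("n_signature_pos", "signature features must number fewer than n_features")
        if not -1.0 <= self.age_gcfw_rho <= 1.0:
            _fail("age_gcfw_rho", "must lie in [-1, 1]")
        if len(self.depth_range) != 2 or self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            _fail("depth_range", "need 1 <= min <= max")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            _fail("duplicate_fraction", "must lie in [0, 1]")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            _fail("contaminant_fraction", "must lie in [0, 1]")
        if self.dispersion <= 0:
            _fail("dispersion", "must be > 0")
        if self.target_phenotype not in PHENOTYPES:
            _fail("target_phenotype", f"must be one of {PHENOTYPES}")
        if self.age_ranges is not None:
            if len(self.age_ranges) != self.n_studies:
                _fail("age_ranges", "need one [min, max] pair per study")
            for lo, hi in self.age_ranges:
                if lo < 0 or hi < lo:
                    _fail("age_ranges", "each range needs 0 <= min <= max")
        for pheno in self.diversity_couplings:
            if pheno not in ("age",) + PHENOTYPES:
                _fail("diversity_couplings", f"unknown phenotype {pheno!r}")

    def resolved_age_ranges(self) -> tuple[tuple[float, float], ...]:
        if self.age_ranges is not None:
            return tuple(tuple(r) for r in self.age_ranges)
        reps = (DEFAULT_AGE_RANGES * (self.n_studies // len(DEFAULT_AGE_RANGES) + 1))
        return reps[: self.n_studies]

    def resolved_phenotype_studies(self) -> dict[str, tuple[int, ...]]:
        if self.phenotype_studies is not None:
            return {k: tuple(v) for k, v in self.phenotype_studies.items()}
        if self.n_studies == 13:
            return dict(DEFAULT_PHENOTYPE_STUDIES)
        every = tuple(range(self.n_studies))
        return {p: every for p in PHENOTYPES}


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure emitted alongside a synthetic dataset."""

    signature_pos: frozenset[str]
    signature_neg: frozenset[str]
    true_differentials: pd.Series  # per feature, log-fold change per SD of target
    per_study_offsets: pd.DataFrame  # studies x features, log-baseline shifts
    target_phenotype: str

    def to_json(self) -> str:
        payload = {
            "target_phenotype": self.target_phenotype,
            "signature_pos": sorted(self.signature_pos),
            "signature_neg": sorted(self.signature_neg),
            "true_differentials": {k: float(v) for k, v in self.true_differentials.items()},
            "per_study_offsets": {
                study: {f: float(x) for f, x in row.items()}
                for study, row in self.per_study_offsets.iterrows()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def _gcfw_from_age(ages: np.ndarray, slope: float, intercept: float,
                   noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    raw = slope * ages + intercept + rng.normal(0.0, noise_sd, ages.shape)
    return np.clip(np.rint(raw), 1, 6).astype(int)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = pd.Series(a).rank().to_numpy()
    rb = pd.Series(b).rank().to_numpy()
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra ** 2).sum() * (rb ** 2).sum())
    return float((ra * rb).sum() / denom) if denom > 0 else 0.0


def _calibrate_gcfw_noise(config: SyntheticConfig, slope: float, intercept: float) -> float:
    """Solve (by bisection) for the Gaussian noise SD in the age->GCFW map
    that hits the target rank correlation on the configured age mixture.

    The calibration uses its own RNG stream derived from the config seed so
    the generated dataset is reproducible."""
    rng = np.random.default_rng([config.seed, 0x5CA1AB1E])
    n_cal = 4000
    ranges = config.resolved_age_ranges()
    # calibrate on the age mixture of the studies that actually record GCFW
    recording = config.resolved_phenotype_studies().get("gcfw", ())
    pool = list(recording) or list(range(config.n_studies))
    study_ix = np.asarray(pool)[rng.integers(0, len(pool), n_cal)]
    lows = np.array([ranges[i][0] for i in study_ix], dtype=float)
    highs = np.array([ranges[i][1] for i in study_ix], dtype=float)
    ages = rng.uniform(lows, highs)

    target = config.age_gcfw_rho
    if target <= 0:
        return 1e6  # no coupling requested: drown the signal

    def rho_at(sd: float) -> float:
        g = _gcfw_from_age(ages, slope, intercept, sd, np.random.default_rng([config.seed, 7, int(sd * 1e6) % (2**31)]))
        return _spearman(ages, g)

    lo, hi = 1e-3, 60.0
    if rho_at(lo) < target:
        return lo
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if rho_at(mid) >= target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _make_taxonomy(feature_ids: list[str], n_contaminants: int,
                   signature: set[str], rng: np.random.Generator) -> pd.Series:
    """7-rank Greengenes/Silva-style lineages.

    The last ``n_contaminants`` features get organelle lineages.  A fraction
    of the remaining non-signature features share a species lineage with a
    neighbour (so species collapse actually merges something), and some have
    an empty species rank."""
    phyla = ["Actinobacteriota", "Firmicutes", "Proteobacteria", "Bacteroidota"]
    lineages: dict[str, str] = {}
    clean = feature_ids[: len(feature_ids) - n_contaminants]
    i = 0
    while i < len(clean):
        fid = clean[i]
        p = phyla[i % len(phyla)]
        base = (f"k__Bacteria; p__{p}; c__Class{i % 7}; o__Order{i % 11}; "
                f"f__Family{i % 17}; g__Genus{i}")
        share_next = (
            i + 1 < len(clean)
            and fid not in signature
            and clean[i + 1] not in signature
            and rng.random() < 0.10
        )
        empty_species = fid not in signature and not share_next and rng.random() < 0.10
        species = "s__" if empty_species else f"s__species{i}"
        lineages[fid] = f"{base}; {species}"
        if share_next:
            lineages[clean[i + 1]] = f"{base}; {species}"
            i += 2
        else:
            i += 1
    organelles = ["f__Mitochondria", "o__Chloroplast"]
    for j, fid in enumerate(feature_ids[len(feature_ids) - n_contaminants:]):
        org = organelles[j % 2]
        if org.startswith("f__"):
            lin = (f"k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; "
                   f"o__Rickettsiales; {org}; g__; s__")
        else:
            lin = (f"k__Bacteria; p__Cyanobacteria; c__Cyanobacteriia; "
                   f"{org}; f__; g__; s__")
        lineages[fid] = lin
    return pd.Series(lineages, name="lineage").loc[feature_ids]


def generate_multistudy(config: SyntheticConfig):
    """Generate a pooled multi-study dataset.

    Returns ``(table, metadata, taxonomy, truth)`` where ``table`` is a
    samples x features integer count DataFrame, ``metadata`` is indexed by
    sample id with columns subject_id, study_id, cheek_side, age, gcfw,
    tewl, corneometer (phenotypes NA where a study did not record them),
    ``taxonomy`` maps feature id to a 7-rank lineage, and ``truth`` carries
    the planted signature sets and effect sizes.

    Counts: per sample, gamma-perturbed intensities
    ``exp(t_i * (b_j + u_{s(i),j}) + beta_j * z_i) * Gamma(phi, 1/phi)``
    are normalised and a uniform random depth is allocated multinomially —
    independent negative-binomial counts conditioned on the sample's total,
    so row sums land in ``depth_range`` exactly.  ``z_i`` is the
    standardized target phenotype and ``t_i`` an evenness factor driven by
    ``diversity_couplings``.
    """
    rng = np.random.default_rng(config.seed)
    n_studies = config.n_studies
    n_sub = config.samples_per_study
    ranges = config.resolved_age_ranges()
    pheno_studies = config.resolved_phenotype_studies()

    # --- subjects and phenotypes -------------------------------------------------
    study_ids, subject_ids, ages = [], [], []
    for s in range(n_studies):
        lo, hi = ranges[s]
        for k in range(n_sub):
            study_ids.append(f"study{s + 1:02d}")
            subject_ids.append(f"S{s + 1:02d}.{k + 1:03d}")
            ages.append(rng.uniform(lo, hi))
    ages = np.asarray(ages)
    n_subjects = len(subject_ids)

    # Ordinal wrinkle grade: linear-in-age latent score, rounded and clamped
    # to 1..6, noise SD calibrated to the target rank correlation.
    all_lo = min(r[0] for r in ranges)
    all_hi = max(r[1] for r in ranges)
    slope = 5.0 / max(all_hi - all_lo, 1.0)
    intercept = 1.0 - slope * all_lo
    noise_sd = _calibrate_gcfw_noise(config, slope, intercept)
    gcfw = _gcfw_from_age(ages, slope, intercept, noise_sd, rng).astype(float)

    tewl = np.clip(rng.normal(17.0, 4.5, n_subjects), 3.0, None)
    corneo = np.clip(rng.normal(55.0, 12.0, n_subjects), 15.0, None)
    phenos = {"age": ages, "gcfw": gcfw, "tewl": tewl, "corneometer": corneo}

    # --- planted structure -------------------------------------------------------
    feature_ids = [f"F{j:04d}" for j in range(config.n_features)]
    n_cont = int(round(config.contaminant_fraction * config.n_features))
    n_clean = config.n_features - n_cont
    if config.n_signature_pos + config.n_signature_neg > n_clean:
        _fail("contaminant_fraction", "too few non-organelle features for the signature sets")
    sig_pos = feature_ids[: config.n_signature_pos]
    sig_neg = feature_ids[config.n_signature_pos: config.n_signature_pos + config.n_signature_neg]
    beta = np.zeros(config.n_features)
    beta[: config.n_signature_pos] = config.effect_size
    beta[config.n_signature_pos: config.n_signature_pos + config.n_signature_neg] = -config.effect_size

    base_log = rng.normal(0.0, 2.0, config.n_features)
    study_offsets = rng.normal(0.0, config.study_effect_sd, (n_studies, config.n_features))

    z_target = _zscore(phenos[config.target_phenotype])
    tilt = np.zeros(n_subjects)
    for pheno, coupling in config.diversity_couplings.items():
        tilt = tilt + coupling * _zscore(phenos[pheno])
    evenness = np.exp(-tilt)  # < 1 flattens the composition => higher diversity

    taxonomy = _make_taxonomy(feature_ids, n_cont, set(sig_pos) | set(sig_neg), rng)

    # --- duplicate cheek samples -------------------------------------------------
    n_dup = int(round(config.duplicate_fraction * n_subjects))
    dup_subjects = set(rng.choice(n_subjects, size=n_dup, replace=False).tolist())

    sample_rows = []  # (sample_id, subject_ix, cheek_side)
    for i, sid in enumerate(subject_ids):
        sample_rows.append((f"{sid}.L", i, "left"))
        if i in dup_subjects:
            sample_rows.append((f"{sid}.R", i, "right"))

    # --- counts ------------------------------------------------------------------
    study_ix = np.repeat(np.arange(n_studies), n_sub)
    depth_lo, depth_hi = config.depth_range
    counts = np.empty((len(sample_rows), config.n_features), dtype=np.int64)
    for r, (_, i, _) in enumerate(sample_rows):
        log_mu = evenness[i] * (base_log + study_offsets[study_ix[i]]) + beta * z_target[i]
        lam = np.exp(log_mu) * rng.gamma(config.dispersion, 1.0 / config.dispersion, config.n_features)
        depth = int(rng.integers(depth_lo, depth_hi + 1))
        counts[r] = rng.multinomial(depth, lam / lam.sum())

    sample_ids = [r[0] for r in sample_rows]
    table = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=feature_ids)

    # --- metadata ---------------------------------------------------------------
    meta = pd.DataFrame(
        {
            "subject_id": [subject_ids[i] for _, i, _ in sample_rows],
            "study_id": [study_ids[i] for _, i, _ in sample_rows],
            "cheek_side": [side for _, _, side in sample_rows],
            "age": [ages[i] for _, i, _ in sample_rows],
            "gcfw": [gcfw[i] for _, i, _ in sample_rows],
            "tewl": [tewl[i] for _, i, _ in sample_rows],
            "corneometer": [corneo[i] for _, i, _ in sample_rows],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for pheno in PHENOTYPES:
        recorded = {f"study{s + 1:02d}" for s in pheno_studies.get(pheno, ())}
        meta.loc[~meta["study_id"].isin(recorded), pheno] = np.nan

    truth = GroundTruth(
        signature_pos=frozenset(sig_pos),
        signature_neg=frozenset(sig_neg),
        true_differentials=pd.Series(beta, index=feature_ids, name="true_differential"),
        per_study_offsets=pd.DataFrame(
            study_offsets, index=[f"study{s + 1:02d}" for s in range(n_studies)], columns=feature_ids
        ),
        target_phenotype=config.target_phenotype,
    )
    return table, meta, taxonomy, truth


def write_dataset(outdir, table: pd.DataFrame, metadata: pd.DataFrame,
                  taxonomy: pd.Series, truth: GroundTruth | None = None) -> None:
    """Serialize a dataset: counts as features x samples TSV, metadata and
    taxonomy as TSV, ground truth (if given) as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.T.to_csv(outdir / "feature_table.tsv", sep="\t", index_label="feature_id")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", na_rep="NA")
    taxonomy.rename_axis("feature_id").to_csv(outdir / "taxonomy.tsv", sep="\t")
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json())
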