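"""End-to-end orchestration.

Two analysis branches run from the harmonized, species-collapsed table:

* branch A (descriptive): rarefy -> Shannon diversity -> Spearman and
  random-intercept mixed-model associations with age/GCFW/TEWL/corneometer
  -> Bray-Curtis + single-term PERMANOVA per variable;
* branch B (differential): prevalence filter on the *unrarefied* counts
  (depth enters the NB model as an offset, so rarefying would discard
  information) -> Bayesian NB differentials with study + age covariates
  -> feature ranking -> top/bottom log-ratio panel per target phenotype.

A single global seed fans out to per-stage seeds by stable hashing of the
stage names, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffrank, diversity, harmonize, logratio
from .synthetic import SyntheticConfig, generate_multistudy

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_feature_table", "load_metadata", "load_taxonomy"]

PHENOTYPES = ("age", "gcfw", "tewl", "corneometer")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stable hashing."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full run.  Inputs come either from ``synthetic``
    or from the three file paths (features x samples TSV, metadata TSV,
    taxonomy TSV)."""

    synthetic: SyntheticConfig | None = None
    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    rarefaction_depth: int = 1000
    min_prevalence: int = 15
    targets: tuple[str, ...] = ("gcfw", "tewl", "corneometer")
    covariates: tuple[str, ...] = ("study_id", "age")
    model: diffrank.NBModelSpec = field(default_factory=diffrank.NBModelSpec)
    max_n: int = 30
    holdout_fraction: float = 0.0
    n_permutations: int = 999
    rarefy_for_model: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and not (self.table_path and self.metadata_path and self.taxonomy_path):
            raise ValueError("provide either a synthetic config or table/metadata/taxonomy paths")
        for t in self.targets:
            if t not in ("gcfw", "tewl", "corneometer"):
                raise ValueError(f"unknown target phenotype {t!r}")


def load_feature_table(path) -> pd.DataFrame:
    """Read a features x samples TSV into a samples x features frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T.astype(np.int64).rename_axis("sample_id")


def load_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA", ""])


def load_taxonomy(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return df.iloc[:, 0].rename("lineage")


def _assoc_pair(x, y, group) -> dict:
    """Spearman + mixed-model association of y on x, grouped by study."""
    out = {}
    try:
        out["spearman"] = diversity.spearman_association(x, y).to_dict()
    except ValueError as exc:
        out["spearman"] = {"error": str(exc)}
    try:
        out["lmm"] = diversity.lmm_association(y, x, group).to_dict()
    except ValueError as exc:
        out["lmm"] = {"error": str(exc)}
    return out


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return str(obj)
        return round(obj, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run harmonization, descriptive, and differential branches; return
    the report as a JSON-serializable dict and (if ``config.outdir`` is
    set) write all stage artifacts beneath it."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": int(config.seed), "stages": {}, "notes": []}

    # ---- inputs ---------------------------------------------------------------
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "synthetic"))
        table, metadata, taxonomy, truth = generate_multistudy(syn)
        report["input"] = {"source": "synthetic", "n_studies": syn.n_studies}
    else:
        table = load_feature_table(config.table_path)
        metadata = load_metadata(config.metadata_path)
        taxonomy = load_taxonomy(config.taxonomy_path)
        truth = None
        report["input"] = {"source": "files", "table": str(config.table_path)}

    report["stages"]["n_samples_raw"] = int(len(table))
    report["stages"]["n_features_raw"] = int(table.shape[1])

    # ---- harmonize ------------------------------------------------------------
    try:
        table = harmonize.filter_features_by_taxonomy(table, taxonomy)
        report["stages"]["n_features_after_organelle_filter"] = int(table.shape[1])

        metadata = metadata.loc[metadata.index.intersection(table.index)]
        dedup = harmonize.deduplicate_subjects(metadata)
        table = table.loc[dedup.index]
        report["stages"]["n_samples_after_dedup"] = int(len(dedup))

        collapsed = harmonize.collapse_to_species(table, taxonomy)
        report["stages"]["n_species_features"] = int(collapsed.shape[1])
    except Exception as exc:
        raise RuntimeError(f"stage harmonize failed: {exc}") from exc

    # ---- branch A: descriptive ------------------------------------------------
    try:
        rare = diversity.rarefy(collapsed, config.rarefaction_depth, stage_seed(config.seed, "rarefy"))
        n_rare = int(len(rare))
        report["stages"]["n_samples_rarefied"] = n_rare
        report["stages"]["n_samples_rarefaction_dropped"] = int(len(collapsed)) - n_rare

        shannon = diversity.shannon_diversity(rare)
        meta_r = dedup.loc[rare.index]

        covar = {}
        for pheno in ("gcfw", "tewl", "corneometer"):
            if pheno in meta_r.columns:
                covar[f"age_vs_{pheno}"] = _assoc_pair(meta_r["age"], meta_r[pheno], meta_r["study_id"])
        report["covariation"] = covar

        assoc = {}
        for pheno in PHENOTYPES:
            if pheno in meta_r.columns:
                assoc[pheno] = _assoc_pair(meta_r[pheno], shannon, meta_r["study_id"])
        report["diversity_associations"] = assoc

        dm = diversity.bray_curtis_distance(rare)
        report["notes"].append(
            "PERMANOVA uses Bray-Curtis on rarefied species-collapsed counts; "
            "no phylogenetic tree is consumed, so UniFrac-style distances are out of scope"
        )
        perma = {}
        variables = {"study_id": meta_r["study_id"]}
        for pheno in PHENOTYPES:
            if pheno in meta_r.columns:
                variables[pheno] = meta_r[pheno]
        for name, values in variables.items():
            ok = values.notna()
            if int(ok.sum()) < 3 or values[ok].nunique() < 2:
                perma[name] = {"error": "insufficient complete samples"}
                continue
            sub = dm.filter([str(i) for i in values[ok].index])
            perma[name] = diversity.permanova(
                sub, values[ok], config.n_permutations,
                stage_seed(config.seed, f"permanova:{name}"),
            ).to_dict()
        report["permanova"] = perma
        if outdir:
            shannon.to_csv(outdir / "shannon.tsv", sep="\t")
            dm.to_data_frame().to_csv(outdir / "bray_curtis.tsv", sep="\t")
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage diversity failed: {exc}") from exc

    # ---- branch B: differentials + panels --------------------------------------
    model_table = rare if config.rarefy_for_model else collapsed
    depths = model_table.sum(axis=1)
    report["differentials"] = {}
    report["panels"] = {}
    for target in config.targets:
        try:
            covs = [c for c in config.covariates] + [target]
            design = diffrank.build_design(dedup.loc[model_table.index], covs)
            sub = model_table.loc[design.sample_ids]
            filtered = diffrank.prevalence_filter(sub, config.min_prevalence)
            spec = dataclasses.replace(config.model, seed=stage_seed(config.seed, f"nb:{target}"))
            result = diffrank.fit_nb_differentials(filtered, design, spec, depths=depths)
            ranked = diffrank.rank_features(result, target)
            report["differentials"][target] = {
                "n_samples": int(len(design.sample_ids)),
                "n_features": int(filtered.shape[1]),
                **result.diagnostics(),
            }
            if outdir:
                result.to_tsv(outdir / f"differentials_{target}.tsv")

            sel = logratio.optimize_top_bottom(
                ranked, filtered, dedup.loc[filtered.index, target],
                max_n=config.max_n, holdout_fraction=config.holdout_fraction,
                seed=stage_seed(config.seed, f"logratio:{target}"),
            )
            entry = sel.to_dict()
            # same panel against age, the confounder the model adjusts for
            age = dedup.loc[list(sel.per_sample_log_ratio.index), "age"]
            ok = age.notna()
            if int(ok.sum()) >= 3:
                entry["age_association"] = diversity.spearman_association(
                    sel.per_sample_log_ratio[ok].to_numpy(), age[ok].to_numpy()
                ).to_dict()
            report["panels"][target] = entry
            if outdir:
                sel.per_sample_log_ratio.rename_axis("sample_id").to_csv(
                    outdir / f"log_ratio_{target}.tsv", sep="\t")
        except Exception as exc:
            raise RuntimeError(f"stage diffrank/logratio[{target}] failed: {exc}") from exc

    if truth is not None:
        report["ground_truth"] = {
            "target_phenotype": truth.target_phenotype,
            "signature_pos": sorted(truth.signature_pos),
            "signature_neg": sorted(truth.signature_neg),
        }

    report = _round_floats(report)
    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1) + "\n")
    return report
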