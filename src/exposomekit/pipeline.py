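"""End-to-end pipeline: generate -> quantify -> clean -> annotate -> associate.

One configuration object drives the whole run; every filter constant
defaults to the pipeline's standard value (5x blank ratio, 0.1
pseudo-count, 90,000 area floor, 0.002 Da / 0.2 min merge tolerances,
r > 0.95 dedup, 70%/60% detection-frequency gates, 0.005 + Bonferroni
multiplicity tiers).  A run manifest records seeds, per-stage feature
counts and wall-clock so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, associations, feature_processing, synthetic_data, target_quant

logger = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    n_women: int = 100
    strata: tuple[int, ...] = synthetic_data.DEFAULT_STRATA
    second_samples: tuple[int, ...] = synthetic_data.DEFAULT_SECOND_SAMPLES


@dataclass
class TargetedConfig:
    df_threshold: float = 0.60
    df_mode: str = "quantified"
    force_include: tuple[str, ...] = ("Cotinine", "Progesterone")
    substitution: bool = True


@dataclass
class UntargetedConfig:
    n_features_pos: int = 120
    n_features_neg: int = 90
    blank_factor: float = 5.0
    pseudo: float = 0.1
    floor: float = 90000.0
    mz_tol: float = 0.002
    rt_tol_merge: float = 0.2
    rt_tol_dedup: float = 0.1
    r_threshold: float = 0.95
    p_threshold: float = 0.001
    df_threshold: float = 0.70
    is_components: int = 2
    normalization: str = "pca"


@dataclass
class AnnotationConfig:
    n_library_entries: int = 40
    bin_tol: float = 0.01
    rt_tol: float = 0.2
    precursor_tol: float = 0.01
    total_threshold: float = 700.0
    dot_threshold: float = 600.0


@dataclass
class AssociationConfig:
    alpha: float = 0.05
    literature_threshold: float = 0.005
    exposures: tuple[str, ...] = associations.EXPOSURES
    parous_subset: str = "pregnancies"
    max_untargeted_outcomes: int = 60  # cap the feature scan for desk-scale runs


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    targeted: TargetedConfig = field(default_factory=TargetedConfig)
    untargeted: UntargetedConfig = field(default_factory=UntargetedConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    associations: AssociationConfig = field(default_factory=AssociationConfig)
    output_dir: str | None = None

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        is_path = isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        )
        raw = yaml.safe_load(Path(source).read_text() if is_path else str(source))
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {
            "cohort": CohortConfig, "targeted": TargetedConfig,
            "untargeted": UntargetedConfig, "annotation": AnnotationConfig,
            "associations": AssociationConfig,
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key in sections:
                section_cls = sections[key]
                fields = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(value) - fields
                if unknown:
                    raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = section_cls(**coerced)
            elif key in {"seed", "output_dir"}:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """All stage outputs plus the run manifest."""

    cohort: synthetic_data.Cohort
    concentrations: target_quant.ConcentrationMatrix  # substituted, isomer-summed
    retained_targets: list[str]
    cleaned: feature_processing.CleanedFeatureMatrix
    annotations: pd.DataFrame
    target_results: pd.DataFrame
    group_results: pd.DataFrame
    feature_results: pd.DataFrame
    multiplicity: associations.MultiplicityDecision
    manifest: dict


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage in fixed order under one master seed."""
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()
    manifest: dict = {"seed": cfg.seed, "stages": {}, "counts": {}}

    # 1. cohort -----------------------------------------------------------
    cohort = synthetic_data.generate_cohort(
        cfg.cohort.n_women, cfg.cohort.strata, cfg.cohort.second_samples, seed=cfg.seed
    )
    manifest["counts"]["participants"] = cohort.n_women
    manifest["counts"]["samples"] = cohort.n_samples

    # 2. targeted quantification -----------------------------------------
    specs, mloqs, classes = synthetic_data.default_target_panel()
    truth_matrix, truth = synthetic_data.generate_target_truth(
        cohort, specs, mloqs, seed=cfg.seed, analyte_class=classes
    )
    cal_table, true_slopes = synthetic_data.generate_calibration_tables(
        list(specs), seed=cfg.seed
    )
    areas, is_areas = synthetic_data.generate_target_areas(
        truth_matrix, true_slopes, seed=cfg.seed
    )
    cals = synthetic_data.calibrations_from_table(cal_table)
    batches = cohort.samples["batch"].to_dict()
    measured = target_quant.quantify_matrix(
        areas, is_areas, cals, mloqs, batches=batches, analyte_class=classes
    )
    if cfg.targeted.substitution:
        measured = target_quant.substitute_censored(measured)
    summed = target_quant.sum_isomers_matrix(measured)
    retained = target_quant.select_targets(
        summed, cfg.targeted.df_threshold, cfg.targeted.force_include, cfg.targeted.df_mode
    )
    manifest["counts"]["target_analytes"] = len(summed.analytes)
    manifest["counts"]["targets_retained"] = len(retained)

    # 3. untargeted cleaning ----------------------------------------------
    library = synthetic_data.generate_spectral_library(
        cfg.annotation.n_library_entries, seed=cfg.seed
    )
    pos, neg, is_matrix = synthetic_data.generate_untargeted_tables(
        cohort,
        {"pos": cfg.untargeted.n_features_pos, "neg": cfg.untargeted.n_features_neg},
        seed=cfg.seed,
        library=library,
    )
    cleaned, funnel = feature_processing.clean_feature_tables(
        pos, neg, is_matrix,
        blank_factor=cfg.untargeted.blank_factor,
        mz_tol=cfg.untargeted.mz_tol,
        rt_tol_merge=cfg.untargeted.rt_tol_merge,
        is_components=cfg.untargeted.is_components,
        pseudo=cfg.untargeted.pseudo,
        floor=cfg.untargeted.floor,
        r_threshold=cfg.untargeted.r_threshold,
        p_threshold=cfg.untargeted.p_threshold,
        rt_tol_dedup=cfg.untargeted.rt_tol_dedup,
        df_threshold=cfg.untargeted.df_threshold,
        normalization=cfg.untargeted.normalization,
    )
    manifest["counts"]["feature_funnel"] = funnel

    # 4. annotation --------------------------------------------------------
    annotations = annotation.annotate_features(
        cleaned.meta, library,
        bin_tol=cfg.annotation.bin_tol, rt_tol=cfg.annotation.rt_tol,
        precursor_tol=cfg.annotation.precursor_tol,
        total_threshold=cfg.annotation.total_threshold,
        dot_threshold=cfg.annotation.dot_threshold,
    )
    manifest["counts"]["annotated"] = int(annotations["level"].isin([1, 2]).sum())
    manifest["counts"]["annotation_classes"] = annotation.class_counts(annotations)

    # 5. associations ------------------------------------------------------
    data = cohort.covariate_frame()
    conc_t = associations.transform_sqrt(summed.values.loc[retained].T)
    group_scores = associations.group_and_sum(conc_t)
    target_results = associations.association_scan(
        conc_t, data, cfg.associations.exposures
    )
    group_results = associations.association_scan(
        group_scores, data, cfg.associations.exposures
    )
    feat_cols = list(cleaned.areas.index[: cfg.associations.max_untargeted_outcomes])
    feat_t = associations.transform_sqrt(cleaned.areas.loc[feat_cols].T)
    feature_results = associations.association_scan(
        feat_t, data, cfg.associations.exposures
    )
    if len(feature_results) and feature_results["p_value"].notna().any():
        multiplicity = associations.adjust_multiplicity(
            feature_results["p_value"],
            cfg.associations.alpha, cfg.associations.literature_threshold,
        )
    else:  # vacuous filter: no untargeted outcome reached the model stage
        multiplicity = associations.MultiplicityDecision(
            cfg.associations.alpha, 0, cfg.associations.literature_threshold,
            float("nan"),
            pd.DataFrame(columns=["pass_alpha", "pass_literature", "pass_bonferroni"]),
        )
    manifest["counts"]["target_models"] = len(target_results)
    manifest["counts"]["feature_models"] = len(feature_results)
    manifest["stages"]["order"] = [
        "generate", "quantify", "clean", "annotate", "associate"
    ]
    manifest["wall_clock_s"] = round(time.perf_counter() - t0, 3)

    result = PipelineResult(
        cohort=cohort, concentrations=summed, retained_targets=retained,
        cleaned=cleaned, annotations=annotations,
        target_results=target_results, group_results=group_results,
        feature_results=feature_results, multiplicity=multiplicity,
        manifest=manifest,
    )
    if cfg.output_dir:
        write_outputs(result, cfg.output_dir)
    return result


def export_report(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Funnel, association and group summary tables from a finished run.

    The funnel table accounts for every feature at every gate
    (retained + removed = input); the association tables mirror the
    per-analyte and per-group coefficient layouts.
    """
    funnel = result.manifest["counts"]["feature_funnel"]
    stages = list(funnel)
    rows = []
    for prev, cur in zip(stages, stages[1:]):
        rows.append(
            {"stage": cur, "input": funnel[prev], "retained": funnel[cur],
             "removed": funnel[prev] - funnel[cur]}
        )
    funnel_table = pd.DataFrame(rows)

    def pivot(res: pd.DataFrame) -> pd.DataFrame:
        if res.empty:
            return res
        return res.pivot_table(
            index="outcome", columns="exposure", values=["coefficient", "p_value"]
        )

    return {
        "funnel": funnel_table,
        "target_associations": pivot(result.target_results),
        "group_associations": pivot(result.group_results),
        "volcano": result.feature_results.assign(
            neg_log10_p=lambda d: -np.log10(d["p_value"].astype(float))
        ).join(result.multiplicity.flags),
    }


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.cohort.write(out / "samples.tsv", out / "participants.tsv")
    result.concentrations.to_tidy().to_csv(out / "concentrations.tsv", sep="\t", index=False)
    pd.Series(result.retained_targets, name="analyte").to_csv(
        out / "retained_targets.tsv", sep="\t", index=False
    )
    result.cleaned.areas.to_csv(out / "cleaned_features.tsv", sep="\t")
    pd.DataFrame(result.cleaned.provenance).to_csv(out / "provenance.tsv", sep="\t", index=False)
    result.annotations.to_csv(out / "annotations.tsv", sep="\t")
    result.target_results.to_csv(out / "target_associations.tsv", sep="\t", index=False)
    result.group_results.to_csv(out / "group_associations.tsv", sep="\t", index=False)
    result.feature_results.to_csv(out / "feature_associations.tsv", sep="\t", index=False)
    report = export_report(result)
    report["funnel"].to_csv(out / "funnel.tsv", sep="\t", index=False)
    report["volcano"].to_csv(out / "volcano.tsv", sep="\t", index=False)
    yaml.safe_dump(result.manifest, (out / "manifest.yaml").open("w"), sort_keys=False)
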