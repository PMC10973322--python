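"""End-to-end pipeline: simulate -> segment -> extract -> screen -> train
-> evaluate -> sub-datasets, with a self-describing output directory."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .features import DiscretizationParams, INTENSITY_TEXTURE_FEATURES, extract_all
from .io import ensure_dir, write_table
from .modeling import BuiltModels, build_models
from .phantom import PhantomSpec, cohort_table, generate_cohort
from .screening import screen, zscore
from .segmentation import SegmentationParams, segment_muscle
from .subsets import evaluate_subsets

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "cohort_features"]


@dataclass
class PipelineConfig:
    out_dir: str | Path = "ctamuscle_run"
    n_mild: int = 36
    n_severe: int = 20
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    discretization: DiscretizationParams = field(default_factory=DiscretizationParams)
    alpha: float = 0.05
    lasso_folds: int = 10
    subset_k: int = 5
    seed: int = 0
    write_volumes: bool = False

    def validate(self) -> None:
        if self.n_mild < 1 or self.n_severe < 1:
            raise ValueError("n_mild and n_severe must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.subset_k < 1:
            raise ValueError("subset_k must be >= 1")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


@dataclass
class PipelineResult:
    subjects: pd.DataFrame
    features: pd.DataFrame
    screening: pd.DataFrame
    models: BuiltModels
    subset_metrics: pd.DataFrame
    out_dir: Path | None


def cohort_features(records, volumes, seg_params, disc, include_shape=True):
    """Segment every subject and extract the full feature vector."""
    masks, rows = [], []
    for rec, vol in zip(records, volumes):
        mask = segment_muscle(vol, seg_params)
        masks.append(mask)
        rows.append(extract_all(vol, mask, disc, include_shape=include_shape))
    feats = pd.DataFrame(rows, index=[r.subject_id for r in records])
    return masks, feats


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    t0 = time.time()
    out = ensure_dir(config.out_dir)
    (out / "config.json").write_text(config.to_json())

    stage = "simulate"
    try:
        records, volumes = generate_cohort(
            config.n_mild,
            config.n_severe,
            spec=config.phantom,
            seed=config.seed,
            out_dir=out / "volumes" if config.write_volumes else None,
        )
        subjects = cohort_table(records)

        stage = "segment/extract"
        masks, feats = cohort_features(
            records, volumes, config.segmentation, config.discretization
        )

        stage = "screen"
        groups = subjects["group"].to_numpy()
        intensity = feats[INTENSITY_TEXTURE_FEATURES]
        constant = intensity.columns[intensity.std(ddof=0) == 0].tolist()
        if constant:
            # e.g. histogram_Minimum: the window bound truncates every subject
            log.info("dropping %d zero-variance features: %s", len(constant), constant)
            intensity = intensity.drop(columns=constant)
        feats_z, ztf = zscore(intensity)
        screening_table = screen(feats_z, groups, alpha=config.alpha)
        selected = screening_table.index[screening_table["selected"]].tolist()
        if not selected:
            raise RuntimeError("screening selected no features")

        stage = "train"
        cta = subjects["cta_score"].to_numpy(dtype=float)
        cta_z = (cta - cta.mean()) / cta.std(ddof=0)
        models = build_models(
            feats_z[selected], cta_z, groups, seed=config.seed, folds=config.lasso_folds
        )

        stage = "subsets"
        subset_metrics = evaluate_subsets(
            volumes,
            masks,
            groups,
            {"LRM-I": models.lrm1, "LRM-II": models.lrm2},
            ztf,
            cta_z=cta_z,
            disc=config.discretization,
            k=config.subset_k,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    write_table(out / "subjects.csv", subjects)
    feats.reset_index(names="subject_id").pipe(lambda d: write_table(out / "features.csv", d))
    write_table(out / "screening.csv", screening_table.reset_index())
    write_table(out / "subset_metrics.csv", subset_metrics)
    (out / "models.json").write_text(json.dumps(models_to_dict(models), indent=2))
    (out / "run.log").write_text(
        f"ctamuscle {__version__}\nseed={config.seed}\n"
        f"n_mild={config.n_mild} n_severe={config.n_severe}\n"
        f"elapsed_s={time.time() - t0:.1f}\n"
    )
    return PipelineResult(
        subjects=subjects,
        features=feats,
        screening=screening_table,
        models=models,
        subset_metrics=subset_metrics,
        out_dir=out,
    )


def models_to_dict(models: BuiltModels) -> dict:
    def report(r):
        return {
            "variables": r.variables,
            "coefficients": r.coefficients,
            "constant": r.constant,
            "odds_ratios": r.odds_ratios,
            "or_ci": {k: list(v) for k, v in r.or_ci.items()},
            "p_values": r.p_values,
            "omnibus_p": r.omnibus_p,
            "hosmer_lemeshow_p": r.hosmer_lemeshow_p,
            "roc": None
            if r.roc is None
            else {
                "auc": r.roc.auc,
                "auc_ci": list(r.roc.auc_ci),
                "auc_p": r.roc.auc_p,
                "cutoff": r.roc.cutoff,
                "sensitivity": r.roc.sensitivity,
                "specificity": r.roc.specificity,
                "accuracy": r.roc.accuracy,
                "counts": {k: list(v) for k, v in r.roc.counts.items()},
            },
        }

    return {
        "LRM-I": report(models.lrm1),
        "LRM-II": report(models.lrm2),
        "cta_score": {
            "auc": models.cta_roc.auc,
            "auc_ci": list(models.cta_roc.auc_ci),
            "cutoff": models.cta_roc.cutoff,
        },
        "lasso": {
            "lambda_star": models.lasso.lambda_star,
            "cv_mse_at_star": list(models.lasso.mse_at_star),
            "selected": models.lasso.selected,
        },
    }
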