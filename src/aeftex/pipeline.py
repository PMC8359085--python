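"""End-to-end orchestration: simulate -> AEF -> features -> compare ->
select -> fit/score -> evaluate.

One :class:`PipelineConfig` (deserializable from JSON) drives the whole
run. Every intermediate artifact (NIfTI volumes, feature CSV, comparison
table, model JSON, evaluation report) is written under the output
directory, and a ``manifest.json`` records the package version, the seed,
a hash of the configuration and per-stage timings, so any numeric artifact
is traceable to config + seed. Reruns with the same config and seed
reproduce the artifacts bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aef import DEFAULT_CLIP_RANGE, DEFAULT_EPSILON_HU, compute_aef_map
from .cohort_stats import compare_groups_continuous
from .evaluation import calibration_curve, decision_curve, roc_analysis
from .io import load_multiphase, load_volume, read_manifest, write_cohort
from .modeling import (
    fit_logistic,
    lasso_select,
    spearman_filter,
    standardize,
)
from .roi_texture import (
    FEATURE_NAMES,
    ROIMask,
    TextureConfig,
    extract_features,
    largest_axial_plane,
    tumor_area,
)
from .synthetic_data import LABEL_SCHEMES, study_cohort_spec

logger = logging.getLogger("aeftex")

__all__ = ["PipelineConfig", "run_pipeline", "features_from_manifest", "compare_features"]


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-cohort analysis run."""

    out_dir: str
    seed: int = 0
    label_scheme: str = "improved"
    simulate: bool = True
    manifest: str | None = None  # existing cohort manifest when simulate=False
    epsilon: float = DEFAULT_EPSILON_HU
    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE
    texture: TextureConfig = field(default_factory=TextureConfig)
    filter_threshold: float = 0.9
    folds: int = 5
    grid_shape: tuple[int, int, int] = (16, 64, 64)

    def __post_init__(self) -> None:
        if not 0 < self.filter_threshold <= 1:
            raise ValueError("filter_threshold must lie in (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.label_scheme not in LABEL_SCHEMES:
            raise ValueError(f"unknown label_scheme {self.label_scheme!r}")
        if not self.simulate and self.manifest is None:
            raise ValueError("a manifest path is required when simulate=False")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "texture" in raw:
            raw["texture"] = TextureConfig(
                **{
                    k: tuple(tuple(d) for d in v) if k == "directions" else v
                    for k, v in raw["texture"].items()
                }
            )
        for key in ("clip_range", "grid_shape"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def features_from_manifest(
    manifest: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON_HU,
    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE,
    texture: TextureConfig | None = None,
) -> pd.DataFrame:
    """AEF + texture extraction for every subject in a cohort manifest."""
    texture = texture or TextureConfig()
    rows = []
    for rec in manifest.itertuples(index=False):
        try:
            mv = load_multiphase(rec.ctu, rec.cta, rec.ctp)
            mask, _ = load_volume(rec.mask)
            roi = ROIMask(mask=mask > 0.5, voxel_size=mv.voxel_size)
            aef = compute_aef_map(mv, epsilon=epsilon, clip_range=clip_range)
            fv = extract_features(aef, roi, texture)
            plane = largest_axial_plane(roi)
            row = {"subject_id": rec.subject_id, "label": rec.label}
            row["tumor_area_cm2"] = tumor_area(roi, plane)
            row.update(fv.values)
            rows.append(row)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for subject {rec.subject_id}: {exc}"
            ) from exc
    return pd.DataFrame(rows)


def compare_features(features: pd.DataFrame, positive_label: str) -> pd.DataFrame:
    """Between-group comparison of all 32 features (report-table shape)."""
    y = (features["label"] == positive_label).astype(int).to_numpy()
    rows = []
    for name in FEATURE_NAMES:
        x = features[name].to_numpy(dtype=float)
        gc = compare_groups_continuous(x[y == 1], x[y == 0], feature=name)
        rows.append(
            {
                "feature": name,
                "rank_mean_pos": gc.rank_mean[0],
                "rank_mean_neg": gc.rank_mean[1],
                "mean_pos": gc.mean[0],
                "mean_neg": gc.mean[1],
                "median_pos": gc.median[0],
                "median_neg": gc.median[1],
                "statistic": gc.statistic,
                "test": gc.statistic_kind,
                "p": gc.p,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run report.

    Stage failures abort with the stage name (and subject id where
    applicable); artifacts from completed stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    # -- simulate ----------------------------------------------------------
    t0 = stage("simulate")
    if config.simulate:
        spec = study_cohort_spec(
            label_scheme=config.label_scheme,
            seed=config.seed,
            grid_shape=config.grid_shape,
        )
        from .synthetic_data import generate_cohort

        cohort = generate_cohort(spec)
        manifest_path = write_cohort(cohort, out / "cohort")
    else:
        manifest_path = Path(config.manifest)
    manifest = read_manifest(manifest_path)
    timings["simulate"] = time.perf_counter() - t0

    # -- aef + features ----------------------------------------------------
    t0 = stage("features")
    features = features_from_manifest(
        manifest, epsilon=config.epsilon, clip_range=config.clip_range, texture=config.texture
    )
    features_path = out / "features.csv"
    features.to_csv(features_path, index=False)
    timings["features"] = time.perf_counter() - t0

    positive_label = LABEL_SCHEMES[config.label_scheme][0]

    # -- compare -----------------------------------------------------------
    t0 = stage("compare")
    comparison = compare_features(features, positive_label)
    comparison.to_csv(out / "comparison.csv", index=False)
    timings["compare"] = time.perf_counter() - t0

    # -- select + fit ------------------------------------------------------
    t0 = stage("model")
    y = (features["label"] == positive_label).astype(int).to_numpy()
    X = features[list(FEATURE_NAMES)]
    constant = [c for c in X.columns if X[c].std(ddof=1) == 0]
    X = X.drop(columns=constant)
    Xz, record = standardize(X)
    retained = spearman_filter(Xz, y, threshold=config.filter_threshold)
    selected, lasso_meta = lasso_select(
        Xz[retained], y, n_folds=config.folds, seed=config.seed
    )
    if selected:
        model = fit_logistic(
            Xz, y, selected, name="fitted", outcome=positive_label
        )
    else:
        model = None
    model_payload = {
        "dropped_constant": constant,
        "retained_after_filter": retained,
        "selected": selected,
        "standardization": {k: {"mean": m, "sd": s} for k, (m, s) in record.items()},
        "lasso": {k: lasso_meta[k] for k in ("chosen_lambda", "n_folds", "seed")},
    }
    if model is not None:
        model_payload["model"] = json.loads(model.to_json())
    (out / "model.json").write_text(json.dumps(model_payload, indent=1))
    timings["model"] = time.perf_counter() - t0

    # -- score + evaluate --------------------------------------------------
    t0 = stage("evaluate")
    evaluation: dict = {}
    if model is not None:
        lp = model.intercept + sum(
            coef * Xz[f].to_numpy() for f, coef in model.coefficients.items()
        )
        prob = 1.0 / (1.0 + np.exp(-lp))
        pd.DataFrame(
            {"subject_id": features["subject_id"], "lp": lp, "prob": prob, "y": y}
        ).to_csv(out / "scores.csv", index=False)
        roc = roc_analysis(prob, y)
        nb = decision_curve(prob, y)
        evaluation = {
            "cutoff_rule": roc.cutoff_rule,
            "roc": {
                "auc": roc.auc,
                "cutoff": roc.cutoff,
                "accuracy": roc.accuracy,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            },
            "decision_curve": {
                "thresholds": nb.thresholds.tolist(),
                "model": nb.model.tolist(),
                "treat_all": nb.treat_all.tolist(),
            },
        }
        try:
            cal = calibration_curve(prob, y, n_bins=min(10, y.size // 2))
            evaluation["calibration"] = {
                "slope": cal.slope,
                "intercept": cal.intercept,
                "bin_pred_mean": cal.bin_pred_mean.tolist(),
                "bin_obs_rate": cal.bin_obs_rate.tolist(),
            }
        except Exception as exc:
            evaluation["calibration"] = {"error": str(exc)}
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=1))
    timings["evaluate"] = time.perf_counter() - t0

    report.update(
        {
            "version": __version__,
            "n_subjects": int(len(features)),
            "positive_label": positive_label,
            "timings_s": timings,
            "artifacts": {
                "manifest": str(manifest_path),
                "features": str(features_path),
                "comparison": str(out / "comparison.csv"),
                "model": str(out / "model.json"),
                "evaluation": str(out / "evaluation.json"),
            },
            "selected_features": selected,
            "evaluation": evaluation,
        }
    )
    (out / "manifest.json").write_text(json.dumps(report, indent=1))
    return report
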