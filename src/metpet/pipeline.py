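"""End-to-end reproducible runs: simulate → segment → texture → select → survival.

A run is driven by one JSON/YAML config (unknown keys rejected, every value
range-checked) whose defaults reproduce the reference analysis settings:
1.3× reference-SUVmean delineation threshold, 10 mm reference ROI, 64 gray
levels, feature reduction to k = 6 cluster representatives, and
dichotomization cutoffs 0.088 (LGRE) and 1.074 (GLCM correlation) for the
Kaplan–Meier comparisons.  Units are fixed pipeline-wide: mm for spacing,
mL for MTV, months for survival, Bq and g for dose and weight.

Each stage reads and writes only declared files under the run directory,
so any stage can be re-run from its inputs; a manifest records the config
snapshot, software version, warnings, and SHA-256 hashes of all data
artifacts (re-running with the same config and seed reproduces the hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .io import load_activity_volume, load_dose_info, save_volume
from .phantom import CohortSpec, default_reference_center, generate_cohort, write_cohort
from .segmentation import ReferenceROI, reference_suvmean, segment_tumor, to_suv
from .selection import cluster_features, render_heatmap, select_representatives, standardize
from .survival import (
    dichotomize,
    encode_clinical,
    log_rank,
    multivariate_models,
    plot_km,
    univariate_screen,
)
from .texture import FEATURE_NAMES, extract_all

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline"]

log = logging.getLogger("metpet")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Section):
    simulate: bool = True
    segment: bool = True
    texture: bool = True
    select: bool = True
    survival: bool = True


class CohortSection(_Section):
    n_subjects: int = Field(40, ge=2)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_uptake_range: tuple[float, float] = (2.2, 4.2)
    tumor_radius_range: tuple[float, float] = (18.0, 24.0)
    field_corr_length_range: tuple[float, float] = (0.0, 8.0)
    field_sd: float = Field(0.25, ge=0)
    n_foci_range: tuple[int, int] = (0, 4)
    focus_radius_range: tuple[float, float] = (2.5, 4.0)
    focus_uptake_range: tuple[float, float] = (0.3, 0.8)
    beta_necrosis: float = 1.2
    beta_corr: float = 0.8
    baseline_hazard: float = Field(0.02, gt=0)
    censor_rate: float = Field(0.3, ge=0, lt=1)
    max_followup: float = Field(60.0, gt=0)


class SegmentationSection(_Section):
    threshold_multiple: float = Field(1.3, gt=0)
    roi_diameter_mm: float = Field(10.0, gt=0)


class TextureSection(_Section):
    n_levels: int = Field(64, ge=2)
    distance: int = Field(1, ge=1)
    fill_boundary_holes: bool = True


class SelectionSection(_Section):
    k: int = Field(6, ge=1)
    linkage: Literal["average", "complete", "single", "ward"] = "average"


class SurvivalSection(_Section):
    texture_features: tuple[str, ...] = ("glrlm_lgre", "glcm_correlation")
    cutoffs: dict[str, float] = Field(
        default_factory=lambda: {"glrlm_lgre": 0.088, "glcm_correlation": 1.074}
    )
    genetic_reference: str = "codel"
    univariate_candidates: tuple[str, ...] = (
        "age",
        "sex",
        "who_grade",
        "genetic_status",
        "tnr",
        "mtv_ml",
        "tlmu",
    )


class RunConfig(_Section):
    """Full pipeline configuration; defaults reproduce the reference settings."""

    seed: int = 0
    out_dir: str = "metpet_run"
    input_dir: str | None = None  # cohort directory when simulate is disabled
    stages: StageToggles = Field(default_factory=StageToggles)
    cohort: CohortSection = Field(default_factory=CohortSection)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    texture: TextureSection = Field(default_factory=TextureSection)
    selection: SelectionSection = Field(default_factory=SelectionSection)
    survival: SurvivalSection = Field(default_factory=SurvivalSection)


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    config: dict
    version: str
    started: str
    finished: str = ""
    stage_seconds: dict[str, float] = Field(default_factory=dict)
    artifact_hashes: dict[str, str] = Field(default_factory=dict)
    warnings: list[str] = Field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Parse, default, and range-check a JSON/YAML config file.

    An empty (or absent) file yields the full defaults; unknown keys and
    out-of-range values raise with the offending key named.
    """
    payload: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML superset: also parses JSON
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        payload = loaded
    if overrides:
        payload = _deep_merge(payload, overrides)
    try:
        return RunConfig(**payload)
    except ValidationError as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order; returns the run manifest.

    Any stage error aborts the run, with the manifest (including the failure
    point) still written to ``out_dir/manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.model_dump(mode="json"),
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    cohort_dir = Path(config.input_dir) if config.input_dir else out / "cohort"
    if not config.stages.simulate and (
        not cohort_dir.exists() or not (cohort_dir / "cohort.csv").exists()
    ):
        manifest.failed_stage = "validate"
        manifest.error = f"simulate stage disabled and no cohort found at {cohort_dir}"
        _write_manifest(manifest, out)
        raise FileNotFoundError(manifest.error)

    stage_fns = [
        ("simulate", _stage_simulate),
        ("segment", _stage_segment),
        ("texture", _stage_texture),
        ("select", _stage_select),
        ("survival", _stage_survival),
    ]
    ctx = {"out": out, "cohort_dir": cohort_dir, "config": config, "manifest": manifest}
    for name, fn in stage_fns:
        if not getattr(config.stages, name):
            log.info("stage %s: skipped", name)
            continue
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            fn(ctx)
        except Exception as exc:
            manifest.failed_stage = name
            manifest.error = f"{type(exc).__name__}: {exc}"
            _write_manifest(manifest, out)
            raise
        manifest.stage_seconds[name] = round(time.time() - t0, 3)
        log.info("stage %s: done in %.1fs", name, manifest.stage_seconds[name])

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.suffix in {".csv", ".json", ".nii"} and p.name != "manifest.json":
            manifest.artifact_hashes[str(p.relative_to(out))] = _sha256(p)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: RunManifest, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest.model_dump(), indent=2))


def _stage_simulate(ctx: dict) -> None:
    config: RunConfig = ctx["config"]
    c = config.cohort
    spec = CohortSpec(seed=config.seed, **c.model_dump())
    subjects = generate_cohort(spec)
    write_cohort(subjects, ctx["cohort_dir"])
    (ctx["cohort_dir"] / "cohort_spec.json").write_text(
        json.dumps({"seed": config.seed, **c.model_dump(mode="json")}, indent=2)
    )


def _load_subject_ids(cohort_dir: Path) -> list[str]:
    return pd.read_csv(cohort_dir / "cohort.csv")["subject_id"].astype(str).tolist()


def _stage_segment(ctx: dict) -> None:
    config: RunConfig = ctx["config"]
    cohort_dir: Path = ctx["cohort_dir"]
    out: Path = ctx["out"]
    mask_dir = out / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in _load_subject_ids(cohort_dir):
        vol = load_activity_volume(cohort_dir / "volumes" / f"{sid}.nii")
        sidecar = json.loads((cohort_dir / "volumes" / f"{sid}.json").read_text())
        dose = load_dose_info(cohort_dir / "volumes" / f"{sid}.json")
        suv = to_suv(vol, dose)
        roi = ReferenceROI(
            center=tuple(sidecar["reference_center"]), diameter_mm=config.segmentation.roi_diameter_mm
        )
        ref = reference_suvmean(suv, roi)
        seg = segment_tumor(
            suv, ref, threshold_multiple=config.segmentation.threshold_multiple
        )
        save_volume(seg.mask.astype(np.uint8), suv.voxel_spacing, mask_dir / f"{sid}_mask.nii")
        ctx["manifest"].warnings.extend(f"{sid}: {w}" for w in seg.warnings)
        rows.append(
            {
                "subject_id": sid,
                "reference_suvmean": seg.reference_suvmean,
                "suvmax": seg.suvmax,
                "suvmean": seg.suvmean,
                "tnr": seg.tnr,
                "mtv_ml": seg.mtv_ml,
                "tlmu": seg.tlmu,
            }
        )
    pd.DataFrame(rows).to_csv(out / "segmentation_metrics.csv", index=False)


def _stage_texture(ctx: dict) -> None:
    config: RunConfig = ctx["config"]
    cohort_dir: Path = ctx["cohort_dir"]
    out: Path = ctx["out"]
    metrics = pd.read_csv(out / "segmentation_metrics.csv").set_index("subject_id")
    rows = []
    for sid in _load_subject_ids(cohort_dir):
        vol = load_activity_volume(cohort_dir / "volumes" / f"{sid}.nii")
        dose = load_dose_info(cohort_dir / "volumes" / f"{sid}.json")
        suv = to_suv(vol, dose)
        ref = float(metrics.loc[sid, "reference_suvmean"])
        seg = segment_tumor(suv, ref, threshold_multiple=config.segmentation.threshold_multiple)
        fv = extract_all(
            seg,
            suv,
            n_levels=config.texture.n_levels,
            distance=config.texture.distance,
            fill_boundary_holes=config.texture.fill_boundary_holes,
        )
        ctx["manifest"].warnings.extend(f"{sid}: {w}" for w in fv.warnings)
        rows.append({"subject_id": sid, **fv.values})
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
    (out / "feature_manifest.json").write_text(
        json.dumps({"n_features": len(FEATURE_NAMES), "features": list(FEATURE_NAMES)}, indent=2)
    )


def _stage_select(ctx: dict) -> None:
    config: RunConfig = ctx["config"]
    out: Path = ctx["out"]
    table = pd.read_csv(out / "features.csv").set_index("subject_id")
    std = standardize(table)
    cr = cluster_features(std, linkage=config.selection.linkage, k=config.selection.k)
    cr = select_representatives(cr, std)
    (out / "selection.json").write_text(json.dumps(cr.to_dict(), indent=2))
    render_heatmap(std, cr, out / "heatmap.png")


def _stage_survival(ctx: dict) -> None:
    config: RunConfig = ctx["config"]
    cohort_dir: Path = ctx["cohort_dir"]
    out: Path = ctx["out"]
    surv_dir = out / "survival"
    surv_dir.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(cohort_dir / "cohort.csv")
    features = pd.read_csv(out / "features.csv")
    metrics = pd.read_csv(out / "segmentation_metrics.csv")
    df = cohort.merge(metrics, on="subject_id").merge(features, on="subject_id")
    df = encode_clinical(df, genetic_reference=config.survival.genetic_reference)
    df.to_csv(surv_dir / "merged.csv", index=False)

    candidates = list(config.survival.univariate_candidates) + list(
        config.survival.texture_features
    )
    uni = univariate_screen(df, candidates)
    uni.to_csv(surv_dir / "univariate.csv")

    summary: dict = {"univariate": json.loads(uni.to_json(orient="index")), "multivariate": {}}
    for feat in config.survival.texture_features:
        try:
            fits = multivariate_models(df, feat)
        except Exception as exc:  # keep other features' tables
            ctx["manifest"].warnings.append(f"multivariate models for {feat} failed: {exc}")
            continue
        rows = []
        for model, fit in fits.items():
            for cov in fit.summary.index:
                rows.append(
                    {
                        "model": model,
                        "covariate": cov,
                        "hr": fit.hr(cov),
                        "ci_lower": float(fit.summary.loc[cov, "ci_lower"]),
                        "ci_upper": float(fit.summary.loc[cov, "ci_upper"]),
                        "p": fit.p(cov),
                        "model_lr_chi2": fit.lr_chi2,
                        "model_lr_p": fit.lr_p,
                    }
                )
        pd.DataFrame(rows).to_csv(surv_dir / f"multivariate_{feat}.csv", index=False)
        summary["multivariate"][feat] = rows

        cutoff = config.survival.cutoffs.get(feat)
        if cutoff is not None:
            groups = dichotomize(df, feat, cutoff)
            if groups.nunique() == 2 and df["event"].sum() >= 1:
                lr = log_rank(df, groups)
                summary.setdefault("km", {})[feat] = {
                    "cutoff": cutoff,
                    "chi2": lr.chi2,
                    "p": lr.p,
                    "group_sizes": groups.value_counts().to_dict(),
                }
                plot_km(df, groups, surv_dir / f"km_{feat}.png", title=f"{feat} @ {cutoff:g}")
            else:
                ctx["manifest"].warnings.append(
                    f"cutoff {cutoff} for {feat} leaves one group; KM comparison skipped"
                )
    (surv_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
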