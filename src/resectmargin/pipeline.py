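"""End-to-end orchestration: localization -> segmentation -> matching -> registration -> margin/TRE.

The driver mirrors the clinical workflow: both scans are resampled to 1 mm
isotropic, lungs are segmented, the post-operative scan is affinely localized
onto the pre-operative one, vessel trees are segmented and matched in two
phases, matched centerline points become TPS control points, and the
resulting displacement field warps the post-operative lung for margin
measurement (and is evaluated with TRE when landmark pairs are supplied).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigurationError, PipelineError, ResectMarginError
from .imaging import BinaryMask, ImageVolume, read_volume, resample_isotropic, write_volume
from .localization import AffineTransform, apply_affine, register_affine_masks
from .margin_eval import (
    LandmarkPair,
    MarginResult,
    TREReport,
    compute_tre,
    measure_margin,
    read_landmarks,
)
from .matching import (
    FeaturePointSet,
    MatchResult,
    build_feature_points,
    match_trees,
)
from .registration import (
    DisplacementField,
    RegistrationParams,
    build_displacement_field,
    warp_with_field,
    write_field,
)
from .segmentation import (
    VesselFilterConfig,
    extract_subvascular_trees,
    segment_lungs,
    segment_tumor,
    segment_vessel_tree,
)

log = logging.getLogger("resectmargin")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults reproduce the published constants."""

    target_spacing: float = 1.0  # mm isotropic grid
    lung_smoothing_sigma: float = 1.0  # mm, before the -775 HU threshold
    vessel: VesselFilterConfig = dc_field(default_factory=VesselFilterConfig)
    lung_erosion_mm: float = 4.0
    tree_min_voxels: int = 250
    dsc_target_min: float = 0.5
    dsc_surround_min: float = 0.2
    dscp_min: float = 0.3
    crop_size: int = 60
    centroid_gate_mm: float = 30.0
    dilation_mm: float = 3.0
    cpd_w: float = 0.1
    cpd_beta: float = 2.0
    cpd_lam: float = 3.0
    confidence_min: float = 0.5
    registration: RegistrationParams = dc_field(default_factory=RegistrationParams)
    resection_band_mm: float = 2.0
    # the surgical neighbourhood (missing from the post scan) is excluded
    # from the localization metric within this radius of the tumor; 0 disables
    localization_exclude_radius_mm: float = 50.0
    compare_baseline: bool = False  # also build the all-control-point TPS field
    seed: int = 0  # no randomness in the core path; recorded for provenance

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "vessel" in d and isinstance(d["vessel"], dict):
            d["vessel"] = VesselFilterConfig(**d["vessel"])
        if "registration" in d and isinstance(d["registration"], dict):
            d["registration"] = RegistrationParams(**d["registration"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    """Artifacts of one case run (all on the pre-operative 1 mm grid)."""

    pre_volume: ImageVolume
    post_volume_localized: ImageVolume
    pre_lung: BinaryMask
    post_lung_localized: BinaryMask
    affine: AffineTransform
    tumor: BinaryMask
    pre_vessels: BinaryMask
    post_vessels: BinaryMask
    pre_trees: list
    post_trees: list
    match_result: MatchResult
    feature_points: FeaturePointSet
    field: DisplacementField
    warped_post_lung: BinaryMask
    margin: MarginResult
    tre: TREReport | None = None
    tre_baseline: TREReport | None = None
    baseline_field: DisplacementField | None = None
    report: dict = dc_field(default_factory=dict)


def _stage(name: str):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline_volumes(
    pre_vol: ImageVolume,
    post_vol: ImageVolume,
    tumor_seed: tuple[int, int, int] | None = None,
    tumor_mask: BinaryMask | None = None,
    landmarks: list[LandmarkPair] | None = None,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full workflow on in-memory volumes.

    The tumor is supplied either as a seed voxel index on the resampled
    pre-operative grid (semi-automatic segmentation) or as a ready mask.
    Landmark post points are given in the *original* post-operative space and
    are carried through the affine localization before TRE evaluation.
    """
    cfg = cfg or PipelineConfig()
    if tumor_seed is None and tumor_mask is None:
        raise ConfigurationError("either tumor_seed or tumor_mask is required")

    t0 = _stage("resample to isotropic grid")
    pre = resample_isotropic(pre_vol, cfg.target_spacing)
    post = resample_isotropic(post_vol, cfg.target_spacing)

    _stage("lung segmentation")
    pre_lung = segment_lungs(pre, cfg.lung_smoothing_sigma)
    post_lung = segment_lungs(post, cfg.lung_smoothing_sigma)

    _stage("affine localization")
    exclude = None
    if cfg.localization_exclude_radius_mm > 0:
        if tumor_mask is not None:
            center = tumor_mask.centroid_mm()
        else:
            center = pre.index_to_world(np.asarray(tumor_seed, dtype=float))[0]
        zz, yy, xx = np.meshgrid(
            *[np.arange(n, dtype=np.float32) for n in pre.shape], indexing="ij"
        )
        sp = np.asarray(pre.spacing)
        og = np.asarray(pre.origin)
        d2 = (
            (og[0] + zz * sp[0] - center[0]) ** 2
            + (og[1] + yy * sp[1] - center[1]) ** 2
            + (og[2] + xx * sp[2] - center[2]) ** 2
        )
        exclude = BinaryMask(
            d2 <= cfg.localization_exclude_radius_mm**2, pre.spacing, pre.origin
        )
    affine = register_affine_masks(pre_lung, post_lung, exclude=exclude)
    post_loc = apply_affine(post, affine, pre)
    post_lung_loc = apply_affine(post_lung, affine, pre)

    _stage("tumor segmentation")
    if tumor_mask is not None:
        if not tumor_mask.same_grid(pre):
            raise ConfigurationError("tumor mask must be on the resampled pre grid")
        tumor = tumor_mask
    else:
        tumor = segment_tumor(pre, pre_lung, tumor_seed, cfg.vessel)

    _stage("vessel tree segmentation")
    pre_vessels = segment_vessel_tree(pre, pre_lung, cfg.vessel, cfg.lung_erosion_mm)
    post_vessels = segment_vessel_tree(
        post_loc, post_lung_loc, cfg.vessel, cfg.lung_erosion_mm
    )
    pre_trees = extract_subvascular_trees(pre_vessels, cfg.tree_min_voxels)
    post_trees = extract_subvascular_trees(post_vessels, cfg.tree_min_voxels)
    if not pre_trees or not post_trees:
        raise PipelineError("no subvascular trees found in one of the scans")

    _stage("two-phase tree matching")
    match_result = match_trees(
        pre_trees,
        post_trees,
        pre_vessels,
        post_vessels,
        dsc_target_min=cfg.dsc_target_min,
        dsc_surround_min=cfg.dsc_surround_min,
        centroid_gate_mm=cfg.centroid_gate_mm,
        crop_size=cfg.crop_size,
        cpd_w=cfg.cpd_w,
        dscp_min=cfg.dscp_min,
        dilation_mm=cfg.dilation_mm,
    )

    _stage("feature point extraction")
    fps = build_feature_points(
        match_result,
        pre_trees,
        post_trees,
        confidence_min=cfg.confidence_min,
        beta=cfg.cpd_beta,
        lam=cfg.cpd_lam,
        cpd_w=cfg.cpd_w,
    )

    _stage("displacement field construction")
    disp_field = build_displacement_field(fps, tumor, pre_lung, cfg.registration)

    _stage("margin measurement")
    warped_post_lung = warp_with_field(post_lung_loc, disp_field)
    margin = measure_margin(
        warped_post_lung, tumor, pre_lung, cfg.resection_band_mm
    )

    tre = tre_baseline = None
    baseline_field = None
    if landmarks:
        _stage("TRE evaluation")
        localized = [
            LandmarkPair(
                lm.pre_point, affine.apply_points(lm.post_point)[0], lm.label
            )
            for lm in landmarks
        ]
        tre = compute_tre(localized, disp_field)
        if cfg.compare_baseline:
            baseline_field = build_displacement_field(
                fps, tumor, pre_lung, cfg.registration, all_points=True
            )
            tre_baseline = compute_tre(localized, baseline_field)

    result = PipelineResult(
        pre_volume=pre,
        post_volume_localized=post_loc,
        pre_lung=pre_lung,
        post_lung_localized=post_lung_loc,
        affine=affine,
        tumor=tumor,
        pre_vessels=pre_vessels,
        post_vessels=post_vessels,
        pre_trees=pre_trees,
        post_trees=post_trees,
        match_result=match_result,
        feature_points=fps,
        field=disp_field,
        warped_post_lung=warped_post_lung,
        margin=margin,
        tre=tre,
        tre_baseline=tre_baseline,
        baseline_field=baseline_field,
    )
    result.report = build_report(result, cfg)
    log.info("pipeline complete in %.1f s", time.time() - t0)
    return result


def build_report(result: PipelineResult, cfg: PipelineConfig) -> dict:
    """Structured per-case report mirroring the published table schema."""
    counts = result.match_result.counts
    report = {
        "config": cfg.to_dict(),
        "affine": result.affine.to_dict(),
        "matching": {
            "total_post_trees": counts.get("total_post", 0),
            "total_pre_trees": counts.get("total_pre", 0),
            "phase_I": {
                "matched": counts.get("phase1_matched", 0),
                "unmatched": counts.get("phase1_unmatched", 0),
            },
            "phase_II": {
                "matched": counts.get("phase2_matched", 0),
                "unmatched": counts.get("phase2_unmatched", 0),
            },
            "pairs": [
                {
                    "post": c.post_tree_id,
                    "pre": c.pre_tree_id,
                    "phase": c.phase,
                    "dsc_target": round(float(c.dsc_target), 6),
                    "dscp": None if np.isnan(c.dscp) else round(float(c.dscp), 6),
                }
                for c in result.match_result.pairs
            ],
        },
        "feature_points": int(len(result.feature_points)),
        "margin": {
            "distance_mm": round(float(result.margin.distance), 6),
            "printed": result.margin.sentinel,
            "overlap": bool(result.margin.overlap),
            "resection_voxels": int(result.margin.resection_region.count()),
        },
    }
    if result.tre is not None:
        report["tre"] = {k: round(v, 6) if isinstance(v, float) else v for k, v in result.tre.to_dict().items()}
    if result.tre_baseline is not None:
        report["tre_all_control_points_baseline"] = {
            k: round(v, 6) if isinstance(v, float) else v
            for k, v in result.tre_baseline.to_dict().items()
        }
    return report


def write_report(report: dict, out_dir: str) -> None:
    """Deterministic JSON + CSV summary row."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    import csv

    m = report["matching"]
    row = {
        "total_trees": m["total_post_trees"],
        "phase1_matched": m["phase_I"]["matched"],
        "phase1_unmatched": m["phase_I"]["unmatched"],
        "phase2_matched": m["phase_II"]["matched"],
        "phase2_unmatched": m["phase_II"]["unmatched"],
        "feature_points": report["feature_points"],
        "margin_mm": report["margin"]["printed"],
    }
    if "tre" in report:
        row.update(
            tre_mean_mm=report["tre"]["mean_mm"],
            tre_sd_mm=report["tre"]["sd_mm"],
            tre_max_mm=report["tre"]["max_mm"],
            tre_min_mm=report["tre"]["min_mm"],
        )
    with open(os.path.join(out_dir, "report.csv"), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(row))
        writer.writeheader()
        writer.writerow(row)


def run_pipeline(
    pre_path: str,
    post_path: str,
    out_dir: str,
    tumor_seed: tuple[int, int, int] | None = None,
    tumor_mask_path: str | None = None,
    landmarks_path: str | None = None,
    cfg: PipelineConfig | None = None,
    save_artifacts: bool = True,
) -> PipelineResult:
    """File-based entry point: read inputs, run, persist artifacts and report."""
    cfg = cfg or PipelineConfig()
    pre_vol = read_volume(pre_path)
    post_vol = read_volume(post_path)
    tumor_mask = None
    if tumor_mask_path is not None:
        tm = read_volume(tumor_mask_path)
        tumor_mask = resample_isotropic(
            BinaryMask(tm.data > 0.5, tm.spacing, tm.origin), cfg.target_spacing
        )
    landmarks = read_landmarks(landmarks_path) if landmarks_path else None
    try:
        result = run_pipeline_volumes(
            pre_vol, post_vol, tumor_seed, tumor_mask, landmarks, cfg
        )
    except ResectMarginError as exc:
        log.error("pipeline aborted: %s (%s)", exc, exc.code)
        raise
    os.makedirs(out_dir, exist_ok=True)
    write_report(result.report, out_dir)
    if save_artifacts:
        write_volume(result.pre_lung, os.path.join(out_dir, "pre_lung.nii.gz"))
        write_volume(
            result.post_lung_localized, os.path.join(out_dir, "post_lung_localized.nii.gz")
        )
        write_volume(result.tumor, os.path.join(out_dir, "tumor.nii.gz"))
        write_volume(result.pre_vessels, os.path.join(out_dir, "pre_vessels.nii.gz"))
        write_volume(result.post_vessels, os.path.join(out_dir, "post_vessels.nii.gz"))
        write_volume(
            result.warped_post_lung, os.path.join(out_dir, "warped_post_lung.nii.gz")
        )
        result.feature_points.to_csv(os.path.join(out_dir, "feature_points.csv"))
        write_field(result.field, os.path.join(out_dir, "displacement_field.nii.gz"))
        with open(os.path.join(out_dir, "affine.json"), "w") as fh:
            json.dump(result.affine.to_dict(), fh, indent=2, sort_keys=True)
    return result
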