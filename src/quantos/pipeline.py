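"""Configuration, orchestration and reproducible end-to-end runs.

A run is described by a validated :class:`RunConfig` (YAML-serializable);
every stage writes its artifacts plus a manifest recording inputs, the
config hash, seeds, package versions and output checksums, so any published
table is regenerable from its manifest alone. One global seed fans out to
per-stage seeds derived by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .classifier import (
    ClassModel,
    build_class_model,
    calibrate_random_factor,
    classify_scene,
    score_maturity,
)
from .features import measure_rois
from .imaging import (
    ImageStack,
    SegmentationConfig,
    extract_rois_dapi,
    extract_rois_postsynaptic,
    extract_rois_presynaptic,
    rois_to_table,
    z_project_mean,
)
from .postanalysis import average_synapse, match_ground_truth, radial_profile, roc_auc
from .statmodels import McmcConfig, fit_gompertz, fit_merg_gamma, fit_robust_t
from .synthetic import SceneConfig, generate_scene

__all__ = ["RunConfig", "run_pipeline", "extract_scene_features"]

Stage = Literal["simulate", "train", "classify", "maturity", "average", "roc", "stats"]

_EXTRACTORS = {
    "pre": extract_rois_presynaptic,
    "post": extract_rois_postsynaptic,
    "dapi": extract_rois_dapi,
}


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    pixel_size: float = 0.1
    n_planes: int = 5
    seed: int = 0
    out_dir: str = "quantos_out"
    # inputs
    pre_path: Optional[str] = None
    post_path: Optional[str] = None
    dapi_path: Optional[str] = None
    mask_path: Optional[str] = None
    model_path: Optional[str] = None
    truth_path: Optional[str] = None
    synapse_table: Optional[str] = None
    data_table: Optional[str] = None
    # classifier options
    max_dist: float = 1.2
    window: float = 5.0
    threshold: float = 0.5
    subset: Literal["all", "signal", "morphology", "geometry", "distance"] = "all"
    resolve: Literal["none", "one_to_one"] = "none"
    # segmentation overrides per channel: {"pre": {"tolerance": 8.0}, ...}
    segmentation: dict = Field(default_factory=dict)
    # synthetic scene overrides
    scene: dict = Field(default_factory=dict)
    # stats options
    stats_model: Literal["gompertz", "merg", "robust"] = "gompertz"
    mcmc: dict = Field(default_factory=dict)

    @field_validator("pixel_size", "max_dist", "window")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    def seg_config(self, channel: str) -> SegmentationConfig:
        return SegmentationConfig(**self.segmentation.get(channel, {}))

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, stage: str, log: dict) -> dict:
    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stage": stage,
        "quantos_version": __version__,
        "config": cfg.model_dump(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "log": log,
        "outputs": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _load_projected(path: str, cfg: RunConfig, role: str) -> np.ndarray:
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    stack = ImageStack(planes=np.asarray(planes, dtype=float),
                       pixel_size=cfg.pixel_size, role=role)  # type: ignore[arg-type]
    n = min(cfg.n_planes, stack.n_planes)
    return z_project_mean(stack, n)


def extract_scene_features(
    images: dict,
    cfg: RunConfig,
) -> dict:
    """ROI extraction + measurement for each provided channel image."""
    out = {}
    for role, img in images.items():
        rois = _EXTRACTORS[role](img, cfg.seg_config(role))
        feats = measure_rois(img, rois, channel=role)
        out[role] = {"rois": rois, "features": feats, "image": img}
    return out


def run_pipeline(cfg: RunConfig, stage: Stage) -> dict:
    """Execute one stage and return its manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {}

    if stage == "simulate":
        scene_cfg = SceneConfig(**{"seed": cfg.stage_seed("simulate"),
                                   "pixel_size": cfg.pixel_size, **cfg.scene})
        scene = generate_scene(scene_cfg)
        for role, stack in scene.stacks.items():
            tifffile.imwrite(out / f"{role}.tif", stack.planes.astype(np.float32))
        scene.synapses.to_csv(out / "truth_synapses.csv", index=False)
        scene.noise_pre.to_csv(out / "truth_noise_pre.csv", index=False)
        scene.noise_post.to_csv(out / "truth_noise_post.csv", index=False)
        scene.nuclei.to_csv(out / "truth_nuclei.csv", index=False)
        tifffile.imwrite(out / "opl_mask.tif",
                         scene.opl_mask_image().astype(np.uint8) * 255)
        with open(out / "scene_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(scene_cfg), fh)
        log["n_synapses"] = int(len(scene.synapses))

    elif stage == "train":
        for need in ("pre_path", "post_path", "mask_path"):
            if getattr(cfg, need) is None:
                raise ValueError(f"train stage requires {need}")
        pre_img = _load_projected(cfg.pre_path, cfg, "pre")
        post_img = _load_projected(cfg.post_path, cfg, "post")
        mask = tifffile.imread(cfg.mask_path) > 0
        data = extract_scene_features({"pre": pre_img, "post": post_img}, cfg)
        masks = []
        for role in ("pre", "post"):
            f = data[role]["features"]
            ys = np.clip(f["ym"].round().astype(int), 0, mask.shape[0] - 1)
            xs = np.clip(f["xm"].round().astype(int), 0, mask.shape[1] - 1)
            masks.append(np.asarray(mask[ys, xs]))
            rois_to_table(data[role]["rois"], role).to_csv(
                out / f"rois_{role}.csv", index=False)
            f.to_csv(out / f"features_{role}.csv", index=False)
        model = build_class_model(
            data["pre"]["features"], data["post"]["features"],
            (masks[0], masks[1]), cfg.pixel_size, max_dist=cfg.max_dist,
            provenance={"pre": cfg.pre_path, "post": cfg.post_path,
                        "mask": cfg.mask_path},
        )
        model.to_json(out / "model.json")
        log["n_pre_rois"] = int(len(data["pre"]["features"]))
        log["n_post_rois"] = int(len(data["post"]["features"]))

    elif stage == "classify":
        for need in ("pre_path", "post_path", "model_path"):
            if getattr(cfg, need) is None:
                raise ValueError(f"classify stage requires {need}")
        model = ClassModel.from_json(cfg.model_path)
        prior = calibrate_random_factor(
            max_dist=cfg.max_dist, window=cfg.window,
            seed=cfg.stage_seed("prior"))
        pre_img = _load_projected(cfg.pre_path, cfg, "pre")
        post_img = _load_projected(cfg.post_path, cfg, "post")
        data = extract_scene_features({"pre": pre_img, "post": post_img}, cfg)
        scored, synapses = classify_scene(
            data["pre"]["features"], data["post"]["features"], model, prior,
            cfg.pixel_size, subset=cfg.subset, threshold=cfg.threshold,
            resolve=cfg.resolve)
        if len(scored):
            pre_xy = data["pre"]["features"].loc[
                scored["pre_index"], ["xm", "ym"]].to_numpy() * cfg.pixel_size
            post_xy = data["post"]["features"].loc[
                scored["post_index"], ["xm", "ym"]].to_numpy() * cfg.pixel_size
            scored["x_um"] = 0.5 * (pre_xy[:, 0] + post_xy[:, 0])
            scored["y_um"] = 0.5 * (pre_xy[:, 1] + post_xy[:, 1])
        for role in ("pre", "post"):
            data[role]["features"].to_csv(out / f"features_{role}.csv", index=False)
        scored.to_csv(out / "candidates.csv", index=False)
        synapses.to_csv(out / "synapses.csv", index=False)
        log["n_pre_rois"] = int(len(data["pre"]["features"]))
        log["n_post_rois"] = int(len(data["post"]["features"]))
        log["n_candidates"] = int(len(scored))
        log["n_synapses"] = int(len(synapses))

    elif stage == "maturity":
        for need in ("model_path", "synapse_table"):
            if getattr(cfg, need) is None:
                raise ValueError(f"maturity stage requires {need}")
        model = ClassModel.from_json(cfg.model_path)
        synapses = pd.read_csv(cfg.synapse_table)
        pre = pd.read_csv(Path(cfg.synapse_table).parent / "features_pre.csv")
        post = pd.read_csv(Path(cfg.synapse_table).parent / "features_post.csv")
        table = score_maturity(synapses, pre, post, model, subset=cfg.subset)
        table.to_csv(out / "maturity.csv", index=False)
        log["n_synapses"] = int(len(table))

    elif stage == "average":
        for need in ("pre_path", "post_path", "synapse_table"):
            if getattr(cfg, need) is None:
                raise ValueError(f"average stage requires {need}")
        synapses = pd.read_csv(cfg.synapse_table)
        images = {
            "pre": _load_projected(cfg.pre_path, cfg, "pre"),
            "post": _load_projected(cfg.post_path, cfg, "post"),
        }
        avg = average_synapse(images, synapses, cfg.pixel_size)
        for ch, img in avg.images.items():
            tifffile.imwrite(out / f"average_{ch}.tif", img.astype(np.float32))
            radial_profile(avg, ch).to_csv(out / f"radial_{ch}.csv", index=False)
        log["n_averaged"] = avg.n
        log["n_skipped_border"] = avg.skipped_border

    elif stage == "roc":
        for need in ("synapse_table", "truth_path"):
            if getattr(cfg, need) is None:
                raise ValueError(f"roc stage requires {need}")
        scored = pd.read_csv(cfg.synapse_table)  # scored candidates
        truth = pd.read_csv(cfg.truth_path)
        det = scored[["x_um", "y_um"]].to_numpy() if "x_um" in scored.columns else None
        if det is None:
            raise ValueError("candidate table must carry x_um/y_um midpoints")
        labels, _ = match_ground_truth(det, truth[["x_um", "y_um"]].to_numpy())
        roc = roc_auc(scored["posterior_synapse"], labels, match_dist=1.0)
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
            out / "roc_curve.csv", index=False)
        (out / "roc_summary.json").write_text(json.dumps({
            "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "n_positive": roc.n_positive, "n_negative": roc.n_negative,
        }, indent=2))
        log["auc"] = roc.auc

    elif stage == "stats":
        if cfg.data_table is None:
            raise ValueError("stats stage requires data_table")
        data = pd.read_csv(cfg.data_table)
        mcmc = McmcConfig(**{"seed": cfg.stage_seed("stats"), **cfg.mcmc})
        if cfg.stats_model == "gompertz":
            fit = fit_gompertz(data, mcmc=mcmc)
        elif cfg.stats_model == "merg":
            fit = fit_merg_gamma(data, mcmc=mcmc)
        else:
            fit = fit_robust_t(data, mcmc=mcmc)
        fit.summary.to_csv(out / "posterior_summary.csv", index=False)
        fit.contrasts.to_csv(out / "contrasts.csv", index=False)
        np.savez(out / "draws.npz", **fit.draws)
        log["converged"] = fit.diagnostics.converged
        log["rhat_max"] = max(fit.diagnostics.rhat.values())

    else:
        raise ValueError(f"unknown stage {stage!r}")

    return _write_manifest(out, cfg, stage, log)
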