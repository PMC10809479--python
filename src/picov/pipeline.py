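"""End-to-end orchestration: simulate/read -> quality filter -> register ->
segment -> PICoV + densities -> cohort statistics.

Every eye is processed independently and failures are isolated: an error
in one stack is logged in the run manifest and the cohort run continues.
The effective configuration is embedded in every output report so a run
is reproducible from its artifacts alone.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .datatypes import DVC, SVC, TEMPORAL_SIDE_MAP, ImageStack
from .metrics import (colorize_picov, compute_density_series,
                      compute_picov_map, summarize_picov)
from .registration import DemonsParams, register_stack
from .segmentation import (binarize_and_mask, remove_projection_artifacts,
                           segment_vessels)
from .stats import run_cohort_stats
from .synthetic import CohortConfig, EyeRecord, generate_cohort

log = logging.getLogger("picov")

__all__ = ["PipelineConfig", "filter_quality", "analyze_eye", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every constant the pipeline actually uses, in one serializable place."""

    out_dir: str = "picov_out"
    input_dir: Optional[str] = None
    simulate: bool = True
    seed: int = 0
    # study constants
    segmentation_threshold: float = 0.5
    picov_cap: float = 0.4
    signal_floor: int = 8
    strict_quality: bool = False
    alpha: float = 0.05
    # analysis options
    pd_definition: str = "ones_to_zeros"
    per_frame_segmentation: bool = True
    picov_reduction: str = "mean"
    temporal_side_map: dict = field(
        default_factory=lambda: dict(TEMPORAL_SIDE_MAP))
    run_registration: bool = True
    template_override: Optional[int] = None
    demons_iterations: tuple = (50, 25, 10)
    demons_smoothing_sigma_px: float = 2.0
    projection_width_threshold_px: int = 6
    # synthetic cohort
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def demons_params(self) -> DemonsParams:
        return DemonsParams(iterations=tuple(self.demons_iterations),
                            smoothing_sigma_px=self.demons_smoothing_sigma_px)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        cohort = d.pop("cohort", None)
        cfg = cls(**d)
        if cohort is not None:
            cfg.cohort = CohortConfig(**cohort)
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        return d


def filter_quality(stack: ImageStack, floor: int = 8,
                   strict: bool = False, min_frames: int = 10) -> ImageStack:
    """Drop frames below the signal-strength floor.

    In strict mode the acquisition contract requires at least
    ``min_frames`` clean frames; a shortfall is an error naming the
    deficient frames.  In permissive mode a warning is logged instead.
    """
    strengths = stack.signal_strength
    keep = strengths >= floor
    bad = np.nonzero(~keep)[0]
    if keep.all():
        return stack
    if keep.sum() < min_frames:
        msg = (f"{stack.eye_id}/{stack.layer}: only {int(keep.sum())} frames "
               f"at signal strength >= {floor} (frames below floor: "
               f"{bad.tolist()})")
        if strict:
            raise ValueError(msg)
        log.warning(msg)
    return stack.copy_with(stack.frames[keep],
                           signal_strength=strengths[keep])


def analyze_eye(stacks: dict, config: PipelineConfig) -> dict:
    """Process one eye's per-layer stacks into metric rows.

    Returns ``{"rows": [per-layer dict], "artifacts": {layer: {...}}}``.
    The SVC is processed first so its vessel mask can drive
    projection-artifact removal in the DVC.
    """
    rows = []
    artifacts: dict = {}
    svc_pmap = None
    order = [layer for layer in (SVC, DVC) if layer in stacks]
    for layer in order:
        stack = filter_quality(stacks[layer], config.signal_floor,
                               strict=config.strict_quality)
        reg = register_stack(stack, template_index=config.template_override,
                             params=config.demons_params(),
                             run_demons=config.run_registration)
        pmap = segment_vessels(reg.averaged)
        validity = reg.validity.copy()
        removed = np.zeros_like(validity)
        frames = reg.frames
        if layer == DVC and svc_pmap is not None:
            frames, removed = remove_projection_artifacts(
                frames, svc_pmap,
                width_threshold_px=config.projection_width_threshold_px)
            validity &= ~removed
        mask, masked = binarize_and_mask(
            pmap, dataclasses.replace(reg, frames=frames),
            threshold=config.segmentation_threshold)
        picov = compute_picov_map(masked, validity & mask.values)
        eye_picov, quadrants = summarize_picov(
            picov, stack.laterality, reduction=config.picov_reduction,
            temporal_side_map=config.temporal_side_map)
        segmenter = segment_vessels if config.per_frame_segmentation else None
        density_frames = frames if config.per_frame_segmentation \
            else masked
        dens = compute_density_series(density_frames, segmenter,
                                      validity=validity,
                                      threshold=config.segmentation_threshold,
                                      pd_definition=config.pd_definition)
        rows.append({
            "eye_id": stack.eye_id, "layer": layer, "group": stack.group,
            "laterality": stack.laterality,
            "picov": eye_picov,
            "picov_ST": quadrants.picov_ST, "picov_SN": quadrants.picov_SN,
            "picov_IT": quadrants.picov_IT, "picov_IN": quadrants.picov_IN,
            "mean_PD": dens.mean_pd, "sd_PD": dens.sd_pd,
            "mean_VD": dens.mean_vd, "sd_VD": dens.sd_vd,
            "pd_definition": dens.pd_definition,
            "template_index": reg.template_index,
            "n_frames": stack.n_frames,
        })
        artifacts[layer] = {
            "registered": reg, "probability_map": pmap, "mask": mask,
            "picov_map": picov, "density": dens,
            "projection_removed": removed,
        }
        if layer == SVC:
            svc_pmap = pmap
    return {"rows": rows, "artifacts": artifacts}


def _eye_stack_groups(input_dir: Path) -> dict:
    """Group stack files in a directory by eye id (``<eye>_<layer>.tif``)."""
    groups: dict = {}
    for f in sorted(input_dir.glob("*.tif*")):
        stack = pio.read_stack(f)
        groups.setdefault(stack.eye_id, {})[stack.layer] = stack
    return groups


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full cohort analysis and write all artifacts.

    Returns a summary dict with the cohort table, statistics report and
    manifest.  Deterministic given (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if config.simulate:
        cohort = generate_cohort(config.cohort, seed=config.seed)
        eyes = {rec.eye_id: rec.stacks for rec in cohort}
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when simulate is off")
        eyes = _eye_stack_groups(Path(config.input_dir))
        if not eyes:
            raise ValueError(f"no stacks found in {config.input_dir}")

    manifest = []
    rows = []
    for eye_id, stacks in eyes.items():
        entry = {"eye_id": eye_id, "layers": sorted(stacks),
                 "status": "ok", "warnings": []}
        try:
            result = analyze_eye(stacks, config)
            rows.extend(result["rows"])
            for row in result["rows"]:
                entry[f"template_{row['layer']}"] = row["template_index"]
            eye_dir = out / "eyes" / eye_id
            for layer, art in result["artifacts"].items():
                pio.write_float_tiff(art["registered"].averaged,
                                     eye_dir / f"{layer}_averaged.tif")
                pio.write_float_tiff(art["picov_map"].values,
                                     eye_dir / f"{layer}_picov.tif")
                pio.write_png(colorize_picov(art["picov_map"],
                                             cap=config.picov_cap),
                              eye_dir / f"{layer}_picov.png")
                pio.write_png(art["mask"].values.astype(float),
                              eye_dir / f"{layer}_mask.png")
        except Exception as exc:  # noqa: BLE001 - per-eye failure isolation
            log.error("eye %s failed: %s", eye_id, exc)
            entry["status"] = "failed"
            entry["error"] = str(exc)
        manifest.append(entry)

    table = pd.DataFrame(rows)
    table.to_csv(out / "cohort.csv", index=False)

    report: dict = {"config": config.as_dict(), "n_eyes": len(eyes)}
    if not table.empty and table["group"].nunique() >= 2:
        stats_report = run_cohort_stats(table, alpha=config.alpha)
        report["stats"] = stats_report.to_dict()
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("constants used: threshold=%s cap=%s floor=%s alpha=%s",
             config.segmentation_threshold, config.picov_cap,
             config.signal_floor, config.alpha)
    return {"table": table, "report": report, "manifest": manifest,
            "out_dir": str(out)}
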