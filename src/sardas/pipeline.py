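"""End-to-end orchestration: SAR localization → aperture → simulate → image → metrics.

The pipeline executes the full process flow with one global seed:
synthesize the field, compute the SAR map, locate its maximum, plan the
reduced aperture (or the conventional ring), simulate baseline and
cancerous scans, reconstruct, and evaluate. Each stage draws randomness
from a seed derived by stable hashing of the stage name.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .config import RunConfig, build_phantom, config_hash, stage_seed
from .errors import InputError
from .evaluation import EvaluationReport, evaluate_image
from .forward_sim import ForwardModelParams, simulate_scan
from .phantom import BreastPhantom
from .pulse import PulseParams, default_time_axis
from .reconstruction import (
    ImagingConfig,
    IntensityImage,
    effective_permittivity,
    reconstruct,
)
from .sar_locator import (
    FieldParams,
    TumorEstimate,
    default_grid_axes,
    locate_tumor,
    plan_aperture,
    plan_full_ring,
    sar_from_field,
    synthesize_field,
)

__all__ = ["PipelineResult", "run_pipeline", "simulate_records"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    status: str  # "ok" | "no_detection"
    estimate: TumorEstimate | None = None
    image: IntensityImage | None = None
    report: EvaluationReport | None = None
    config_hash: str = ""
    extras: dict = field(default_factory=dict)


def _pulse_params(cfg: RunConfig) -> PulseParams:
    return PulseParams(
        center_frequency=cfg.pulse.center_frequency,
        time_shift=cfg.pulse.time_shift,
        normalize=cfg.pulse.normalize,
    )


def _forward_params(cfg: RunConfig, stage: str) -> ForwardModelParams:
    return ForwardModelParams(
        attenuation_skin=cfg.forward.attenuation_skin,
        attenuation_interior=cfg.forward.attenuation_interior,
        spreading_exponent=cfg.forward.spreading_exponent,
        directivity_exponent=cfg.forward.directivity_exponent,
        artifact_amplitude=cfg.forward.artifact_amplitude,
        noise_sigma=cfg.forward.noise_sigma,
        seed=stage_seed(cfg.seed, stage),
    )


def _plan_geometry(cfg: RunConfig, phantom: BreastPhantom, estimate: TumorEstimate | None):
    if cfg.aperture.mode == "full_ring":
        height = estimate.center_estimate[2] if estimate is not None else 0.0
        return plan_full_ring(
            phantom,
            n_positions=cfg.aperture.n_positions,
            standoff=cfg.aperture.standoff,
            plane_height=height,
        )
    if estimate is None:
        raise InputError("SAR-guided aperture requires a tumor estimate")
    return plan_aperture(
        estimate.center_estimate,
        phantom,
        standoff=cfg.aperture.standoff,
        rows=cfg.aperture.rows,
        cols=cfg.aperture.cols,
        angular_step=cfg.aperture.angular_step,
        mode=cfg.aperture.layout,
    )


def _locate(cfg: RunConfig, phantom: BreastPhantom) -> TumorEstimate | None:
    axes = default_grid_axes(phantom, spacing=cfg.sar.voxel_mm)
    fparams = FieldParams(
        decay_offset=cfg.sar.decay_offset, tumor_enhancement=cfg.sar.tumor_enhancement
    )
    grid = synthesize_field(phantom, cfg.sar.source_position, fparams, axes)
    return locate_tumor(sar_from_field(grid, phantom), ratio_threshold=cfg.sar.ratio_threshold)


def _imaging_config(cfg: RunConfig, phantom, geometry, focus) -> ImagingConfig:
    eps = cfg.imaging.permittivity
    if eps == "auto":
        eps = effective_permittivity(phantom, geometry.positions, focus)
    plane_z = float(focus[2])
    return ImagingConfig(
        n_x=cfg.imaging.grid[0],
        n_y=cfg.imaging.grid[1],
        region=cfg.imaging.region,
        medium_permittivity=float(eps),
        intensity_exponent=cfg.imaging.intensity_exponent,
        interpolation=cfg.imaging.interpolation,
        plane_z=plane_z,
        time_reference=cfg.pulse.time_shift,
        strict_literal_velocity=cfg.imaging.strict_literal_velocity,
    )


def simulate_records(cfg: RunConfig, estimate: TumorEstimate | None = None):
    """Simulate the (tumor_free, cancerous) pair of scan records for a config."""
    phantom = build_phantom(cfg.phantom)
    if estimate is None and cfg.aperture.mode == "sar_guided":
        estimate = _locate(cfg, phantom)
        if estimate is None:
            raise InputError("no SAR detection on this phantom")
    geometry = _plan_geometry(cfg, phantom, estimate)
    pulse = _pulse_params(cfg)
    t_axis = default_time_axis(cfg.pulse.n_samples, cfg.pulse.t_max)
    baseline = simulate_scan(
        phantom.without_tumors(), geometry, pulse, _forward_params(cfg, "baseline"),
        with_tumors=False, time_axis=t_axis,
    )
    cancerous = simulate_scan(
        phantom, geometry, pulse, _forward_params(cfg, "cancerous"),
        with_tumors=True, time_axis=t_axis,
    )
    return baseline, cancerous, geometry, estimate


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the whole chain; returns ``status="no_detection"`` when SAR finds nothing."""
    t0 = time.perf_counter()
    phantom = build_phantom(cfg.phantom)

    estimate = _locate(cfg, phantom)
    if estimate is None:
        logger.warning("SAR map is all-zero: no detection")
        return PipelineResult(status="no_detection", config_hash=config_hash(cfg))
    logger.info("SAR estimate at %s (ratio %.2f)", estimate.position, estimate.peak_ratio)

    baseline, cancerous, geometry, _ = simulate_records(cfg, estimate)
    imaging = _imaging_config(cfg, phantom, geometry, estimate.center_estimate)
    image = reconstruct(cancerous, baseline, imaging)

    report = None
    if phantom.tumors:
        tumor = phantom.tumors[0]
        report = evaluate_image(
            image, tumor.center[:2], tumor.radius, scenario="pipeline", seed=cfg.seed
        )
    logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return PipelineResult(
        status="ok",
        estimate=estimate,
        image=image,
        report=report,
        config_hash=config_hash(cfg),
        extras={"effective_permittivity": imaging.medium_permittivity},
    )
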