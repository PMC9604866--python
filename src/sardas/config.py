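"""Run configuration schema (pydantic), seed fan-out, and config I/O.

A run is fully described by a :class:`RunConfig` (YAML or JSON on disk).
Unknown keys are rejected with field-path messages; every run echoes its
resolved configuration next to its outputs. The single global seed fans out
to per-stage seeds by stable hashing of the stage name, so any stage can be
re-run in isolation with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .phantom import (
    INTERIOR,
    SKIN,
    TUMOR,
    BreastPhantom,
    TissueProperties,
    Tumor,
)

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "stage_seed",
    "build_phantom",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed (< 2^31) from the global seed."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TissueSection(_Section):
    permittivity: float = Field(gt=0)
    conductivity: float = Field(gt=0)
    density: float = Field(default=1000.0, gt=0)

    def to_tissue(self) -> TissueProperties:
        return TissueProperties(self.permittivity, self.conductivity, self.density)


class TumorSection(_Section):
    center: tuple[float, float, float] = (20.0, -13.0, 14.0)
    radius: float = Field(default=5.0, gt=0)
    tissue: TissueSection = TissueSection(
        permittivity=TUMOR.relative_permittivity, conductivity=TUMOR.conductivity
    )


class PhantomSection(_Section):
    radius: float = Field(default=50.0, gt=0)
    skin_thickness: float = Field(default=2.0, gt=0)
    skin: TissueSection = TissueSection(
        permittivity=SKIN.relative_permittivity, conductivity=SKIN.conductivity
    )
    interior: TissueSection = TissueSection(
        permittivity=INTERIOR.relative_permittivity, conductivity=INTERIOR.conductivity
    )
    tumors: list[TumorSection] = Field(default_factory=lambda: [TumorSection()])


class PulseSection(_Section):
    center_frequency: float = Field(default=5.8e9, gt=0)
    time_shift: float = 0.5e-9
    normalize: bool = True
    n_samples: int = Field(default=2048, ge=16)
    t_max: float = Field(default=5e-9, gt=0)


class ForwardSection(_Section):
    attenuation_skin: float = Field(default=0.1, ge=0)
    attenuation_interior: float = Field(default=0.02, ge=0)
    spreading_exponent: float = Field(default=2.0, ge=0)
    directivity_exponent: float = Field(default=4.0, ge=0)
    artifact_amplitude: float = Field(default=0.02, ge=0)
    noise_sigma: float = Field(default=0.0, ge=0)


class ApertureSection(_Section):
    mode: str = Field(default="sar_guided", pattern="^(sar_guided|full_ring)$")
    rows: int = Field(default=3, ge=1)
    cols: int = Field(default=3, ge=1)
    n_positions: int = Field(default=36, ge=3)
    angular_step: float = Field(default=10.0, gt=0)
    standoff: float = Field(default=10.0, gt=0)
    layout: str = Field(default="grid", pattern="^(grid|arc)$")


class SarSection(_Section):
    source_position: tuple[float, float, float] = (0.0, 0.0, 60.0)
    voxel_mm: float = Field(default=1.0, gt=0)
    decay_offset: float = Field(default=50.0, gt=0)
    tumor_enhancement: float = Field(default=4.0, gt=0)
    ratio_threshold: float = Field(default=1.5, gt=0)


class ImagingSection(_Section):
    grid: tuple[int, int] = (350, 350)
    region: tuple[float, float, float, float] = (-50.0, 50.0, -50.0, 50.0)
    permittivity: float | str = "auto"  # numeric, or "auto" = path-averaged
    intensity_exponent: int = Field(default=2, ge=2)
    interpolation: str = Field(default="linear", pattern="^(linear|nearest)$")
    strict_literal_velocity: bool = False


class EvaluationSection(_Section):
    noisy_replicates: int = Field(default=20, ge=0)
    noise_sigma: float = Field(default=2e-6, ge=0)


class RunConfig(_Section):
    phantom: PhantomSection
    pulse: PulseSection = PulseSection()
    forward: ForwardSection = ForwardSection()
    aperture: ApertureSection = ApertureSection()
    sar: SarSection = SarSection()
    imaging: ImagingSection = ImagingSection()
    evaluation: EvaluationSection = EvaluationSection()
    seed: int = 0


def build_phantom(section: PhantomSection) -> BreastPhantom:
    return BreastPhantom(
        breast_radius=section.radius,
        skin_thickness=section.skin_thickness,
        skin=section.skin.to_tissue(),
        interior=section.interior.to_tissue(),
        tumors=tuple(
            Tumor(center=t.center, radius=t.radius, tissue=t.tissue.to_tissue())
            for t in section.tumors
        ),
    )


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown keys are rejected."""
    text = pathlib.Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
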