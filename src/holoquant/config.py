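"""Validated study configuration.

A single :class:`StudyConfig` drives the end-to-end pipeline: phantom
definitions, grids, acquisition settings, the dead-time profile, the
decay schedule and the quantification methods to run. Units are fixed
by policy: activities MBq, concentrations MBq/mL, lengths mm, schedule
times hours, acquisition sub-times seconds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .phantom_geometry import (
    JASZCZAK_SPHERE_DIAMETERS_MM,
    PhantomSpec,
    cylinder_phantom,
    jaszczak_phantom,
)
from .synthetic_spect import (
    CYLINDER_SCAN_DT_H,
    HO166_HALF_LIFE_H,
    JASZCZAK_SCHEDULE_H,
    AcquisitionSpec,
    DeadTimeModel,
)

__all__ = ["StudyConfig", "PhantomConfig", "AcquisitionConfig", "DeadTimeConfig"]


class PhantomConfig(BaseModel):
    kind: Literal["cylinder", "jaszczak"] = "jaszczak"
    body_diameter_mm: float = 216.0
    body_height_mm: float = 186.0
    sphere_diameters_mm: tuple[float, ...] = JASZCZAK_SPHERE_DIAMETERS_MM
    sphere_centers_mm: Optional[tuple[tuple[float, float, float], ...]] = None
    concentration_spheres: float = 4.10
    concentration_background: float = 0.41

    def build(self) -> PhantomSpec:
        if self.kind == "cylinder":
            return cylinder_phantom(
                concentration=self.concentration_background,
                diameter_mm=self.body_diameter_mm,
                height_mm=self.body_height_mm,
            )
        return jaszczak_phantom(
            concentration_spheres=self.concentration_spheres,
            concentration_background=self.concentration_background,
            body_diameter_mm=self.body_diameter_mm,
            body_height_mm=self.body_height_mm,
            sphere_diameters_mm=self.sphere_diameters_mm,
            sphere_centers_mm=self.sphere_centers_mm,
        )


class AcquisitionConfig(BaseModel):
    n_projections: int = Field(120, ge=1)
    projection_time_s: float = Field(20.0, gt=0)
    sensitivity_cps_per_mbq: float = Field(19.7, gt=0)
    psf_fwhm_mm: float = Field(15.0, ge=0)
    noise: bool = True

    def build(self, dt_hours: float = 0.0, seed: int = 0) -> AcquisitionSpec:
        return AcquisitionSpec(
            n=self.n_projections,
            t=self.projection_time_s,
            sensitivity=self.sensitivity_cps_per_mbq,
            psf_fwhm=self.psf_fwhm_mm,
            dt_hours=dt_hours,
            seed=seed,
            noise=self.noise,
        )


class DeadTimeConfig(BaseModel):
    """Dead-time profile: the loss fraction at the highest scheduled rate."""

    enabled: bool = True
    loss_fraction_at_max: float = Field(0.40, ge=0, lt=1)

    def build(self, max_true_rate_cps: float) -> DeadTimeModel:
        if not self.enabled or self.loss_fraction_at_max == 0:
            return DeadTimeModel.none()
        return DeadTimeModel.from_loss_fraction(self.loss_fraction_at_max, max_true_rate_cps)


class StudyConfig(BaseModel):
    jaszczak: PhantomConfig = PhantomConfig()
    cylinder: PhantomConfig = PhantomConfig(
        kind="cylinder",
        body_diameter_mm=200.0,
        body_height_mm=200.0,
        concentration_background=0.049,
    )
    acquisition: AcquisitionConfig = AcquisitionConfig()
    dead_time: DeadTimeConfig = DeadTimeConfig()
    schedule_h: tuple[float, ...] = JASZCZAK_SCHEDULE_H
    cylinder_dt_h: float = CYLINDER_SCAN_DT_H
    half_life_h: float = Field(HO166_HALF_LIFE_H, gt=0)
    methods: tuple[Literal["self", "homogeneous"], ...] = ("self", "homogeneous")
    # triplicate groups (indices into schedule_h) used for recovery-curve fits
    fit_groups: dict[str, tuple[int, ...]] = {
        "tp10": (9, 10, 11),
        "tp12": (13, 14, 15),
        "tp13": (16, 17, 18),
        "tp14": (19, 20, 21),
    }
    sim_spacing_mm: float = Field(4.8, gt=0)
    metrics_spacing_mm: float = Field(1.0, gt=0)
    grid_margin_mm: float = Field(60.0, ge=0)
    supersampling: int = Field(3, ge=1)
    compute_acrc: bool = True
    compute_homogeneity: bool = True
    homogeneous_voi_radius_mm: float = 70.0
    homogeneous_voi_height_mm: float = 130.0
    profile_rows: tuple[tuple[float, float], ...] = ((0.0, 0.0), (30.0, 0.0), (70.0, 0.0))
    profile_radii: tuple[float, ...] = (30.0, 70.0)
    profile_margin_mm: float = 30.0
    cavh_levels: int = Field(256, ge=2)
    seed: int = 0
    output_dir: Optional[str] = None

    @field_validator("schedule_h")
    @classmethod
    def _schedule_nonneg(cls, v):
        if len(v) == 0:
            raise ValueError("schedule must be non-empty")
        if any(dt < 0 for dt in v):
            raise ValueError("schedule entries must be >= 0 hours")
        return v

    @field_validator("methods")
    @classmethod
    def _at_least_one_method(cls, v):
        if len(v) == 0:
            raise ValueError("at least one quantification method must be selected")
        return v

    @model_validator(mode="after")
    def _fit_groups_in_range(self):
        for name, idxs in self.fit_groups.items():
            if any(i < 0 or i >= len(self.schedule_h) for i in idxs):
                raise ValueError(f"fit group {name!r} indexes outside the schedule")
        return self

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(json.loads(self.model_dump_json()), sort_keys=True).encode()
        ).hexdigest()[:12]
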