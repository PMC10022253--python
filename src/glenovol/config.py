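"""Run configuration for the end-to-end pipeline (YAML-backed)."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, field_validator

from .errors import ConfigError
from .simulate import (INJECTION_COMPONENTS_ML, INJECTION_TOTAL_ML, PUBLISHED_COHORT_MARGINS,
                       CohortSimConfig, PhantomSpec, RaterSimConfig,
                       default_correlation_matrix, validate_injection_protocol)

__all__ = ["RunConfig", "load_run_config", "config_hash"]


class PhantomEntry(BaseModel):
    shape: str = "solid_sphere"
    radius_mm: float = 20.0
    inner_radius_mm: float = 0.0
    offset_mm: list[float] = [0.0, 0.0, 0.0]
    spacing_mm: float = 1.0
    grid_shape: list[int] = [64, 64, 64]
    contrast: float = 300.0
    background: float = 0.0
    noise_sd: float = 20.0
    side: str = "right"

    def to_spec(self) -> PhantomSpec:
        return PhantomSpec(shape=self.shape, radius_mm=self.radius_mm,
                           inner_radius_mm=self.inner_radius_mm,
                           offset_mm=np.array(self.offset_mm),
                           spacing_mm=self.spacing_mm,
                           grid_shape=tuple(self.grid_shape),
                           contrast=self.contrast, background=self.background,
                           noise_sd=self.noise_sd, side=self.side)


class CohortEntry(BaseModel):
    n: int = 200
    within_volumes_r: float = 0.3
    within_motions_r: float = 0.3

    def to_config(self, seed: int | None) -> CohortSimConfig:
        return CohortSimConfig(
            n=self.n, margins=dict(PUBLISHED_COHORT_MARGINS),
            correlation=default_correlation_matrix(self.within_volumes_r,
                                                   self.within_motions_r),
            seed=seed)


class RatingsEntry(BaseModel):
    n_subjects: int = 83
    n_raters: int = 2
    error_sd: float = 1.0

    def to_config(self, seed: int | None) -> RaterSimConfig:
        return RaterSimConfig(n_subjects=self.n_subjects, n_raters=self.n_raters,
                              error_sd=self.error_sd, seed=seed)


class RunConfig(BaseModel):
    """Everything the ``glenovol run`` pipeline needs, serializable as YAML."""

    seed: int = 0
    outdir: str = "glenovol_out"
    side: str = "right"
    threshold: float | None = None  # default: phantom mid-contrast
    report_format: str = "json"
    injection_components_ml: list[float] = list(INJECTION_COMPONENTS_ML)
    expected_injectate_ml: float = INJECTION_TOTAL_ML
    phantoms: list[PhantomEntry] = [
        PhantomEntry(shape="solid_sphere", radius_mm=20.0),
        PhantomEntry(shape="spherical_shell", radius_mm=30.0, inner_radius_mm=25.0,
                     grid_shape=[70, 70, 70]),
        PhantomEntry(shape="offset_sphere", radius_mm=20.0, offset_mm=[5.0, 0.0, 0.0]),
    ]
    cohort: CohortEntry = CohortEntry()
    ratings: RatingsEntry = RatingsEntry()

    @field_validator("report_format")
    @classmethod
    def _fmt(cls, v: str) -> str:
        if v not in ("json", "csv"):
            raise ValueError("report_format must be 'json' or 'csv'")
        return v

    def validate_protocol(self) -> float:
        """Check the injectate components sum to the expected filling volume."""
        total = validate_injection_protocol(self.injection_components_ml)
        if abs(total - self.expected_injectate_ml) > 1e-9:
            raise ConfigError(
                f"injectate components sum to {total} mL, expected "
                f"{self.expected_injectate_ml} mL (standardized-filling criterion)")
        return total


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 over the canonical JSON serialization of the config."""
    payload = config.model_dump_json().encode()
    return hashlib.sha256(payload).hexdigest()
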