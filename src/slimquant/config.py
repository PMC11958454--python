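"""Configuration containers for the simulator and the analysis pipeline.

Defaults encode the acquisition regime the package targets: Slimfield movies
of budding yeast sampled at 5 ms/frame for 1,000+ frames, imaged with a high-NA
objective (diffraction-limited PSF, sigma ~87 nm) onto a camera with ~120 nm
pixels, with per-fluorophore stochastic photobleaching bringing bright
aggregates down to the single-molecule level within one acquisition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "SimulationConfig",
    "PipelineConfig",
    "ConfigError",
    "load_pipeline_config",
]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values (fail-fast)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and camera parameters of a simulated acquisition.

    Lengths are in nm, times in seconds, photon budgets in expected detected
    photons. ``psf_sigma`` defaults to 0.25*lambda/NA for 488 nm excitation
    and NA 1.4 (~87 nm). The photon budget / background / read-noise defaults
    are the calibration point at which the localizer reaches the target
    ~40 nm lateral precision with margin; they are documented choices, not
    measured values.
    """

    pixel_size: float = 120.0          # nm per pixel
    frame_interval: float = 0.005      # s
    n_frames: int = 1000
    image_shape: tuple[int, int] = (48, 48)
    psf_sigma: float = 87.0            # nm
    photons_per_fluorophore_per_frame: float = 300.0
    bleach_prob: float = 0.01          # per fluorophore per frame
    dark_fraction: float = 0.07        # fraction of fluorophores never photoactive
    background_photons: float = 10.0   # per pixel per frame
    read_noise_sd: float = 1.0         # camera counts
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ConfigError("pixel_size and psf_sigma must be positive")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.n_frames <= 0:
            raise ConfigError("n_frames must be positive")
        if any(s <= 0 for s in self.image_shape):
            raise ConfigError("image_shape must be positive")
        if not (0.0 <= self.bleach_prob <= 1.0):
            raise ConfigError("bleach_prob must be in [0, 1]")
        if not (0.0 <= self.dark_fraction < 1.0):
            raise ConfigError("dark_fraction must be in [0, 1)")
        if self.photons_per_fluorophore_per_frame <= 0:
            raise ConfigError("photon budget must be positive")
        if self.background_photons < 0 or self.read_noise_sd < 0:
            raise ConfigError("noise levels must be non-negative")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size / 1000.0


@dataclass(frozen=True)
class DetectionConfig:
    threshold_method: str = "otsu"     # otsu | mean | percentile | fixed
    min_area_px: int = 4
    percentile: float = 99.0
    fixed_value: float | None = None


@dataclass(frozen=True)
class TrackingConfig:
    max_disp: float = 5.0              # px, per frame
    window_radius: int = 8             # px, localization fit window
    msd_n_points: int = 4
    min_track_length: int = 10


@dataclass(frozen=True)
class StoichiometryConfig:
    calibration_method: str = "terminal_steps"   # or fourier_pairwise
    dark_fraction: float = 0.0                   # correction OFF by default
    ck_window: int = 10
    ck_exponent: float = 2.0
    min_dwell: int = 5
    initial_window: int = 4


@dataclass(frozen=True)
class AnalysisConfig:
    coloc_max_distance: float = 250.0  # nm, optical resolution criterion
    iqr_k: float = 1.5
    test: str = "mann_whitney"         # or student_t


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; unknown keys are rejected on load."""

    acquisition: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    stoichiometry: StoichiometryConfig = field(default_factory=StoichiometryConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_BLOCKS = {
    "acquisition": SimulationConfig,
    "detection": DetectionConfig,
    "tracking": TrackingConfig,
    "stoichiometry": StoichiometryConfig,
    "analysis": AnalysisConfig,
}


def _build(cls: type, data: Mapping[str, Any], where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in '{where}'")
    if "image_shape" in data and data["image_shape"] is not None:
        data = dict(data)
        data["image_shape"] = tuple(data["image_shape"])
    return cls(**data)


def pipeline_config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    unknown = set(data) - set(_BLOCKS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return PipelineConfig(**kwargs)


def load_pipeline_config(path) -> PipelineConfig:
    """Read a YAML pipeline configuration, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return pipeline_config_from_dict(data)
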