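"""Configuration of the synthetic embryo-movie generator.

All durations are in minutes in the config (matching how cleavage-cycle
lengths are usually reported) and converted to seconds internally.  Spatial
quantities are in micrometres; the rendered field is specified in voxels
with an explicit anisotropic voxel size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


@dataclass(frozen=True)
class NoiseParams:
    """Camera-like noise model: scaled Poisson shot noise plus additive
    Gaussian read noise on top of a constant background offset.

    ``photon_scale`` is the (inverse) gain: counts are divided by it before
    Poisson resampling, so smaller values mean noisier images.
    """

    background: float = 100.0
    gaussian_sd: float = 6.0
    photon_scale: float = 0.25

    def validate(self) -> None:
        if self.background < 0 or self.gaussian_sd < 0:
            raise ConfigError("noise levels must be non-negative")
        if self.photon_scale < 0:
            raise ConfigError("photon_scale must be >= 0 (0 disables shot noise)")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated blastula movie.

    The defaults emulate the animal-pole field of a pre-MBT zebrafish embryo
    followed from the 128-cell through the 512-cell cycle: metasynchronous
    divisions sweeping across the field as a spatial wave, per-generation
    elongation of S-phase with a constant M-phase, S-phase-restricted paired
    transcription foci whose detectable span scales with S-phase length,
    chromatin depletion at active foci, and optional transcription-block
    (triptolide-like) or replication-checkpoint (chk1-like) perturbations.
    """

    seed: int = 0

    # lineage / field geometry
    n_founders: int = 12
    n_generations: int = 2          # division rounds; generations 0..n_generations
    frame_interval_s: float = 51.0
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 1.0)   # (x, y, z)
    field_shape: tuple[int, int, int] = (20, 200, 200)            # (z, y, x)
    nucleus_radius_um: tuple[float, ...] = (5.5, 4.8, 4.2)        # per generation

    # cell-cycle timing, minutes (one entry per generation)
    cycle_mean_min: tuple[float, ...] = (10.0, 13.0, 17.0)
    cycle_sd_min: tuple[float, ...] = (0.8, 1.0, 1.3)
    m_phase_min: float = 4.0
    # prophase / prometaphase / metaphase / anaphase / telophase fractions of M
    m_subphase_fracs: tuple[float, float, float, float, float] = (
        0.25, 0.15, 0.2, 0.25, 0.15)
    wave_speed_um_per_s: float = 0.5

    # expression model
    ploidy: int = 2
    onset_generation: int = 0
    onset_delay_frac: tuple[float, float] = (0.05, 0.35)   # uniform(lo, hi) of S
    span_coupling: float = 1.0
    p_express: float = 0.75
    memory_boost: float = 0.15

    # compartment volume dynamics
    peak_volume_um3: float = 16.0
    rise_min: float = 3.0
    decay_min: float = 2.0
    residual_m_frac: float = 0.3
    hole_radius_um: float = 1.5

    noise: NoiseParams = field(default_factory=NoiseParams)
    perturbation: str = "none"      # none | triptolide | chk1
    chk1_s_scale: float = 1.5

    # -- derived helpers ---------------------------------------------------
    @property
    def m_phase_s(self) -> float:
        return self.m_phase_min * 60.0

    @property
    def n_levels(self) -> int:
        """Number of simulated generations (founders count as level 0)."""
        return self.n_generations + 1

    def radius_um(self, generation: int) -> float:
        """Nucleus radius for a generation; tetraploids scale with genome
        content (doubled DNA -> 2^(1/3) larger radius)."""
        radii = self.nucleus_radius_um
        r = float(radii[min(generation, len(radii) - 1)])
        return r * (self.ploidy / 2) ** (1 / 3)

    def validate(self) -> None:
        if self.n_founders < 1:
            raise ConfigError("n_founders must be >= 1")
        if self.n_generations < 0:
            raise ConfigError("n_generations must be >= 0")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be > 0")
        if self.m_phase_min <= 0:
            raise ConfigError("m_phase_min must be > 0")
        if len(self.cycle_mean_min) < self.n_levels or len(self.cycle_sd_min) < self.n_levels:
            raise ConfigError(
                f"cycle_mean_min/cycle_sd_min need >= {self.n_levels} entries "
                f"(one per generation)")
        if any(m <= self.m_phase_min for m in self.cycle_mean_min[: self.n_levels]):
            raise ConfigError("mean cycle length must exceed m_phase_min")
        if any(s < 0 for s in self.cycle_sd_min):
            raise ConfigError("cycle_sd_min must be non-negative")
        if abs(sum(self.m_subphase_fracs) - 1.0) > 1e-6:
            raise ConfigError("m_subphase_fracs must sum to 1")
        if self.wave_speed_um_per_s <= 0:
            raise ConfigError("wave_speed_um_per_s must be > 0")
        if self.ploidy not in (2, 4):
            raise ConfigError("ploidy must be 2 or 4")
        if not 0 <= self.p_express <= 1 or not 0 <= self.p_express + self.memory_boost <= 1:
            raise ConfigError("need 0 <= p_express + memory_boost <= 1")
        if self.memory_boost < 0:
            raise ConfigError("memory_boost must be >= 0")
        lo, hi = self.onset_delay_frac
        if not (0 <= lo <= hi < 1):
            raise ConfigError("onset_delay_frac must satisfy 0 <= lo <= hi < 1")
        if not 0 < self.span_coupling <= 1:
            raise ConfigError("span_coupling must be in (0, 1]")
        if self.peak_volume_um3 <= 0 or self.rise_min <= 0 or self.decay_min <= 0:
            raise ConfigError("volume-profile parameters must be > 0")
        if not 0 <= self.residual_m_frac <= 1:
            raise ConfigError("residual_m_frac must be in [0, 1]")
        if self.hole_radius_um <= 0:
            raise ConfigError("hole_radius_um must be > 0")
        if self.perturbation not in ("none", "triptolide", "chk1"):
            raise ConfigError(f"unknown perturbation {self.perturbation!r}")
        if self.chk1_s_scale <= 0:
            raise ConfigError("chk1_s_scale must be > 0")
        if any(v <= 0 for v in self.voxel_size_um) or any(s < 4 for s in self.field_shape):
            raise ConfigError("invalid field geometry")
        self.noise.validate()

    # -- (de)serialisation -------------------------------------------------
    def replace(self, **kwargs) -> "SimConfig":
        if "noise" in kwargs and isinstance(kwargs["noise"], dict):
            kwargs["noise"] = NoiseParams(**kwargs["noise"])
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseParams(**d["noise"])
        for key in ("voxel_size_um", "field_shape", "nucleus_radius_um",
                    "cycle_mean_min", "cycle_sd_min", "m_subphase_fracs",
                    "onset_delay_frac"):
            if key in d and isinstance(d[key], Sequence) and not isinstance(d[key], tuple):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
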