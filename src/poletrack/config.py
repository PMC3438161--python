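"""Simulation configuration.

:class:`SimConfig` bundles every knob of the synthetic time-lapse generator:
optics (pixel size, PSF, noise), cell geometry, the per-pole exponential
elongation-rate distributions, septum-placement statistics, and the event
timers (patch appearance, condensation, invagination delay).  The defaults
are the conditions of the live-cell M. smegmatis experiment this package
models: images every 10 min, a fast pole elongating at 1.66e-4 min^-1 and a
slow pole at 7.87e-5 min^-1, and envelope invagination 160 min after the
septal focus condenses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["SimConfig", "ConfigurationError", "SPECIES_LENGTH_PARAMS"]


class ConfigurationError(ValueError):
    """Raised when a :class:`SimConfig` violates its invariants."""


#: Published mean/SD of three-spot cell length per species (µm), usable as
#: ``birth_length_mean``/``birth_length_sd`` or as truth-length distributions
#: for static snapshots.
SPECIES_LENGTH_PARAMS: dict[str, tuple[float, float]] = {
    "M_smegmatis_mc2_155": (4.8, 1.37),
    "M_bovis_BCG": (4.32, 1.10),
    "C_glutamicum": (3.46, 0.34),
}


@dataclass
class SimConfig:
    """All generator parameters plus the master seed.

    Attributes
    ----------
    frame_interval:
        Minutes between consecutive frames.
    pixel_size:
        µm per pixel of the rendered images.
    cell_width:
        Capsule diameter in µm.
    psf_sigma:
        Gaussian point-spread-function sigma in µm.
    background_level, cell_contrast:
        Phase-channel background intensity and the amount by which a cell is
        darker than background (arbitrary units, pre-noise).
    fluor_background, focus_amplitude, patch_amplitude, patch_sigma_factor:
        Fluorescence-channel background, peak amplitude of a condensed focus,
        peak amplitude of the pre-condensation diffuse patch, and the factor
        by which the patch is broader than the PSF.
    noise_sd:
        SD of additive Gaussian noise applied to both channels.
    fast_rate_mean, fast_rate_sd, slow_rate_mean, slow_rate_sd:
        Per-pole exponential elongation-rate distributions (min^-1).  Each
        cell carries one pole from each distribution.
    birth_length_mean, birth_length_sd, min_length:
        Birth-length distribution (µm); draws below ``min_length`` are
        redrawn (truncation, never clamping).
    placement_offset_sd:
        SD of the septum offset from mid-cell, as a fraction of cell length.
    wander_step_sd, wander_lo, wander_hi:
        Pre-condensation patch dynamics: per-frame step SD (fraction of cell
        length) of a random walk reflected into [wander_lo, wander_hi].
    appearance_delay_mean, appearance_delay_sd:
        Minutes from birth to first appearance of the internal patch.
    condensation_frames_mean, condensation_frames_sd:
        Frames from patch appearance to stable condensation (integer draw,
        at least 1).
    invagination_delay:
        Minutes from condensation to division (the division timer).
    invagination_frames:
        Number of final pre-division frames rendered with a local width
        constriction at the septum.
    separation_gap:
        µm of clear background inserted between daughters at division.
    fast_on_short_prob:
        Probability that the fast rate lands on the side that is shorter at
        septum placement (0.5 = unbiased assignment).
    inherit_old_pole_rate:
        If true a daughter's old pole keeps its parental rate and the new
        pole draws from the other rate class; if false daughters re-draw both
        rates like founders.
    n_cells:
        Number of founder cells.
    n_frames:
        Movie length in frames; ``None`` means long enough for every founder
        to divide plus a short tail.
    seed:
        Master seed; every stochastic stage derives its own stream from it.
    """

    frame_interval: float = 10.0
    pixel_size: float = 0.05
    cell_width: float = 0.5
    psf_sigma: float = 0.10
    background_level: float = 200.0
    cell_contrast: float = 140.0
    fluor_background: float = 20.0
    focus_amplitude: float = 150.0
    patch_amplitude: float = 90.0
    patch_sigma_factor: float = 1.6
    noise_sd: float = 6.0
    fast_rate_mean: float = 1.66e-4
    fast_rate_sd: float = 2.39e-5
    slow_rate_mean: float = 7.87e-5
    slow_rate_sd: float = 8.80e-6
    birth_length_mean: float = 6.5
    birth_length_sd: float = 1.8
    min_length: float = 2.0
    placement_offset_sd: float = 0.066
    wander_step_sd: float = 0.6
    wander_lo: float = 0.15
    wander_hi: float = 0.85
    appearance_delay_mean: float = 30.0
    appearance_delay_sd: float = 10.0
    condensation_frames_mean: float = 3.0
    condensation_frames_sd: float = 1.0
    invagination_delay: float = 160.0
    invagination_frames: int = 3
    separation_gap: float = 0.5
    fast_on_short_prob: float = 0.78
    inherit_old_pole_rate: bool = True
    n_cells: int = 24
    n_frames: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        nonneg = (
            "cell_width psf_sigma background_level cell_contrast "
            "fluor_background focus_amplitude patch_amplitude noise_sd "
            "fast_rate_mean fast_rate_sd slow_rate_mean slow_rate_sd "
            "birth_length_mean birth_length_sd min_length wander_step_sd "
            "appearance_delay_mean appearance_delay_sd "
            "condensation_frames_mean condensation_frames_sd "
            "invagination_delay separation_gap"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.placement_offset_sd < 0.5):
            raise ConfigurationError("placement_offset_sd must be in [0, 0.5)")
        if not (0.0 < self.wander_lo < self.wander_hi < 1.0):
            raise ConfigurationError("need 0 < wander_lo < wander_hi < 1")
        if not (0.0 <= self.fast_on_short_prob <= 1.0):
            raise ConfigurationError("fast_on_short_prob must be in [0, 1]")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.n_frames is not None and self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1 (or None)")
        if self.invagination_frames < 0:
            raise ConfigurationError("invagination_frames must be >= 0")

    # -- derived pixel-space quantities -----------------------------------
    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    @property
    def cell_width_px(self) -> float:
        return self.cell_width / self.pixel_size

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path} is not a key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)
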