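"""Simulation configuration: parameters of the synthetic time-kill experiment."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

LINK_SHAPES = ("continuous_negative", "continuous_positive", "threshold_top_decile", "none")


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic single-cell time-kill experiment.

    Defaults mirror a typical time-lapse design: five replicate
    microscopy positions of ~100 cells each, imaged every 5 minutes for
    5 hours, with cell killing concentrated between 1 and 3 hours after
    antibiotic addition.

    Parameters
    ----------
    n_positions
        Number of replicate microscopy positions (pads).
    cells_per_position
        Cells tracked per position.
    frame_interval
        Minutes between consecutive frames.
    movie_length
        Total movie duration in minutes; must be a positive multiple of
        ``frame_interval``.  Cells still alive at the final frame are
        right-censored.
    fluor_log_mean, fluor_log_sd
        Mean and standard deviation of log initial fluorescence
        (arbitrary units); initial expression is log-normal.
    link_shape
        How initial fluorescence maps to death time:
        ``continuous_negative`` (bright cells die later — a negative
        relationship between killing and expression),
        ``continuous_positive`` (bright cells die sooner),
        ``threshold_top_decile`` (only the brightest 10% gain extended
        survival), or ``none`` (death independent of expression).
    link_strength
        Death-time span attributable to expression, in minutes.  For
        the continuous shapes the deterministic death-time component
        ranges over ``link_strength`` minutes from the dimmest to the
        brightest cell; for the threshold shape the top decile is
        shifted later by ``link_strength`` minutes.
    death_time_center
        Center of the death-time distribution in minutes.
    death_time_noise_sd
        SD of Gaussian death-time noise, minutes.
    size_death_coupling
        Death-time span (minutes) attributable to initial cell size;
        positive values make larger cells die later.
    growth_death_coupling
        Death-time span (minutes) attributable to early growth rate;
        positive values make fast-growing cells die sooner (slow
        growers survive longer).
    seed
        Global RNG seed; per-position substreams are derived from it.
    """

    n_positions: int = 5
    cells_per_position: int = 100
    frame_interval: float = 5.0
    movie_length: float = 300.0
    fluor_log_mean: float = 5.0
    fluor_log_sd: float = 0.5
    link_shape: str = "continuous_negative"
    link_strength: float = 120.0
    death_time_center: float = 120.0
    death_time_noise_sd: float = 15.0
    size_death_coupling: float = 0.0
    growth_death_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_positions < 1:
            raise ConfigError(f"n_positions must be >= 1, got {self.n_positions}")
        if self.cells_per_position < 1:
            raise ConfigError(
                f"cells_per_position must be >= 1, got {self.cells_per_position}"
            )
        if self.frame_interval <= 0:
            raise ConfigError(f"frame_interval must be > 0, got {self.frame_interval}")
        n_frames = self.movie_length / self.frame_interval
        if self.movie_length <= 0 or abs(n_frames - round(n_frames)) > 1e-9:
            raise ConfigError(
                "movie_length must be a positive multiple of frame_interval, "
                f"got movie_length={self.movie_length}, frame_interval={self.frame_interval}"
            )
        if self.fluor_log_sd < 0:
            raise ConfigError(f"fluor_log_sd must be >= 0, got {self.fluor_log_sd}")
        if self.death_time_noise_sd < 0:
            raise ConfigError(
                f"death_time_noise_sd must be >= 0, got {self.death_time_noise_sd}"
            )
        if self.link_strength < 0:
            raise ConfigError(f"link_strength must be >= 0, got {self.link_strength}")
        if self.link_shape not in LINK_SHAPES:
            raise ConfigError(
                f"link_shape must be one of {LINK_SHAPES}, got {self.link_shape!r}"
            )
        if not math.isfinite(self.death_time_center):
            raise ConfigError(f"death_time_center must be finite, got {self.death_time_center}")

    @property
    def n_cells(self) -> int:
        return self.n_positions * self.cells_per_position

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
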