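"""Run configuration: YAML-loadable settings shared by the CLI commands.

The schema is flat and small; unknown keys are rejected on load so typos do
not silently fall back to defaults.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .filters import BandSpec, DEFAULT_BAND

__all__ = ["RunConfig", "load_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Settings for a benchmark or filtering run.

    f_low/f_high: bandpass edges, Hz.  fs: sampling rate, Hz.
    window_len_s: SQI window, seconds.  passband_ripple_db applies to
    Chebyshev I and elliptic designs; stopband attenuation is per family.
    seed feeds the synthetic generator.
    """

    fs: float = 1000.0
    f_low: float = DEFAULT_BAND.f_low
    f_high: float = DEFAULT_BAND.f_high
    window_len_s: float = 1.0
    passband_ripple_db: float = 0.1
    cheby2_stopband_db: float = 20.0
    elliptic_stopband_db: float = 30.0
    seed: int = 0
    duration_s: float = 2.1
    n_per_group: Tuple[int, int, int] = (36, 132, 51)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not (0 < self.f_low < self.f_high < self.fs / 2):
            raise ValueError(
                f"need 0 < f_low < f_high < fs/2, got ({self.f_low}, {self.f_high}) at fs={self.fs}"
            )
        if self.window_len_s <= 0:
            raise ValueError("window_len_s must be positive")
        if self.duration_s < self.window_len_s:
            raise ValueError("duration_s must cover at least one window")

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.f_low, self.f_high)

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", asdict(self))


def load_config(path: Optional[Path] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    YAML keys must match RunConfig field names exactly; unknown keys raise.
    """
    values = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        allowed = set(RunConfig.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "n_per_group" in values:
        values["n_per_group"] = tuple(values["n_per_group"])
    return RunConfig(**values)
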