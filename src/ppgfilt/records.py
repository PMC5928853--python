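"""Domain types for short single-channel PPG records.

A record is one sampled photoplethysmogram segment together with its
sampling rate, identity, and an optional expert quality label.  The study
conditions this package targets are 2.1-second segments sampled at 1 kHz
with 12-bit amplitude resolution, graded by experts as

* ``G1`` — excellent: complete systole and diastole, dicrotic/tidal waves visible;
* ``G2`` — acceptable: complete systole, secondary waves polluted by noise;
* ``G3`` — unfit: noise dominates, heartbeat period indistinguishable.

Nothing in the types enforces those exact study dimensions; any positive
sampling rate and non-empty finite sample vector is a valid record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "QUALITY_LABELS",
    "UNLABELED",
    "PPGRecord",
    "Annotation",
    "SubjectMeta",
    "ADC_MAX",
]

#: Expert quality grades, best to worst.
QUALITY_LABELS = ("G1", "G2", "G3")

#: Placeholder label for records without an annotation.
UNLABELED = "unlabeled"

#: Full-scale value of a 12-bit analog-to-digital converter.
ADC_MAX = 4095


@dataclass(frozen=True)
class PPGRecord:
    """One sampled PPG segment.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values in arbitrary units (nominally the 12-bit ADC range
        0–4095, but stored as-is: no clipping is applied on construction).
    fs : float
        Sampling rate in Hz; must be positive.
    subject_id, segment_id : str
        Identity of the record within a dataset.
    label : str
        One of ``G1``/``G2``/``G3`` or ``"unlabeled"``.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    segment_id: str = ""
    label: str = UNLABELED

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            samples = samples.ravel()
        if samples.size == 0:
            raise ValueError("PPGRecord requires a non-empty sample vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("PPGRecord samples must all be finite")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be positive and finite, got {self.fs}")
        if self.label not in QUALITY_LABELS and self.label != UNLABELED:
            raise ValueError(
                f"label must be one of {QUALITY_LABELS + (UNLABELED,)}, got {self.label!r}"
            )
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (``n_samples / fs``)."""
        return self.samples.size / self.fs

    def with_samples(self, samples: Sequence[float]) -> "PPGRecord":
        """A copy with new samples but identical metadata (ids, fs, label)."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def time_axis(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class Annotation:
    """An expert quality grade attached to one record."""

    subject_id: str
    segment_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in QUALITY_LABELS:
            raise ValueError(f"label must be one of {QUALITY_LABELS}, got {self.label!r}")


def _check_positive(name: str, value: Optional[float]) -> None:
    if value is not None and not (value > 0 and np.isfinite(value)):
        raise ValueError(f"{name} must be positive and finite when present, got {value}")


@dataclass(frozen=True)
class SubjectMeta:
    """Optional demographic / physiological metadata for one subject.

    All quantitative fields are optional; when present they must be positive
    and finite.  Units: age in years, height in cm, weight in kg, blood
    pressures in mmHg, heart rate in beats/min.
    """

    subject_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    heart_rate: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("age", "height", "weight", "sbp", "dbp", "heart_rate"):
            _check_positive(name, getattr(self, name))
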