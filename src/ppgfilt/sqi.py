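"""Skewness signal-quality index (S_SQI) with windowed record scoring.

The index for a window of N samples x_1..x_N is the third standardized
moment with population (1/N) normalization throughout:

    S_SQI = (1/N) * sum_i ((x_i - mean(x)) / sd(x))^3,   sd = population sd.

A clean PPG beat is strongly asymmetric (sharp systolic upstroke), so good
windows score high positive skewness; symmetric noise scores near zero.  A
record is scored by computing the index on consecutive non-overlapping
windows (1 s by default, left-aligned, trailing remainder discarded) and
taking the maximum over windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .records import PPGRecord

__all__ = ["SQIResult", "skewness", "windowed_sqi"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SQIResult:
    """Per-window skewness values and the record-level index.

    ``record_sqi`` is the maximum of ``per_window``; ``n_windows`` equals
    ``floor(duration_s / window_len_s)``.
    """

    per_window: Tuple[float, ...]
    record_sqi: float
    window_len_s: float
    n_windows: int


def skewness(x: Sequence[float], *, sample_sd: bool = False) -> float:
    """Third standardized moment of a sample.

    Parameters
    ----------
    x : sequence of float
        At least two finite values.
    sample_sd : bool
        Use the (1/(N-1)) sample standard deviation instead of the
        population (1/N) one.  Off by default: the population form matches
        the moment definition of the index.

    Returns
    -------
    float
        Dimensionless skewness.  Invariant under ``a*x + b`` for ``a > 0``;
        negates under ``x -> -x``.  A constant input has undefined skewness;
        by convention 0.0 is returned (with a logged warning) so that batch
        scoring never aborts on degenerate filter outputs.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"skewness requires at least 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("skewness requires finite samples")
    mu = x.mean()
    sd = x.std(ddof=1 if sample_sd else 0)
    # relative guard: an exactly-constant signal offset by a large mean can
    # leave sd at round-off level; z-scores would then be pure noise
    if sd == 0.0 or sd < 1e-12 * abs(mu):
        logger.warning("constant input to skewness; returning 0.0 by convention")
        return 0.0
    return float(np.mean(((x - mu) / sd) ** 3))


def windowed_sqi(record: PPGRecord, window_len_s: float = 1.0) -> SQIResult:
    """Score a record: max skewness over non-overlapping windows.

    The record is partitioned into consecutive windows of
    ``round(window_len_s * fs)`` samples starting at sample 0; a trailing
    remainder shorter than one window is discarded (a 2.1-s record at 1 kHz
    scored with 1-s windows yields exactly 2 windows).

    Raises
    ------
    ValueError
        If the record is shorter than one window.
    """
    if window_len_s <= 0:
        raise ValueError(f"window_len_s must be positive, got {window_len_s}")
    win = int(round(window_len_s * record.fs))
    if win < 2:
        raise ValueError(
            f"window of {window_len_s} s at fs={record.fs} Hz spans {win} sample(s); need >= 2"
        )
    n_windows = record.n_samples // win
    if n_windows == 0:
        raise ValueError(
            f"record of {record.n_samples} samples is shorter than one "
            f"{window_len_s} s window ({win} samples) at fs={record.fs} Hz"
        )
    per_window = tuple(
        skewness(record.samples[i * win : (i + 1) * win]) for i in range(n_windows)
    )
    return SQIResult(
        per_window=per_window,
        record_sqi=max(per_window),
        window_len_s=float(window_len_s),
        n_windows=n_windows,
    )
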