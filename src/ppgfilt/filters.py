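"""The nine-family digital filter bank and its zero-phase application.

Families and order grids (9 families x 10 orders = 90 configurations):

================  =============================  =========================
family            order parameter                meaning
================  =============================  =========================
moving_average    0.05, 0.10, ..., 0.50          window length, seconds
median            0.05, 0.10, ..., 0.50          window length, seconds
fir_hamming       0.05, 0.10, ..., 0.50          impulse-response length, s
fir_ls            0.05, 0.10, ..., 0.50          impulse-response length, s
butterworth       2, 4, ..., 20                  bandpass design order
cheby1            2, 4, ..., 20                  bandpass design order
cheby2            2, 4, ..., 20                  bandpass design order
elliptic          2, 4, ..., 20                  bandpass design order
wavelet           1, 2, ..., 10                  decomposition level
================  =============================  =========================

"Order" for the IIR families is the design-function argument, exactly as in
the standard ``butter``/``cheby1``/``cheby2``/``ellip`` APIs; a bandpass of
design order N has effective order 2N.  So the recommended "4th-order
Chebyshev II" is a design-order-4 (effective 8th-order) bandpass.

Design constants: Chebyshev I and elliptic passband ripple 0.1 dB;
Chebyshev II stopband attenuation 20 dB; elliptic stopband 30 dB.  Window
and tap lengths given in seconds convert via ``round(len_s * fs)``;
moving-average and median windows are forced odd so the window is centered.

Linear filters are applied forward-backward (zero phase, squared magnitude)
with odd-reflection edge padding; the sliding-window filters use centered
windows that shrink symmetrically at the edges; wavelet denoising is
zero-phase by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .records import PPGRecord

__all__ = [
    "FAMILIES",
    "ORDER_GRIDS",
    "DEFAULT_BAND",
    "BandSpec",
    "FilterSpec",
    "DesignedFilter",
    "FilterDesignError",
    "design_filter",
    "apply_zero_phase",
    "enumerate_bank",
    "optimal_filter",
]

logger = logging.getLogger(__name__)

#: Family names, in canonical enumeration order.
FAMILIES = (
    "moving_average",
    "median",
    "fir_hamming",
    "fir_ls",
    "butterworth",
    "cheby1",
    "cheby2",
    "elliptic",
    "wavelet",
)

_WINDOW_GRID = tuple(round(0.05 * k, 2) for k in range(1, 11))  # seconds
_IIR_GRID = tuple(range(2, 21, 2))  # design order
_WAVELET_GRID = tuple(range(1, 11))  # decomposition level

#: Per-family order grids (ascending).
ORDER_GRIDS: Dict[str, tuple] = {
    "moving_average": _WINDOW_GRID,
    "median": _WINDOW_GRID,
    "fir_hamming": _WINDOW_GRID,
    "fir_ls": _WINDOW_GRID,
    "butterworth": _IIR_GRID,
    "cheby1": _IIR_GRID,
    "cheby2": _IIR_GRID,
    "elliptic": _IIR_GRID,
    "wavelet": _WAVELET_GRID,
}

_IIR_FAMILIES = ("butterworth", "cheby1", "cheby2", "elliptic")
_FIR_FAMILIES = ("fir_hamming", "fir_ls")
_WINDOW_FAMILIES = ("moving_average", "median")

#: Default design constants (dB), overridable per spec.
DEFAULT_PASSBAND_RIPPLE_DB = {"cheby1": 0.1, "elliptic": 0.1}
DEFAULT_STOPBAND_ATTEN_DB = {"cheby2": 20.0, "elliptic": 30.0}

_WAVELET_NAME = "db2"


class FilterDesignError(RuntimeError):
    """A filter design failed (e.g. an unstable IIR realization)."""


@dataclass(frozen=True)
class BandSpec:
    """Bandpass edges in Hz.  Must satisfy 0 < f_low < f_high < fs/2."""

    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"need 0 < f_low < f_high, got ({self.f_low}, {self.f_high})")

    def validate_for(self, fs: float) -> None:
        if not self.f_high < fs / 2:
            raise ValueError(
                f"f_high={self.f_high} Hz must be below the Nyquist rate {fs / 2} Hz"
            )


#: Default PPG passband: covers cardiac fundamentals (~0.7–2 Hz at rest)
#: and their harmonics, rejects baseline wander and high-frequency noise.
DEFAULT_BAND = BandSpec(0.5, 8.0)


@dataclass(frozen=True)
class FilterSpec:
    """A named filter family plus order and design constants.

    ``passband_ripple_db`` / ``stopband_atten_db`` default to the family's
    standard constants when left ``None`` and are ignored by families that
    do not use them.
    """

    family: str
    order_param: float
    passband_ripple_db: Optional[float] = None
    stopband_atten_db: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not (self.order_param > 0 and np.isfinite(self.order_param)):
            raise ValueError(f"order_param must be positive, got {self.order_param}")
        if self.family in ("butterworth", "cheby1", "cheby2", "elliptic", "wavelet"):
            if self.order_param != int(self.order_param):
                raise ValueError(
                    f"{self.family} order must be an integer, got {self.order_param}"
                )

    @property
    def ripple_db(self) -> Optional[float]:
        if self.passband_ripple_db is not None:
            return self.passband_ripple_db
        return DEFAULT_PASSBAND_RIPPLE_DB.get(self.family)

    @property
    def atten_db(self) -> Optional[float]:
        if self.stopband_atten_db is not None:
            return self.stopband_atten_db
        return DEFAULT_STOPBAND_ATTEN_DB.get(self.family)

    def on_grid(self) -> bool:
        """Whether ``order_param`` belongs to the family's published grid."""
        grid = ORDER_GRIDS[self.family]
        return any(np.isclose(self.order_param, g) for g in grid)


@dataclass(frozen=True)
class DesignedFilter:
    """A realized, applicable filter.

    ``kind`` is ``linear_iir`` (coefficients = second-order-section array),
    ``linear_fir`` (coefficients = tap vector), or ``procedural``
    (coefficients = parameter dict for the sliding-window or wavelet
    procedures).  ``effective_order`` drives the forward-backward padding
    length for linear filters.
    """

    spec: FilterSpec
    kind: str
    coefficients: object
    fs: float
    band: Optional[BandSpec]
    effective_order: int = 0

    @property
    def sos(self) -> np.ndarray:
        if self.kind != "linear_iir":
            raise AttributeError("sos available only for linear_iir filters")
        return self.coefficients  # type: ignore[return-value]

    @property
    def taps(self) -> np.ndarray:
        if self.kind != "linear_fir":
            raise AttributeError("taps available only for linear_fir filters")
        return self.coefficients  # type: ignore[return-value]


def _odd_window_samples(len_s: float, fs: float) -> int:
    n = int(round(len_s * fs))
    if n < 1:
        n = 1
    if n % 2 == 0:
        n += 1  # force odd so the window has a center sample
    return n


def _sos_is_stable(sos: np.ndarray) -> bool:
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            return False
    return True


def design_filter(spec: FilterSpec, fs: float, band: Optional[BandSpec] = None) -> DesignedFilter:
    """Realize a filter specification at a sampling rate and passband.

    The IIR families are designed as bandpass second-order-section cascades
    (stability is verified; an unstable realization raises rather than
    returning silently).  The least-squares FIR uses stopband edges
    ``f_low - 0.2`` Hz and ``f_high + 2`` Hz; if the lower stopband edge
    would be non-positive it is clamped to ``f_low / 2`` with a warning.
    ``band`` is ignored by the sliding-window and wavelet families.
    """
    band = band if band is not None else DEFAULT_BAND
    family = spec.family

    if family in _IIR_FAMILIES or family in _FIR_FAMILIES:
        band.validate_for(fs)

    if family in _IIR_FAMILIES:
        n = int(spec.order_param)
        wn = [band.f_low, band.f_high]
        if family == "butterworth":
            sos = signal.butter(n, wn, btype="bandpass", output="sos", fs=fs)
        elif family == "cheby1":
            sos = signal.cheby1(n, spec.ripple_db, wn, btype="bandpass", output="sos", fs=fs)
        elif family == "cheby2":
            sos = signal.cheby2(n, spec.atten_db, wn, btype="bandpass", output="sos", fs=fs)
        else:  # elliptic
            sos = signal.ellip(
                n, spec.ripple_db, spec.atten_db, wn, btype="bandpass", output="sos", fs=fs
            )
        if not _sos_is_stable(sos):
            raise FilterDesignError(
                f"{family} design order {n} at fs={fs} Hz yields an unstable "
                "second-order-section cascade"
            )
        return DesignedFilter(
            spec=spec, kind="linear_iir", coefficients=sos, fs=fs, band=band,
            effective_order=2 * n,
        )

    if family == "fir_hamming":
        order = int(round(spec.order_param * fs))
        taps = signal.firwin(
            order + 1, [band.f_low, band.f_high], window="hamming", pass_zero=False, fs=fs
        )
        return DesignedFilter(
            spec=spec, kind="linear_fir", coefficients=taps, fs=fs, band=band,
            effective_order=order,
        )

    if family == "fir_ls":
        order = int(round(spec.order_param * fs))
        if order % 2 == 1:
            order += 1  # firls needs an even order (odd tap count, type-I FIR)
        stop_lo = band.f_low - 0.2
        if stop_lo <= 0:
            stop_lo = band.f_low / 2
            logger.warning(
                "fir_ls lower stopband edge f_low-0.2 is non-positive; clamped to %.3g Hz",
                stop_lo,
            )
        stop_hi = band.f_high + 2.0
        if stop_hi >= fs / 2:
            raise ValueError(
                f"fir_ls upper stopband edge {stop_hi} Hz exceeds Nyquist at fs={fs}"
            )
        bands = [0.0, stop_lo, band.f_low, band.f_high, stop_hi, fs / 2]
        desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
        taps = signal.firls(order + 1, bands, desired, fs=fs)
        return DesignedFilter(
            spec=spec, kind="linear_fir", coefficients=taps, fs=fs, band=band,
            effective_order=order,
        )

    if family in _WINDOW_FAMILIES:
        n = _odd_window_samples(spec.order_param, fs)
        return DesignedFilter(
            spec=spec, kind="procedural", coefficients={"window": n}, fs=fs, band=None,
        )

    # wavelet
    level = int(spec.order_param)
    return DesignedFilter(
        spec=spec, kind="procedural",
        coefficients={"level": level, "wavelet": _WAVELET_NAME}, fs=fs, band=None,
    )


def _moving_average_shrink(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average; near the edges the (odd) window shrinks
    symmetrically so it stays centered, down to a single sample."""
    if n == 1 or x.size == 1:
        return x.copy()
    half = n // 2
    y = np.empty_like(x)
    if x.size >= n:
        core = np.convolve(x, np.full(n, 1.0 / n), mode="valid")
        y[half : x.size - half] = core
        edge = half
    else:
        edge = (x.size + 1) // 2
    for i in range(min(edge, x.size)):
        h = min(i, half, x.size - 1 - i)
        y[i] = x[max(i - h, 0) : i + h + 1].mean()
    for i in range(max(x.size - edge, 0), x.size):
        h = min(i, half, x.size - 1 - i)
        y[i] = x[i - h : i + h + 1].mean()
    return y


def _median_shrink(x: np.ndarray, n: int) -> np.ndarray:
    """Centered sliding median with the same symmetric edge shrinkage."""
    if n == 1 or x.size == 1:
        return x.copy()
    half = n // 2
    y = np.empty_like(x)
    if x.size >= n:
        y[half : x.size - half] = np.median(sliding_window_view(x, n), axis=1)
        edge = half
    else:
        edge = (x.size + 1) // 2
    for i in range(min(edge, x.size)):
        h = min(i, half, x.size - 1 - i)
        y[i] = np.median(x[max(i - h, 0) : i + h + 1])
    for i in range(max(x.size - edge, 0), x.size):
        h = min(i, half, x.size - 1 - i)
        y[i] = np.median(x[i - h : i + h + 1])
    return y


def _wavelet_denoise(x: np.ndarray, level: int, wavelet: str) -> np.ndarray:
    """Shift-invariant (stationary) wavelet denoising.

    Decompose with the undecimated transform, soft-threshold each detail
    level with its own universal threshold sigma_j * sqrt(2 ln n) where
    sigma_j is the median-absolute-deviation noise estimate of that level's
    coefficients, then reconstruct.  The input is reflection-padded at the
    tail to the length multiple the undecimated transform requires and
    truncated after reconstruction.
    """
    n = x.size
    mult = 2**level
    pad = (-n) % mult
    if pad:
        xp = np.pad(x, (0, pad), mode="reflect")
    else:
        xp = x
    max_level = pywt.swt_max_level(xp.size)
    if level > max_level:
        raise FilterDesignError(
            f"wavelet level {level} exceeds the maximum {max_level} for a "
            f"record of {n} samples"
        )
    coeffs = pywt.swt(xp, wavelet, level=level, trim_approx=True, norm=True)
    # coeffs = [approx, detail_level, ..., detail_1]
    thresholded = [coeffs[0]]
    for d in coeffs[1:]:
        sigma = np.median(np.abs(d)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(xp.size))
        thresholded.append(pywt.threshold(d, thr, mode="soft"))
    y = pywt.iswt(thresholded, wavelet, norm=True)
    return np.asarray(y)[:n]


def apply_zero_phase(f: DesignedFilter, record: PPGRecord) -> PPGRecord:
    """Filter a record without phase distortion; metadata is preserved.

    Linear filters run forward then backward (``filtfilt``), giving the
    squared magnitude response and zero group delay, with odd-reflection
    edge padding of length ``min(3 * effective_order, len - 1)``.  The
    moving-average and median filters are centered sliding windows (already
    phase-free); wavelet denoising is applied once.
    """
    if record.fs != f.fs:
        raise ValueError(
            f"record fs={record.fs} Hz does not match filter fs={f.fs} Hz"
        )
    x = record.samples
    if x.size < 2:
        raise ValueError("cannot filter a record with fewer than 2 samples")

    if f.kind == "linear_iir":
        padlen = min(3 * f.effective_order, x.size - 1)
        y = signal.sosfiltfilt(f.sos, x, padtype="odd", padlen=padlen)
    elif f.kind == "linear_fir":
        padlen = min(3 * f.effective_order, x.size - 1)
        y = signal.filtfilt(f.taps, [1.0], x, padtype="odd", padlen=padlen)
    elif f.spec.family == "moving_average":
        y = _moving_average_shrink(x, f.coefficients["window"])
    elif f.spec.family == "median":
        y = _median_shrink(x, f.coefficients["window"])
    elif f.spec.family == "wavelet":
        y = _wavelet_denoise(x, f.coefficients["level"], f.coefficients["wavelet"])
    else:  # pragma: no cover - unreachable by construction
        raise FilterDesignError(f"cannot apply filter of kind {f.kind!r}")

    return record.with_samples(y)


def enumerate_bank() -> List[FilterSpec]:
    """The full benchmark grid: 9 families x 10 orders = 90 specifications,
    in deterministic order (family enumeration order, ascending order)."""
    bank: List[FilterSpec] = []
    for family in FAMILIES:
        for order in ORDER_GRIDS[family]:
            bank.append(FilterSpec(family=family, order_param=order))
    return bank


def optimal_filter(fs: float, band: Optional[BandSpec] = None) -> DesignedFilter:
    """The recommended configuration: design-order-4 Chebyshev II bandpass
    (20 dB stopband attenuation), realized at the given rate and band."""
    return design_filter(FilterSpec(family="cheby2", order_param=4), fs=fs, band=band)
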