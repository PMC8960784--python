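"""Tremor features: vector-magnitude PSD band-power ratio and task time.

The primary tremor feature is the ratio of integrated power spectral density
of the acceleration vector magnitude in the tremor band (4–12 Hz) to that in
the voluntary-movement band (0.5–4 Hz).  Taking the vector magnitude
sqrt(ax^2 + ay^2 + az^2) makes the feature invariant to sensor mounting
orientation, and taking a ratio of band powers makes it invariant to the
acceleration unit, removing the need for per-subject normalisation.

Processing order: magnitude first, then a zero-phase 0.5 Hz high-pass (which
removes the gravity offset embedded in the magnitude), then Welch PSD
estimation and trapezoidal band integration.  Band edges are half-open /
closed — [0.5, 4) and [4, 12] — so that a 4 Hz component counts as tremor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    InvalidBandError,
    TooShortError,
    UndefinedRatioError,
)
from .ingest import AccelTrace, PenTrace, segment_task, slice_accel

logger = logging.getLogger(__name__)

#: Voluntary-movement band, Hz (half-open: upper edge excluded).
BAND_LOW = (0.5, 4.0)
#: Tremor band, Hz (closed: both edges included).
BAND_HIGH = (4.0, 12.0)

#: Welch defaults: Hann window, 4 s segments (0.25 Hz resolution, resolving
#: the 0.5 Hz band edge), 50% overlap.
WELCH_SEGMENT_S = 4.0
WELCH_OVERLAP = 0.5
WELCH_WINDOW = "hann"

FILTER_ORDER = 4
FILTER_CUTOFF = 0.5


@dataclass
class MagnitudeSignal:
    """Acceleration vector-magnitude time series.

    ``filtered`` records whether the high-pass has been applied; band powers
    are only meaningful afterwards (the raw magnitude is dominated by the
    constant gravity offset).
    """

    t: np.ndarray
    m: np.ndarray
    fs: float
    filtered: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.t.size != self.m.size:
            raise ValueError("time and magnitude arrays must have equal length")
        if not self.filtered and np.any(self.m < 0):
            raise ValueError("unfiltered magnitude must be non-negative")

    def __len__(self) -> int:
        return self.m.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size > 1 else 0.0


@dataclass(frozen=True)
class BandPowers:
    """Integrated band powers and their ratio rho = p_high / p_low."""

    p_low: float
    p_high: float

    @property
    def ratio(self) -> float:
        return self.p_high / self.p_low


@dataclass(frozen=True)
class SubjectFeatures:
    """The per subject x site feature pair used by all downstream stages."""

    subject_id: str
    site: str
    psd_ratio: float
    task_time: float

    def __post_init__(self) -> None:
        if self.task_time <= 0:
            raise ValueError("task_time must be positive")
        if self.psd_ratio < 0:
            raise ValueError("psd_ratio must be non-negative")


def vector_magnitude(accel: AccelTrace) -> MagnitudeSignal:
    """Orientation-invariant magnitude sqrt(ax^2 + ay^2 + az^2)."""
    m = np.sqrt(accel.ax**2 + accel.ay**2 + accel.az**2)
    assert accel.fs is not None
    return MagnitudeSignal(t=accel.t, m=m, fs=accel.fs, filtered=False)


def highpass(
    sig: MagnitudeSignal,
    cutoff: float = FILTER_CUTOFF,
    order: int = FILTER_ORDER,
) -> MagnitudeSignal:
    """Zero-phase Butterworth high-pass; removes gravity and slow artefacts.

    Applied forward-backward (``sosfiltfilt``) so the effective attenuation
    is twice the one-pass Butterworth roll-off and the phase is zero.
    """
    if sig.fs <= 2 * cutoff:
        raise InvalidBandError(f"fs={sig.fs} Hz cannot support a {cutoff} Hz high-pass")
    sos = sps.butter(order, cutoff, btype="highpass", fs=sig.fs, output="sos")
    try:
        filtered = sps.sosfiltfilt(sos, sig.m)
    except ValueError as exc:  # input shorter than the filter padding
        raise TooShortError(f"signal too short for the high-pass filter: {exc}") from exc
    return MagnitudeSignal(t=sig.t, m=filtered, fs=sig.fs, filtered=True)


def _welch_psd(
    sig: MagnitudeSignal,
    segment_s: float = WELCH_SEGMENT_S,
    overlap: float = WELCH_OVERLAP,
    window: str = WELCH_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(sig)
    nperseg = int(round(segment_s * sig.fs))
    if nperseg > n:
        # short recordings fall back to a single-segment periodogram
        logger.warning(
            "signal of %.2f s is shorter than the %.0f s Welch segment; "
            "falling back to a single-segment periodogram",
            sig.duration,
            segment_s,
        )
        nperseg = n
    noverlap = int(round(overlap * nperseg))
    return sps.welch(sig.m, fs=sig.fs, window=window, nperseg=nperseg, noverlap=noverlap)


def band_power(
    sig: MagnitudeSignal,
    band: tuple[float, float],
    include_upper: bool = True,
    **welch_kwargs,
) -> float:
    """Welch PSD integrated over ``band`` with the trapezoidal rule.

    ``include_upper`` selects the closed upper edge (tremor band) versus the
    half-open convention (voluntary band), so the shared 4 Hz edge is counted
    exactly once in the ratio.
    """
    f1, f2 = band
    if not sig.filtered:
        raise ValueError("band_power expects a high-pass-filtered signal")
    if not (0 <= f1 < f2 <= sig.fs / 2):
        raise InvalidBandError(
            f"band [{f1}, {f2}] Hz is invalid for fs={sig.fs:.2f} Hz (Nyquist "
            f"{sig.fs / 2:.2f} Hz)"
        )
    if sig.duration < MIN_DURATION_S:
        raise TooShortError(
            f"{sig.duration:.2f} s signal is too short for band-power estimation"
        )
    freqs, psd = _welch_psd(sig, **welch_kwargs)
    mask = (freqs >= f1) & ((freqs <= f2) if include_upper else (freqs < f2))
    if mask.sum() < 2:
        raise InvalidBandError(f"band [{f1}, {f2}] Hz covers fewer than 2 PSD bins")
    return float(np.trapezoid(psd[mask], freqs[mask]))


MIN_DURATION_S = 2.0


def psd_ratio(
    sig: MagnitudeSignal,
    band_low: tuple[float, float] = BAND_LOW,
    band_high: tuple[float, float] = BAND_HIGH,
    **welch_kwargs,
) -> BandPowers:
    """The tremor-band : voluntary-band integrated PSD ratio.

    The low band is integrated over [f1, f2) and the high band over [f1, f2],
    so a component exactly at the shared edge belongs to the tremor band.
    """
    p_low = band_power(sig, band_low, include_upper=False, **welch_kwargs)
    p_high = band_power(sig, band_high, include_upper=True, **welch_kwargs)
    floor = np.finfo(float).tiny * max(1.0, len(sig))
    if p_low <= floor:
        raise UndefinedRatioError(
            "voluntary-band power is at the machine-precision floor; "
            "PSD ratio undefined"
        )
    return BandPowers(p_low=p_low, p_high=p_high)


def extract_features(
    accel: AccelTrace,
    pen: PenTrace,
    subject_id: str = "",
    clock_offset: float = 0.0,
    min_stroke_duration: float = 0.0,
    **welch_kwargs,
) -> SubjectFeatures:
    """Full feature extraction for one subject x site.

    Composition: segment_task -> slice_accel -> vector_magnitude -> highpass
    -> psd_ratio, paired with the task time T from the pen stream.
    """
    window = segment_task(pen, min_stroke_duration=min_stroke_duration)
    segment = slice_accel(accel, window, clock_offset=clock_offset)
    mag = highpass(vector_magnitude(segment))
    powers = psd_ratio(mag, **welch_kwargs)
    return SubjectFeatures(
        subject_id=subject_id,
        site=accel.site,
        psd_ratio=powers.ratio,
        task_time=window.pen_down_duration,
    )
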