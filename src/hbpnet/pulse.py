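"""Reference pulse handling and heartbeat-probability (HBP) label construction.

A contact pulse trace (BVP/PPG) is the supervision source for video-based
heart-rate models.  This module turns such a trace into (a) a clean sequence
of systolic peak indices and (b) a per-frame *heartbeat probability* map: a
value in [0, 1] for every video frame that equals 1 exactly at each beat and
decays smoothly as a raised cosine between beats.  Smooth targets, rather
than isolated impulses, are what make per-frame probability supervision
trainable — the same reason keypoint detectors blur their target heatmaps.

Conventions
-----------
Indexing is 0-based; an HBP map sample ``i`` corresponds to video frame ``i``.
Peak indices and inter-beat intervals are in frames of the indexed axis and
convert to seconds through its rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "PulseTrace",
    "PeakSequence",
    "HbpMap",
    "bandpass_pulse",
    "resample_normalize",
    "detect_peaks",
    "psd_hr",
    "filter_peaks_ibi",
    "validate_peaks_psd",
    "PsdValidationReport",
    "hbp_from_peaks",
]

#: Cardiac frequency band in Hz (42–180 bpm).
CARDIAC_BAND = (0.7, 3.0)


@dataclass(frozen=True)
class PulseTrace:
    """A sampled pulse signal with its sampling rate.

    Parameters
    ----------
    samples : ndarray
        Amplitude values, finite, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Start-time offset in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("pulse trace needs a 1-D array of at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("pulse trace contains non-finite values")

    @property
    def duration(self) -> float:
        """Trace duration in seconds (span of the sample grid)."""
        return (self.samples.size - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class PeakSequence:
    """Strictly ascending peak indices on an axis sampled at ``fs`` Hz."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if idx.size >= 2 and not np.all(np.diff(idx) > 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def intervals(self) -> np.ndarray:
        """Consecutive inter-peak intervals in samples (empty if < 2 peaks)."""
        return np.diff(self.indices)

    @property
    def d_max(self) -> int:
        """Largest inter-peak interval; defined only with >= 2 peaks."""
        if len(self) < 2:
            raise ValueError("d_max requires at least 2 peaks")
        return int(np.max(self.intervals))

    def mean_hr_bpm(self) -> float:
        """Heart rate from the mean inter-beat interval."""
        if len(self) < 2:
            raise ValueError("need at least 2 peaks for a heart rate")
        return 60.0 * self.fs / float(np.mean(self.intervals))


@dataclass(frozen=True)
class HbpMap:
    """Per-frame heartbeat probabilities: ``values[i]`` in [0, 1] for frame i."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if values.ndim != 1:
            raise ValueError("HBP map must be 1-D")
        if values.size and (values.min() < -1e-9 or values.max() > 1 + 1e-9):
            raise ValueError("HBP values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.values.size)


def bandpass_pulse(trace: PulseTrace, low_hz: float = CARDIAC_BAND[0],
                   high_hz: float = CARDIAC_BAND[1]) -> PulseTrace:
    """Zero-phase band-pass filter isolating the cardiac band.

    An order-4 Butterworth band-pass applied forward and backward
    (``sosfiltfilt``), so peak positions are not shifted in time.
    """
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= trace.fs / 2:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist rate {trace.fs / 2}")
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=trace.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return PulseTrace(filtered, trace.fs, trace.t0)


def resample_normalize(trace: PulseTrace, T: int, *, scale: bool = False) -> np.ndarray:
    """Linearly interpolate a trace onto ``T`` equally spaced points, zero-mean.

    With ``scale=True`` the result is additionally divided by its standard
    deviation (plain mean removal is the default).
    """
    if T < 2:
        raise ValueError(f"target length must be >= 2, got {T}")
    src_t = np.linspace(0.0, 1.0, trace.samples.size)
    dst_t = np.linspace(0.0, 1.0, T)
    out = np.interp(dst_t, src_t, trace.samples)
    out = out - out.mean()
    if scale:
        sd = out.std()
        if sd > 0:
            out = out / sd
    return out


def detect_peaks(signal: np.ndarray, fs: float, min_hr_bpm: float = 40.0,
                 max_hr_bpm: float = 180.0) -> PeakSequence:
    """Strict local maxima separated by at least ``fs * 60 / max_hr_bpm`` samples.

    Candidates are all strict local maxima; within an exclusion window the
    larger amplitude wins, ties go to the earlier index.  A monotone signal
    yields an empty sequence.  ``min_hr_bpm`` is not used for selection (one
    cannot force peaks to exist) but is kept for interface symmetry with the
    physiological band used elsewhere.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("signal must be 1-D with at least 3 samples")
    if not (0 < min_hr_bpm < max_hr_bpm):
        raise ValueError("need 0 < min_hr_bpm < max_hr_bpm")
    candidates, _ = sps.find_peaks(x)  # strict local maxima (plateau midpoints)
    min_dist = fs * 60.0 / max_hr_bpm
    # greedy selection: highest first, earlier index breaks ties
    order = sorted(range(candidates.size), key=lambda i: (-x[candidates[i]], candidates[i]))
    kept: list[int] = []
    for i in order:
        c = int(candidates[i])
        if all(abs(c - k) >= min_dist for k in kept):
            kept.append(c)
    return PeakSequence(np.sort(np.asarray(kept, dtype=int)), fs)


def psd_hr(trace: PulseTrace) -> float:
    """Spectral heart-rate estimate: 60 x argmax of in-band PSD power.

    Welch's averaged periodogram with segments of at least 10 s when the
    trace allows, otherwise a single periodogram over the whole trace.
    The search band is the cardiac band 0.7-3.0 Hz.
    """
    if trace.duration < 5.0:
        raise ValueError(
            f"trace of {trace.duration:.2f}s is too short for a PSD heart rate "
            "(need >= 5 s)")
    n = trace.samples.size
    seg = min(n, int(round(10.0 * trace.fs)))
    freqs, power = sps.welch(trace.samples, fs=trace.fs, nperseg=seg)
    lo, hi = CARDIAC_BAND
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        raise ValueError("no PSD frequency bin falls inside the cardiac band")
    band_freqs = freqs[in_band]
    band_power = power[in_band]
    return 60.0 * float(band_freqs[np.argmax(band_power)])


def filter_peaks_ibi(peaks: PeakSequence, rel_tol: float = 0.20) -> PeakSequence:
    """Discard peaks whose inter-beat interval deviates from the median.

    The median is computed once from the *original* intervals; any interval
    deviating by more than ``rel_tol`` (relative) removes the peak that
    terminates it.  Removal repeats against that fixed median until every
    surviving interval complies, so motion-artifact bursts cannot survive by
    merging with a neighbour.  Fewer than 3 peaks are returned unchanged with
    a warning.
    """
    if len(peaks) < 3:
        warnings.warn("fewer than 3 peaks: interval filtering skipped",
                      stacklevel=2)
        return peaks
    median = float(np.median(np.diff(peaks.indices)))
    idx = list(peaks.indices)
    changed = True
    while changed and len(idx) >= 2:
        changed = False
        for i in range(1, len(idx)):
            interval = idx[i] - idx[i - 1]
            if abs(interval - median) > rel_tol * median:
                del idx[i]
                changed = True
                break
    return PeakSequence(np.asarray(idx, dtype=int), peaks.fs)


@dataclass(frozen=True)
class PsdValidationReport:
    """Cross-check of interval-based HR against the spectral estimate."""

    passed: bool
    hr_peaks_bpm: float
    hr_psd_bpm: float
    rel_diff: float
    rel_tol: float


def validate_peaks_psd(peaks: PeakSequence, trace: PulseTrace,
                       rel_tol: float = 0.20) -> PsdValidationReport:
    """Flag a segment whose peak-derived HR disagrees with the PSD estimate.

    Disagreement beyond ``rel_tol`` (relative to the spectral estimate) marks
    the segment for exclusion from training labels; both rates are reported
    either way.
    """
    hr_peaks = peaks.mean_hr_bpm()
    hr_psd = psd_hr(trace)
    rel = abs(hr_peaks - hr_psd) / hr_psd
    return PsdValidationReport(bool(rel <= rel_tol), hr_peaks, hr_psd, rel, rel_tol)


def hbp_from_peaks(peaks: PeakSequence, T: int, fps: float | None = None) -> HbpMap:
    """Cosine-decay heartbeat-probability map from peak indices.

    For frame index ``x`` in ``[0, T)`` the probability is
    ``1/2 + 1/2 cos(theta)`` with the phase chosen per segment:

    * before the first peak ``P0``: period ``Dmax`` (largest inter-peak
      interval), phase ``2*pi/Dmax * (x + Dmax - P0)``;
    * between peaks: period equal to the local interval, phase measured from
      the preceding peak;
    * after the last peak ``PT``: period ``Dmax``, phase ``x - PT``.

    The map is exactly 1 at every peak and exactly 0 at the midpoint of any
    even inter-peak interval.
    """
    if len(peaks) < 2:
        raise ValueError("HBP construction requires >= 2 peaks (Dmax undefined)")
    idx = peaks.indices
    if idx[0] < 0 or idx[-1] >= T:
        raise ValueError(f"peak indices {idx[0]}..{idx[-1]} outside [0, {T})")
    d_max = peaks.d_max
    x = np.arange(T)
    theta = np.empty(T, dtype=float)

    p0, pt = int(idx[0]), int(idx[-1])
    pre = x < p0
    theta[pre] = 2 * np.pi / d_max * (x[pre] + d_max - p0)
    post = x > pt
    theta[post] = 2 * np.pi / d_max * (x[post] - pt)
    mid = ~pre & ~post
    # preceding peak for each mid-frame; local period from its interval
    seg = np.searchsorted(idx, x[mid], side="right") - 1
    seg = np.clip(seg, 0, len(idx) - 2)
    pb = idx[seg]
    pf = idx[seg + 1]
    theta[mid] = 2 * np.pi / (pf - pb) * (x[mid] - pb)

    values = 0.5 + 0.5 * np.cos(theta)
    # cosine is bounded; clip only guards against rounding at branch edges
    values = np.clip(values, 0.0, 1.0)
    values[idx] = 1.0
    return HbpMap(values, fps if fps is not None else peaks.fs)
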