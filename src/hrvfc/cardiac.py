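"""Cardiac metric time courses from ECG / RR-interval input.

This module turns a beat record into the five 1-s-resolution cardiac time
courses used by the downstream connectivity analysis: moving-average RR
interval, RMSSD, normalized LF-HRV and HF-HRV (percent of 0.04-0.50 Hz
successive-difference power), and instantaneous heart rate.

Conventions
-----------
* RR intervals are in milliseconds; ``rr[i] = 1000 * (t[i+1] - t[i])`` and is
  attributed to the time the interval completes, ``t[i+1]``.
* Windowed metrics are computed in 100-s windows centered on a 1-s grid;
  window positions whose full window does not fit inside the record are NaN.
* Within each window, RR outliers (more than 3 unscaled median absolute
  deviations from the window median) are linearly interpolated before any
  statistic is computed.
* Band powers come from a Welch PSD of the successive-difference series
  uniformly resampled at 10 Hz; bands are half-open ``[lo, hi)`` with LF
  [0.04, 0.15), HF [0.15, 0.40) and denominator [0.04, 0.50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "RRSeries",
    "CardiacMetricSeries",
    "bandpass_ecg",
    "detect_r_peaks",
    "instantaneous_hr",
    "interpolate_outliers",
    "rmssd",
    "normalized_band_power",
    "sliding_metrics",
    "orthogonalize",
]

#: spectral bands (Hz): half-open [lo, hi)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_BAND = (0.04, 0.50)
RESAMPLE_HZ = 10.0
WELCH_SEGMENT_S = 50.0  # Hann segments, 50% overlap


@dataclass
class RRSeries:
    """Beat times (s from scan start) and RR intervals (ms) for one scan.

    ``len(rr) == len(beat_times) - 1``; beat times strictly increasing.
    """

    beat_times: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.beat_times.ndim != 1 or self.rr.ndim != 1:
            raise ValueError("beat_times and rr must be 1-D")
        if len(self.rr) != len(self.beat_times) - 1:
            raise ValueError("need len(rr) == len(beat_times) - 1")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive")

    @classmethod
    def from_beat_times(cls, beat_times) -> "RRSeries":
        t = np.asarray(beat_times, dtype=float)
        return cls(t, 1000.0 * np.diff(t))

    @property
    def rr_times(self) -> np.ndarray:
        """Time each RR interval completes (the second beat of the pair)."""
        return self.beat_times[1:]

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass
class CardiacMetricSeries:
    """Cardiac metric time courses on a uniform 1-s grid.

    ``lf_hrv`` / ``hf_hrv`` are percentages of 0.04-0.50 Hz power; NaN marks
    grid points whose window did not fit in the record.
    """

    timestamps: np.ndarray
    mean_rr: np.ndarray
    rmssd: np.ndarray
    lf_hrv: np.ndarray
    hf_hrv: np.ndarray
    hr: np.ndarray
    window_length: float = 100.0
    orthogonalized: dict = field(default_factory=dict)

    def metric(self, name: str) -> np.ndarray:
        if name not in ("mean_rr", "rmssd", "lf_hrv", "hf_hrv", "hr"):
            raise KeyError(f"unknown cardiac metric {name!r}")
        return getattr(self, name)

    def orthogonalize_hrv(self) -> "CardiacMetricSeries":
        """Remove the mean-RR-explained component from the three HRV metrics.

        Returns a new series; ``orthogonalized`` flags which metrics were
        residualized against the moving-average RR course.
        """
        out = CardiacMetricSeries(
            self.timestamps.copy(), self.mean_rr.copy(), self.rmssd.copy(),
            self.lf_hrv.copy(), self.hf_hrv.copy(), self.hr.copy(),
            self.window_length, dict(self.orthogonalized),
        )
        for name in ("rmssd", "lf_hrv", "hf_hrv"):
            setattr(out, name, orthogonalize(out.metric(name), out.mean_rr))
            out.orthogonalized[name] = True
        return out


def bandpass_ecg(ecg, fs: float, low: float = 0.5, high: float = 40.0) -> np.ndarray:
    """Zero-phase 0.5-40 Hz band-pass (4th-order Butterworth, filtfilt)."""
    ecg = np.asarray(ecg, dtype=float)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, ecg)


def detect_r_peaks(ecg, fs: float, min_distance: float | None = None) -> RRSeries:
    """Detect R-waves in a band-passed single-channel ECG trace.

    Peaks are local maxima above an adaptive amplitude threshold (half the
    90th percentile of the rectified trace), separated by at least
    ``min_distance`` seconds. When ``min_distance`` is None it is set from a
    first pass at 0.5 s to 0.7x the estimated mean RR, clipped to [0.5, 0.9] --
    the spacing range appropriate for resting human heart rates.
    """
    ecg = np.asarray(ecg, dtype=float)
    if min_distance is not None and len(ecg) < 2 * min_distance * fs:
        raise ValueError("ECG trace shorter than two minimum peak distances")

    def _find(dist_s: float) -> np.ndarray:
        height = 0.5 * np.percentile(np.abs(ecg), 90)
        peaks, _ = signal.find_peaks(
            ecg, height=height, distance=max(1, int(round(dist_s * fs)))
        )
        return peaks

    if min_distance is None:
        first = _find(0.5)
        if len(first) < 2:
            raise ValueError("no R-peaks detected")
        mean_rr = np.mean(np.diff(first)) / fs
        min_distance = float(np.clip(0.7 * mean_rr, 0.5, 0.9))
        if len(ecg) < 2 * min_distance * fs:
            raise ValueError("ECG trace shorter than two minimum peak distances")
    peaks = _find(min_distance)
    if len(peaks) < 2:
        raise ValueError("no R-peaks detected")
    return RRSeries.from_beat_times(peaks / fs)


def instantaneous_hr(rr: RRSeries, timestamps: np.ndarray | None = None) -> np.ndarray:
    """Instantaneous heart rate, 60 / RR(s), at beat times then on a 1-s grid.

    With ``timestamps`` given, linearly interpolates the beat-wise rate onto
    that grid (edges clamp to the nearest beat's rate).
    """
    hr_beats = 60.0 / (rr.rr / 1000.0)
    if timestamps is None:
        return hr_beats
    return np.interp(np.asarray(timestamps, dtype=float), rr.rr_times, hr_beats)


def interpolate_outliers(values, n_mad: float = 3.0):
    """Replace values > ``n_mad`` unscaled MADs from the median by linear
    interpolation between the nearest non-outlier neighbours.

    Boundary outliers take the nearest valid value. Returns ``(cleaned,
    outlier_mask)``; raises if every value is an outlier (degenerate window).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        return x.copy(), np.zeros(len(x), dtype=bool)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    out = np.abs(x - med) > n_mad * mad
    if not out.any():
        return x.copy(), out
    if out.all():
        raise ValueError("all values flagged as outliers; window invalid")
    good = np.flatnonzero(~out)
    cleaned = x.copy()
    cleaned[out] = np.interp(np.flatnonzero(out), good, x[good])
    return cleaned, out


def rmssd(rr_values) -> float:
    """Root mean square of successive RR differences (ms); NaN for < 2 beats."""
    x = np.asarray(rr_values, dtype=float)
    if len(x) < 2:
        return float("nan")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def _resample_diffs(diff_times, diffs, t0, t1, fs=RESAMPLE_HZ):
    """Successive differences linearly interpolated onto a uniform grid."""
    grid = t0 + np.arange(int(round((t1 - t0) * fs))) / fs
    return np.interp(grid, diff_times, diffs)


def _welch_bands(x2d: np.ndarray, fs: float = RESAMPLE_HZ):
    """Normalized LF/HF percentages for rows of ``x2d`` (each a resampled,
    not-yet-demeaned successive-difference window)."""
    x2d = x2d - x2d.mean(axis=-1, keepdims=True)
    nperseg = min(x2d.shape[-1], int(WELCH_SEGMENT_S * fs))
    freqs, psd = signal.welch(
        x2d, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    lf_sel = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_sel = (freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])
    tot_sel = (freqs >= TOTAL_BAND[0]) & (freqs < TOTAL_BAND[1])
    tot = psd[..., tot_sel].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lf = 100.0 * psd[..., lf_sel].sum(axis=-1) / tot
        hf = 100.0 * psd[..., hf_sel].sum(axis=-1) / tot
    bad = tot <= 0
    if np.ndim(lf):
        lf[bad] = np.nan
        hf[bad] = np.nan
    elif bad:
        lf = hf = float("nan")
    return lf, hf


def normalized_band_power(rr: RRSeries | np.ndarray, rr_times=None):
    """Normalized LF and HF successive-difference power for one window.

    Accepts an :class:`RRSeries` or a pair ``(rr_ms_values, rr_times)``.
    The successive-difference series is placed at the completing beat of each
    difference, linearly resampled at 10 Hz over the window span, de-meaned,
    and fed to a Welch PSD (50-s Hann segments, 50% overlap). Returns
    ``(lf_pct, hf_pct)``; NaN when total 0.04-0.50 Hz power vanishes.
    """
    if isinstance(rr, RRSeries):
        values, times = rr.rr, rr.rr_times
    else:
        values = np.asarray(rr, dtype=float)
        if rr_times is None:
            raise ValueError("rr_times required when passing raw RR values")
        times = np.asarray(rr_times, dtype=float)
    if len(values) < 3:
        return float("nan"), float("nan")
    diffs = np.diff(values)
    diff_times = times[1:]
    x = _resample_diffs(diff_times, diffs, times[0], times[-1])
    if len(x) < 2:
        return float("nan"), float("nan")
    lf, hf = _welch_bands(x[None, :])
    return float(lf[0]), float(hf[0])


def sliding_metrics(
    rr: RRSeries,
    window: float = 100.0,
    step: float = 1.0,
    timestamps: np.ndarray | None = None,
) -> CardiacMetricSeries:
    """Windowed cardiac metrics on a uniform grid.

    For each grid time ``t`` the statistics use the RR intervals completing in
    the centered window ``[t - window/2, t + window/2)``; 3-MAD outlier
    interpolation is applied to each window's RR values first.  Grid points
    whose window extends past either end of the record are NaN.  ``timestamps``
    overrides the default ``step``-spaced grid (used to evaluate metrics
    directly at fMRI volume times).
    """
    t0, t1 = rr.beat_times[0], rr.beat_times[-1]
    if t1 - t0 < window:
        raise ValueError("record shorter than one analysis window")
    if timestamps is None:
        grid = np.arange(np.ceil(t0), np.floor(t1) + 0.5 * step, step)
    else:
        grid = np.asarray(timestamps, dtype=float)
    half = window / 2.0
    valid = (grid - half >= t0 - 1e-9) & (grid + half <= t1 + 1e-9)

    rt = rr.rr_times
    lo_idx = np.searchsorted(rt, grid - half, side="left")
    hi_idx = np.searchsorted(rt, grid + half, side="left")

    n = len(grid)
    mean_rr = np.full(n, np.nan)
    rmssd_ts = np.full(n, np.nan)
    fs = RESAMPLE_HZ
    n_samp = int(round(window * fs))
    resampled = np.zeros((n, n_samp))
    has_psd = np.zeros(n, dtype=bool)

    for i in range(n):
        if not valid[i]:
            continue
        sl = slice(lo_idx[i], hi_idx[i])
        vals = rr.rr[sl]
        times = rt[sl]
        if len(vals) < 3:
            continue
        try:
            cleaned, _ = interpolate_outliers(vals)
        except ValueError:
            continue
        mean_rr[i] = cleaned.mean()
        rmssd_ts[i] = rmssd(cleaned)
        diffs = np.diff(cleaned)
        wgrid = (grid[i] - half) + np.arange(n_samp) / fs
        resampled[i] = np.interp(wgrid, times[1:], diffs)
        has_psd[i] = True

    lf = np.full(n, np.nan)
    hf = np.full(n, np.nan)
    if has_psd.any():
        lf_v, hf_v = _welch_bands(resampled[has_psd])
        lf[has_psd] = lf_v
        hf[has_psd] = hf_v

    hr = instantaneous_hr(rr, grid)
    hr[~valid] = np.nan
    return CardiacMetricSeries(grid, mean_rr, rmssd_ts, lf, hf, hr, window)


def orthogonalize(metric, reference) -> np.ndarray:
    """Residualize ``metric`` against ``[intercept, reference]`` by least
    squares, preserving NaN positions.

    The residual is exactly uncorrelated with the reference.  A constant
    reference degenerates to de-meaning (with a warning).
    """
    y = np.asarray(metric, dtype=float).copy()
    x = np.asarray(reference, dtype=float)
    if y.shape != x.shape:
        raise ValueError("metric and reference must have equal length")
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        return y
    xs = x[ok]
    if np.ptp(xs) == 0:
        warnings.warn("constant reference; returning de-meaned metric")
        y[ok] = y[ok] - y[ok].mean()
        return y
    design = np.column_stack([np.ones(ok.sum()), xs])
    beta, *_ = np.linalg.lstsq(design, y[ok], rcond=None)
    y[ok] = y[ok] - design @ beta
    return y
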