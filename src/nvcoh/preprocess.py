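"""Preprocessing: segment extraction, polynomial detrending, zero-phase
bandpass filtering and moving-average downsampling.

The default pipeline mirrors standard practice for slow-oscillation
analysis: cut a continuous 20-min segment, subtract a best-fit third-order
polynomial to remove drifts slower than the lowest analysed frequency,
bandpass 0.007-4 Hz (4-48 Hz for fast EEG rhythms), then reduce the
sampling rate with a moving average so downstream transforms stay cheap.
All filtering is zero-phase: phase fidelity is what the coherence analysis
lives on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import ChannelSeries, Recording, ValidationError

#: per-analysis target sampling rates (Hz)
TARGET_FS = {
    "fnirs_eeg": 31.25,     # EEG matched to the native fNIRS rate
    "eeg_eeg_low": 20.0,    # EEG-EEG coherence below 4 Hz
    "fnirs_low": 20.0,      # fNIRS vs rate/respiration series
    "eeg_high": 142.0,      # EEG rhythms above delta
    "rate_extract": 100.0,  # ECG/respiration prior to ridge rate extraction
}


@dataclass
class PreprocessConfig:
    detrend_order: int = 3
    band_lo: float = 0.007
    band_hi: float = 4.0
    target_fs: float | None = None
    segment_start: float = 0.0
    segment_length: float = 1200.0

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ValidationError("need 0 < band_lo < band_hi")
        if self.segment_length <= 0:
            raise ValidationError("segment_length must be positive")


def extract_segment(rec: Recording, start: float, length: float) -> Recording:
    """Cut all channels to the window [start, start+length) seconds."""
    i0 = int(round(start * rec.fs))
    i1 = i0 + int(round(length * rec.fs))
    if start < 0 or i1 > rec.n_samples:
        raise ValidationError(
            f"window [{start}, {start + length}) s exceeds recording duration "
            f"{rec.duration:.1f} s"
        )
    channels = [
        ChannelSeries(ch.label, ch.samples[i0:i1], ch.modality, ch.units)
        for ch in rec.channels
    ]
    return Recording(channels, rec.fs, rec.subject_id, rec.group_label, t0=rec.t0 + start)


def detrend_poly(x: np.ndarray, fs: float, order: int = 3) -> np.ndarray:
    """Subtract the least-squares polynomial fit of the given order."""
    x = np.asarray(x, dtype=float)
    if x.size <= order + 1:
        raise ValidationError(f"series of length {x.size} too short for order {order}")
    # fit on a [-1, 1] time axis for conditioning
    t = np.linspace(-1.0, 1.0, x.size)
    coef = np.polynomial.polynomial.polyfit(t, x, order)
    return x - np.polynomial.polynomial.polyval(t, coef)


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase Butterworth bandpass (2nd-order sections, forward-backward).

    Reflect-padding by one settling length keeps edge transients out of the
    lowest frequencies.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    if not 0 < lo < hi:
        raise ValidationError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValidationError(f"high edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # settling length ~ 3 periods of the low edge, capped at the record length
    pad = min(x.size - 1, int(3 * fs / lo))
    return sps.sosfiltfilt(sos, x, padtype="even", padlen=pad)


def downsample_moving_average(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Moving-average smoothing followed by resampling to a uniform grid.

    The smoothing window is round(fs_in/fs_out) samples; the smoothed series
    is then linearly interpolated onto the exact fs_out time grid, which also
    handles non-integer rate ratios (e.g. 1000 -> 142 Hz). Output length is
    floor(n * fs_out / fs_in).
    """
    x = np.asarray(x, dtype=float)
    if fs_out > fs_in:
        raise ValidationError(f"fs_out {fs_out} > fs_in {fs_in}")
    if fs_out == fs_in:
        return x.copy()
    win = max(1, int(round(fs_in / fs_out)))
    kernel = np.ones(win) / win
    # centered moving average with edge-value padding
    xp = np.concatenate([np.full(win // 2, x[0]), x, np.full(win - 1 - win // 2, x[-1])])
    smooth = np.convolve(xp, kernel, mode="valid")
    n_out = int(np.floor(x.size * fs_out / fs_in))
    t_in = np.arange(x.size) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, smooth)


def preprocess_channel(
    x: np.ndarray, fs: float, config: PreprocessConfig
) -> tuple[np.ndarray, float]:
    """detrend -> bandpass -> downsample; returns (series, new fs)."""
    y = detrend_poly(x, fs, config.detrend_order)
    y = bandpass(y, fs, config.band_lo, config.band_hi)
    fs_out = fs
    if config.target_fs is not None and config.target_fs < fs:
        y = downsample_moving_average(y, fs, config.target_fs)
        fs_out = config.target_fs
    return y, fs_out


def preprocess_recording(rec: Recording, config: PreprocessConfig) -> Recording:
    """Apply segment extraction and per-channel preprocessing to a recording."""
    length = min(config.segment_length, rec.duration - config.segment_start)
    seg = extract_segment(rec, config.segment_start, length)
    out = []
    fs_out = seg.fs
    for ch in seg.channels:
        y, fs_out = preprocess_channel(ch.samples, seg.fs, config)
        out.append(ChannelSeries(ch.label, y, ch.modality, ch.units))
    return Recording(out, fs_out, seg.subject_id, seg.group_label, t0=seg.t0)
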