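"""Ridge extraction: instantaneous frequency, amplitude and phase of one
oscillatory mode, and ridge-based rate series (IHR/IRR).

A ridge is the path through the time-frequency plane that follows the
dominant in-band spectral amplitude while staying physiologically smooth.
We find the path maximizing

    sum_t [ ln|W(nu_t, t)| - lambda * (Delta ln nu_t)^2 ]

by dynamic programming over the grid frequencies restricted to the band.
The quadratic log-frequency jump penalty encodes a prior on how fast the
mode's frequency can slew; the default allows roughly 0.3 octave/s, ample
for beat-to-beat heart-rate variation.

The ridge frequency of an ECG (or respiration effort) wavelet transform is
itself a rate series sampled at the input rate -- no beat detection or
interpolation is involved, which is what makes the instantaneous heart
rate (IHR) directly usable in further spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import ValidationError
from .timefreq import TimeFrequencyRepresentation, make_log_grid, wavelet_transform

#: heart-rate extraction band (Hz); the fallback for fast hearts is 0.8-3
CARDIAC_BAND = (0.6, 2.0)
CARDIAC_BAND_FAST = (0.8, 3.0)
RESPIRATORY_BAND = (0.145, 0.6)


@dataclass
class RidgeCurve:
    """One extracted mode: per-sample frequency, amplitude, unwrapped phase."""

    freq: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    band: tuple[float, float]
    fs: float

    @property
    def n_samples(self) -> int:
        return self.freq.size


@dataclass
class RateSeries:
    """Instantaneous rate (Hz per time point) derived from a ridge."""

    samples: np.ndarray
    fs: float
    source: str  # ECG | RESP

    @property
    def n_samples(self) -> int:
        return self.samples.size


def default_jump_penalty(grid_step_ln: float, slew_octaves_per_s: float = 0.3) -> float:
    """Penalty weight for which the allowed frequency slew matches
    ``slew_octaves_per_s``.

    On a discrete grid the path moves in whole grid steps, so a slew of s
    octaves/s costs lambda*step^2 per jump at s*ln2/step jumps per second;
    lambda = 1/(s*ln2*step) makes that one penalty unit per second,
    comparable to the log-amplitude gain of staying on a ridge.
    """
    return 1.0 / (slew_octaves_per_s * np.log(2.0) * grid_step_ln)


def extract_ridge(
    tfr: TimeFrequencyRepresentation,
    lo: float,
    hi: float,
    jump_penalty: float | None = None,
) -> RidgeCurve:
    """Dynamic-programming ridge through [lo, hi) of a wavelet transform."""
    idx = tfr.grid.band_indices(lo, hi)
    if idx.size == 0:
        raise ValidationError(f"band [{lo}, {hi}) is outside the grid")
    if jump_penalty is None:
        steps = np.diff(np.log(tfr.grid.values[idx]))
        lam = default_jump_penalty(float(np.median(steps))) if steps.size else 0.0
    else:
        lam = jump_penalty

    W = tfr.coefficients[:, idx]
    amp = np.abs(W)
    # floor relative to the global peak so silent samples don't dominate
    floor = amp.max() * 1e-12 + np.finfo(float).tiny
    logamp = np.log(np.maximum(amp, floor))
    lnnu = np.log(tfr.grid.values[idx])
    K = idx.size
    T = tfr.n_times
    d2 = lam * (lnnu[None, :] - lnnu[:, None]) ** 2  # penalty[prev, new]

    back = np.empty((T, K), dtype=np.int32)
    score = logamp[0].copy()
    back[0] = np.arange(K)
    for t in range(1, T):
        # candidate[prev, new] = score[prev] - penalty[prev, new]
        cand = score[:, None] - d2
        best_prev = np.argmax(cand, axis=0)
        score = cand[best_prev, np.arange(K)] + logamp[t]
        back[t] = best_prev

    path = np.empty(T, dtype=np.int32)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]

    sel = idx[path]
    rows = np.arange(T)
    freq = tfr.grid.values[sel]
    amplitude = np.abs(tfr.coefficients[rows, sel])
    phase = np.unwrap(np.angle(tfr.coefficients[rows, sel]))

    # COI-invalid endpoints carry edge-effect phase/frequency; replace the
    # frequency there with the nearest valid ridge value for continuity
    valid = tfr.coi_mask[rows, sel]
    if valid.any() and not valid.all():
        good = np.nonzero(valid)[0]
        freq = freq.copy()
        freq[: good[0]] = freq[good[0]]
        freq[good[-1] + 1:] = freq[good[-1]]
    return RidgeCurve(freq, amplitude, phase, (lo, hi), tfr.fs)


def instantaneous_rate(
    x: np.ndarray,
    fs: float,
    lo: float = CARDIAC_BAND[0],
    hi: float = CARDIAC_BAND[1],
    source: str = "ECG",
    resolution: float = 2.0,
    n_freq_per_octave: int = 24,
    jump_penalty: float | None = None,
) -> RateSeries:
    """Ridge-frequency rate series from an ECG or respiration signal.

    The band of interest is first isolated with a zero-phase bandpass
    (which strips the pulse train's harmonics), then wavelet transformed
    (lognormal mother wavelet, resolution 2) on a log grid spanning the
    band with half an octave of margin. The rate is the derivative of the
    unwrapped ridge phase, smoothed by a zero-phase lowpass at half the
    mean rate: sub-beat phase ripple is removed while respiratory-scale
    rate modulation passes. Output length equals input length and shares
    its sampling rate; samples are confined to [lo, hi].
    """
    from scipy import signal as sps

    from .preprocess import bandpass

    x = np.asarray(x, dtype=float)
    if not 0 < lo < hi:
        raise ValidationError("empty rate band")
    gmin = lo / np.sqrt(2.0)
    gmax = min(hi * np.sqrt(2.0), 0.49 * fs)
    if gmax <= gmin:
        raise ValidationError(f"band [{lo}, {hi}) too close to Nyquist at fs={fs}")
    xb = bandpass(x, fs, lo, min(hi, 0.49 * fs * 0.999))
    n_freq = max(8, int(np.ceil(np.log2(gmax / gmin) * n_freq_per_octave)))
    grid = make_log_grid(gmin, gmax, n_freq)
    tfr = wavelet_transform(xb, fs, grid, wavelet="lognormal", resolution=resolution)
    ridge = extract_ridge(tfr, lo, hi, jump_penalty=jump_penalty)
    rate = np.gradient(ridge.phase) * fs / (2.0 * np.pi)
    cut = 0.5 * float(np.median(ridge.freq))
    if 0 < cut < 0.49 * fs:
        sos = sps.butter(2, cut, btype="lowpass", fs=fs, output="sos")
        rate = sps.sosfiltfilt(sos, rate - rate.mean()) + rate.mean()
    return RateSeries(np.clip(rate, lo, hi), fs, source)


def reconstruct_mode(ridge: RidgeCurve) -> np.ndarray:
    """Time-domain reconstruction amplitude(t) * cos(phase(t)).

    With the unit-tone amplitude calibration of the transforms the
    reconstruction gain is 1.
    """
    return ridge.amplitude * np.cos(ridge.phase)


def remove_cardiac(
    eeg: np.ndarray,
    fs: float,
    lo: float = CARDIAC_BAND[0],
    hi: float = CARDIAC_BAND[1],
    resolution: float = 2.0,
    n_freq_per_octave: int = 24,
) -> np.ndarray:
    """Subtract the dominant cardiac-band mode from an EEG channel.

    A single-mode ridge reconstruction of the electrical heart-beat
    signature is removed; when no cardiac component rises above the noise
    floor (ridge amplitude below the band's median level), the input is
    returned unchanged.
    """
    x = np.asarray(eeg, dtype=float)
    gmin = lo / np.sqrt(2.0)
    gmax = min(hi * np.sqrt(2.0), 0.49 * fs)
    n_freq = max(8, int(np.ceil(np.log2(gmax / gmin) * n_freq_per_octave)))
    grid = make_log_grid(gmin, gmax, n_freq)
    tfr = wavelet_transform(x, fs, grid, wavelet="lognormal", resolution=resolution)

    # spectral-peak gate: the band's time-averaged power, whitened by the
    # analysis bandwidth (proportional to nu, so flat noise flattens to a
    # constant), must show a clear peak before anything is subtracted
    from .timefreq import time_averaged_power

    idx = tfr.grid.band_indices(lo, hi)
    whitened = time_averaged_power(tfr).power[idx] / tfr.grid.values[idx]
    whitened = whitened[np.isfinite(whitened)]
    if whitened.size == 0 or whitened.max() < 1.2 * np.median(whitened):
        return x.copy()
    ridge = extract_ridge(tfr, lo, hi)
    from .preprocess import bandpass

    # confine the subtraction to the cardiac band so out-of-band content
    # is untouched
    recon = bandpass(reconstruct_mode(ridge), fs, lo, min(hi, 0.49 * fs * 0.999))
    return x - recon
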