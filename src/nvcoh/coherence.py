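"""Wavelet phase coherence (WPC), surrogate significance thresholds and
phase-difference statistics.

At each analysis frequency the WPC is the magnitude of the time-averaged
unit phasor of the phase difference between two transforms,

    WPC(nu) = | < exp(i [phi_1(nu,t) - phi_2(nu,t)]) >_t |,

so 1 means a perfectly constant phase difference and values near 0 mean no
phase relation. The measure is independent of amplitude by construction.

Finite records produce non-zero apparent coherence even between unrelated
signals, growing towards low frequencies where fewer oscillation cycles
fit in the record. Inter-subject surrogates quantify that bias: coherence
computed between channels of *different* subjects, where no physical link
exists, and its 95th percentile across surrogate pairings serves as a
per-frequency significance threshold. "Effective coherence" is raw
coherence minus this threshold, kept signed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .signal_io import ValidationError
from .timefreq import FrequencyGrid, TimeFrequencyRepresentation


@dataclass
class CoherenceSpectrum:
    """Per-frequency coherence between two signals."""

    grid: FrequencyGrid
    raw: np.ndarray
    phase_diff: np.ndarray
    n_valid: np.ndarray
    threshold: np.ndarray | None = None
    effective: np.ndarray | None = None

    def band_mean(self, lo: float, hi: float, which: str = "raw") -> float:
        """Unweighted mean of a component over grid frequencies in [lo, hi)."""
        idx = self.grid.band_indices(lo, hi)
        if idx.size == 0:
            raise ValidationError(f"band [{lo}, {hi}) contains no grid frequencies")
        values = getattr(self, which)
        if values is None:
            raise ValueError(f"{which} not computed")
        return float(np.nanmean(values[idx]))


@dataclass
class SurrogateEnsemble:
    """Coherence values from inter-subject surrogate pairings."""

    values: np.ndarray          # (n_surrogates, n_freq)
    grid: FrequencyGrid
    pairing_scheme: str
    seed: int | None

    @property
    def n_surrogates(self) -> int:
        return self.values.shape[0]

    def percentile(self, q: float = 95.0) -> np.ndarray:
        """Nearest-rank percentile per frequency."""
        return nearest_rank_percentile(self.values, q, axis=0)


def nearest_rank_percentile(values: np.ndarray, q: float, axis: int = 0) -> np.ndarray:
    """Nearest-rank percentile: the ceil(q/100 * n)-th order statistic."""
    values = np.asarray(values)
    n = values.shape[axis]
    rank = max(1, int(np.ceil(q / 100.0 * n)))  # 1-based
    return np.take(np.sort(values, axis=axis), rank - 1, axis=axis)


def _check_compatible(tfr1: TimeFrequencyRepresentation, tfr2: TimeFrequencyRepresentation):
    if tfr1.grid.n != tfr2.grid.n or not np.allclose(tfr1.grid.values, tfr2.grid.values):
        raise ValueError("transforms have different frequency grids")
    if tfr1.fs != tfr2.fs or tfr1.n_times != tfr2.n_times:
        raise ValueError("transforms have different time axes")


def _unit_phasors(tfr: TimeFrequencyRepresentation) -> np.ndarray:
    # cached on the transform: surrogate ensembles revisit the same TFRs
    cached = getattr(tfr, "_unit_phasors_cache", None)
    if cached is not None:
        return cached
    w = tfr.coefficients
    mag = np.abs(w)
    z = np.zeros_like(w)
    np.divide(w, mag, out=z, where=mag > 0)
    tfr._unit_phasors_cache = z
    return z


def wavelet_phase_coherence(
    tfr1: TimeFrequencyRepresentation, tfr2: TimeFrequencyRepresentation
) -> CoherenceSpectrum:
    """Phase coherence per frequency over samples COI-valid in both inputs.

    The phase-difference convention is phi(first) - phi(second): a positive
    circular-mean phase difference means the first signal leads.
    """
    _check_compatible(tfr1, tfr2)
    z = _unit_phasors(tfr1) * np.conj(_unit_phasors(tfr2))
    valid = tfr1.coi_mask & tfr2.coi_mask
    n_valid = valid.sum(axis=0)
    z[~valid] = 0.0
    zsum = z.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_phasor = np.where(n_valid > 0, zsum / np.maximum(n_valid, 1), np.nan)
    raw = np.abs(mean_phasor)
    phase_diff = np.angle(mean_phasor)
    return CoherenceSpectrum(tfr1.grid, raw, phase_diff, n_valid)


def time_localized_wpc(
    tfr1: TimeFrequencyRepresentation,
    tfr2: TimeFrequencyRepresentation,
    window_cycles: float = 10.0,
) -> np.ndarray:
    """Sliding-window coherence map (time x frequency).

    At each frequency nu the window spans window_cycles/nu seconds. Entries
    where the window does not fit in the record, or overlaps COI-invalid
    samples, are NaN.
    """
    _check_compatible(tfr1, tfr2)
    z = _unit_phasors(tfr1) * np.conj(_unit_phasors(tfr2))
    valid = tfr1.coi_mask & tfr2.coi_mask
    T, K = z.shape
    out = np.full((T, K), np.nan)
    for k in range(K):
        w = int(round(window_cycles / tfr1.grid.values[k] * tfr1.fs))
        if w < 2 or w > T:
            continue  # frequency flagged missing: window does not fit
        kern = np.ones(w)
        zsum = np.convolve(z[:, k], kern, mode="same")
        ok = np.convolve(valid[:, k].astype(float), kern, mode="same")
        col = np.abs(zsum) / w
        col[ok < w - 0.5] = np.nan  # window touches invalid samples
        out[:, k] = col
    return out


def surrogate_threshold(
    channel_a_tfrs: Sequence[TimeFrequencyRepresentation],
    channel_b_tfrs: Sequence[TimeFrequencyRepresentation],
    n_surrogates: int = 176,
    percentile: float = 95.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, SurrogateEnsemble]:
    """Inter-subject surrogate coherence threshold.

    Parameters
    ----------
    channel_a_tfrs, channel_b_tfrs : sequences of transforms, one per
        subject, identically preprocessed (same grid, fs and length).
    n_surrogates : number of random ordered cross-subject pairings (i, j),
        i != j, drawn without repetition. Default 176.
    percentile : nearest-rank percentile defining the threshold (default
        95).

    Returns (threshold per frequency, surrogate ensemble).
    """
    n_sub = len(channel_a_tfrs)
    if n_sub != len(channel_b_tfrs):
        raise ValidationError("channel_a and channel_b cohorts differ in size")
    if n_sub < 2:
        raise ValidationError("need at least 2 subjects for inter-subject surrogates")
    if n_surrogates < 19:
        raise ValidationError("need >= 19 surrogates for a 95th percentile")
    n_pairs = n_sub * (n_sub - 1)
    if n_surrogates > n_pairs:
        raise ValidationError(
            f"{n_surrogates} surrogates requested but only {n_pairs} ordered "
            f"cross-subject pairs exist for {n_sub} subjects"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(n_pairs, size=n_surrogates, replace=False)
    values = np.empty((n_surrogates, channel_a_tfrs[0].grid.n))
    for row, flat in enumerate(np.asarray(chosen)):
        i, rem = divmod(int(flat), n_sub - 1)
        j = rem if rem < i else rem + 1
        spec = wavelet_phase_coherence(channel_a_tfrs[i], channel_b_tfrs[j])
        values[row] = spec.raw
    ens = SurrogateEnsemble(
        values,
        channel_a_tfrs[0].grid,
        pairing_scheme=f"uniform ordered cross-subject pairs, n_sub={n_sub}",
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )
    return ens.percentile(percentile), ens


def surrogate_threshold_from_recordings(
    cohort,
    channel_a: str,
    channel_b: str,
    n_surrogates: int = 176,
    percentile: float = 95.0,
    seed: int | np.random.Generator | None = None,
    grid: FrequencyGrid | None = None,
    wavelet: str = "morlet",
    resolution: float = 1.0,
    preprocess: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> tuple[np.ndarray, SurrogateEnsemble]:
    """Surrogate threshold from a cohort of Recordings.

    Each subject's ``channel_a`` and ``channel_b`` series are (optionally)
    preprocessed, truncated to the cohort's common length and transformed
    identically; thresholds come from `surrogate_threshold` on the cached
    transforms.
    """
    from .timefreq import default_grid, wavelet_transform

    if len(cohort) < 2:
        raise ValidationError("need at least 2 subjects for inter-subject surrogates")
    fs = cohort[0].fs
    if any(rec.fs != fs for rec in cohort):
        raise ValidationError("cohort recordings must share a sampling rate")
    grid = grid or default_grid()

    def prep(rec, label):
        x = rec.channel(label).samples
        return preprocess(x, fs) if preprocess is not None else x

    series_a = [prep(rec, channel_a) for rec in cohort]
    series_b = [prep(rec, channel_b) for rec in cohort]
    n_common = min(min(len(x) for x in series_a), min(len(x) for x in series_b))
    tfrs_a = [
        wavelet_transform(x[:n_common], fs, grid, wavelet, resolution) for x in series_a
    ]
    tfrs_b = [
        wavelet_transform(x[:n_common], fs, grid, wavelet, resolution) for x in series_b
    ]
    return surrogate_threshold(tfrs_a, tfrs_b, n_surrogates, percentile, seed)


def effective_coherence(
    spec: CoherenceSpectrum, threshold: np.ndarray
) -> CoherenceSpectrum:
    """Attach a surrogate threshold: effective = raw - threshold (signed)."""
    threshold = np.asarray(threshold, dtype=float)
    if threshold.shape != (spec.grid.n,):
        raise ValueError(
            f"threshold length {threshold.size} does not match grid size {spec.grid.n}"
        )
    return CoherenceSpectrum(
        spec.grid,
        spec.raw,
        spec.phase_diff,
        spec.n_valid,
        threshold=threshold,
        effective=spec.raw - threshold,
    )


def band_phase_difference(spec: CoherenceSpectrum, lo: float, hi: float) -> float:
    """Circular mean of per-frequency phase differences over [lo, hi).

    Positive values mean the first signal of the coherence computation
    leads the second.
    """
    idx = spec.grid.band_indices(lo, hi)
    if idx.size == 0:
        raise ValidationError(f"band [{lo}, {hi}) contains no grid frequencies")
    ph = spec.phase_diff[idx]
    ph = ph[np.isfinite(ph)]
    if ph.size == 0:
        return np.nan
    return float(np.angle(np.mean(np.exp(1j * ph))))
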