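"""Canonical physiological frequency bands and band averaging.

Six cardiovascular bands tile 0.007-2 Hz: two endothelial bands (NO-independent
and NO-dependent), neurogenic, myogenic, respiratory and cardiac. EEG rhythms
cover delta through gamma up to 48 Hz, with the beta/gamma split available in
both the 22 Hz and 30 Hz conventions. Band intervals are half-open [lo, hi) so
every frequency belongs to exactly one band of its family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import ValidationError
from .timefreq import FrequencyGrid


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    lo: float  # inclusive
    hi: float  # exclusive

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"band {self.name}: lo must be < hi")

    def __contains__(self, freq: float) -> bool:
        return self.lo <= freq < self.hi


def cardiovascular_bands() -> list[FrequencyBand]:
    """The six cardiovascular oscillation bands, 0.007-2 Hz."""
    return [
        FrequencyBand("endothelial_V1", 0.007, 0.0095),   # NO-independent
        FrequencyBand("endothelial_V", 0.0095, 0.021),    # NO-dependent
        FrequencyBand("neurogenic", 0.021, 0.052),
        FrequencyBand("myogenic", 0.052, 0.145),
        FrequencyBand("respiratory", 0.145, 0.6),
        FrequencyBand("cardiac", 0.6, 2.0),
    ]


def eeg_bands(beta_hi: float = 22.0) -> list[FrequencyBand]:
    """EEG rhythm bands delta..gamma; ``beta_hi`` picks the beta/gamma split
    convention (22 or 30 Hz)."""
    if beta_hi not in (22.0, 30.0):
        raise ValidationError(f"beta_hi must be 22 or 30 Hz, got {beta_hi}")
    return [
        FrequencyBand("delta", 0.5, 4.0),
        FrequencyBand("theta", 4.0, 7.5),
        FrequencyBand("alpha", 7.5, 14.0),
        FrequencyBand("beta", 14.0, beta_hi),
        FrequencyBand("gamma", beta_hi, 48.0),
    ]


def slow_ultraslow_band() -> FrequencyBand:
    """Slow/ultraslow EEG oscillations, kept separate as it overlaps delta."""
    return FrequencyBand("slow_ultraslow", 0.025, 1.5)


def band_by_name(name: str, beta_hi: float = 22.0) -> FrequencyBand:
    for b in cardiovascular_bands() + eeg_bands(beta_hi) + [slow_ultraslow_band()]:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


def band_average(grid: FrequencyGrid, values: np.ndarray, band: FrequencyBand) -> float:
    """Unweighted arithmetic mean of ``values`` over grid frequencies in the
    band. On a log grid this is a log-uniform frequency weighting."""
    idx = grid.band_indices(band.lo, band.hi)
    if idx.size == 0:
        raise ValidationError(f"band {band.name} contains no grid frequencies")
    return float(np.nanmean(np.asarray(values, dtype=float)[idx]))


@dataclass
class BandSummaryTable:
    """Subject x channel-pair matrix of band-averaged scalars.

    ``values`` is a DataFrame indexed by subject id with one column per
    pair label; missing entries are NaN (flagged, never imputed).
    """

    band: FrequencyBand
    values: pd.DataFrame
    metric: str  # "coherence" | "power"

    def __post_init__(self) -> None:
        if self.metric not in ("coherence", "power"):
            raise ValidationError(f"unknown metric {self.metric!r}")

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def pairs(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="subject")


def build_summary_table(
    cohort_spectra: dict[str, dict[str, tuple[FrequencyGrid, np.ndarray]]],
    band: FrequencyBand,
    metric: str,
) -> BandSummaryTable:
    """Band-average per-subject, per-pair spectra into a summary matrix.

    ``cohort_spectra`` maps subject id -> {pair label -> (grid, values)}.
    All present spectra must share one grid; a subject missing a pair gets
    NaN in that cell.
    """
    subjects = list(cohort_spectra)
    pair_set: list[str] = []
    for spectra in cohort_spectra.values():
        for pair in spectra:
            if pair not in pair_set:
                pair_set.append(pair)
    ref_grid: FrequencyGrid | None = None
    mat = np.full((len(subjects), len(pair_set)), np.nan)
    for i, sub in enumerate(subjects):
        for j, pair in enumerate(pair_set):
            if pair not in cohort_spectra[sub]:
                continue
            grid, values = cohort_spectra[sub][pair]
            if ref_grid is None:
                ref_grid = grid
            elif grid.n != ref_grid.n or not np.allclose(grid.values, ref_grid.values):
                raise ValueError(f"subject {sub} pair {pair}: inconsistent grid")
            mat[i, j] = band_average(grid, values, band)
    df = pd.DataFrame(mat, index=subjects, columns=pair_set)
    return BandSummaryTable(band, df, metric)
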