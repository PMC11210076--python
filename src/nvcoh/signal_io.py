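"""Reading, writing and validating multichannel physiological recordings.

Recordings hold uniformly sampled channels of mixed modality (EEG, fNIRS
oxygenated-haemoglobin, ECG, respiration effort, derived rate series).
Two on-disk formats are supported: EDF/EDF+ (read through MNE, written by a
minimal 16-bit writer) and a tab-separated text dialect with a ``#fs=<Hz>``
metadata line followed by a header row of channel labels.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

GROUP_LABELS = {"P", "S", "PC", "SC", "CS", "SYNTH"}
MODALITIES = {"EEG", "FNIRS", "ECG", "RESP", "RATE"}

#: 16-channel EEG montage used for scalp recordings (10-20 positions).
DEFAULT_EEG_LABELS = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8", "T7",
    "C3", "Cz", "C4", "T8", "P3", "P4", "O1", "O2",
)
#: 11 fNIRS source-detector channels.
DEFAULT_FNIRS_LABELS = tuple(f"N{i}" for i in range(1, 12))
#: fNIRS probes known to be co-located with EEG electrodes. Only the two
#: occipital co-locations are published; the rest of the map is left to the
#: user's montage description.
DEFAULT_COLOCATION = {"N3": "O2", "N5": "O1"}


class ValidationError(ValueError):
    """Raised when a recording or layout violates a structural invariant."""


def infer_modality(label: str) -> str:
    """Guess a channel's modality from its label.

    ``N<k>`` labels are fNIRS channels, literal ``ECG``/``RESP``/``RATE``
    prefixes map to themselves, and anything else is treated as EEG.
    """
    up = label.upper()
    if re.fullmatch(r"N\d+", up):
        return "FNIRS"
    for prefix in ("ECG", "RESP", "RATE"):
        if up.startswith(prefix):
            return prefix if prefix != "RATE" else "RATE"
    return "EEG"


@dataclass
class ChannelSeries:
    """A single uniformly sampled channel."""

    label: str
    samples: np.ndarray
    modality: str = "EEG"
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError(f"channel {self.label!r}: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"channel {self.label!r}: non-finite samples")
        if self.modality not in MODALITIES:
            raise ValidationError(f"channel {self.label!r}: unknown modality {self.modality!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class Recording:
    """Multichannel recording with shared sampling rate and subject metadata."""

    channels: list[ChannelSeries]
    fs: float
    subject_id: str = "anon"
    group_label: str = "SYNTH"
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            raise ValidationError("recording must contain at least one channel")
        if self.group_label not in GROUP_LABELS:
            raise ValidationError(f"unknown group label {self.group_label!r}")
        lengths = {ch.n_samples for ch in self.channels}
        if len(lengths) != 1:
            raise ValidationError(f"inconsistent channel lengths: {sorted(lengths)}")
        if lengths.pop() < 2:
            raise ValidationError("channels must contain at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.channels[0].n_samples

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    def channel(self, label: str) -> ChannelSeries:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise KeyError(f"no channel labelled {label!r}")

    def __contains__(self, label: str) -> bool:
        return any(ch.label == label for ch in self.channels)


@dataclass
class ProbeLayout:
    """Sensor layout: EEG electrode and fNIRS probe labels plus co-locations."""

    eeg_labels: tuple[str, ...] = DEFAULT_EEG_LABELS
    fnirs_labels: tuple[str, ...] = DEFAULT_FNIRS_LABELS
    colocation: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLOCATION))

    def __post_init__(self) -> None:
        if len(set(self.eeg_labels)) != len(self.eeg_labels):
            raise ValidationError("duplicate EEG labels")
        if len(set(self.fnirs_labels)) != len(self.fnirs_labels):
            raise ValidationError("duplicate fNIRS labels")
        for nirs, eeg in self.colocation.items():
            if nirs not in self.fnirs_labels or eeg not in self.eeg_labels:
                raise ValidationError(f"co-location {nirs}->{eeg} refers to unknown labels")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProbeLayout":
        doc = json.loads(Path(path).read_text())
        return cls(
            eeg_labels=tuple(doc["eeg"]),
            fnirs_labels=tuple(doc["fnirs"]),
            colocation=dict(doc.get("colocation", {})),
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "eeg": list(self.eeg_labels),
            "fnirs": list(self.fnirs_labels),
            "colocation": dict(self.colocation),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def enumerate_pairs(layout: ProbeLayout, mode: str) -> list[tuple[str, str]]:
    """Enumerate analysis channel pairs for a layout.

    ``fnirs_fnirs`` yields C(11,2)=55 pairs for the default layout,
    ``eeg_eeg`` C(16,2)=120 and ``fnirs_eeg`` 11*16=176. Ordering is
    deterministic (lexicographic in layout order).
    """
    if mode == "fnirs_fnirs":
        return list(combinations(layout.fnirs_labels, 2))
    if mode == "eeg_eeg":
        return list(combinations(layout.eeg_labels, 2))
    if mode == "fnirs_eeg":
        return [(n, e) for n in layout.fnirs_labels for e in layout.eeg_labels]
    raise ValueError(f"unknown pair mode {mode!r}; expected fnirs_fnirs, eeg_eeg or fnirs_eeg")


# ---------------------------------------------------------------------------
# Delimited (TSV) dialect
# ---------------------------------------------------------------------------

def _read_delimited(path: Path) -> Recording:
    with open(path) as fh:
        meta_line = fh.readline().strip()
        m = re.match(r"#fs=([0-9.eE+-]+)(?:\s+subject=(\S+))?(?:\s+group=(\S+))?", meta_line)
        if not m:
            raise ValidationError(f"{path}: missing '#fs=<Hz>' metadata line")
        fs = float(m.group(1))
        subject = m.group(2) or "anon"
        group = m.group(3) or "SYNTH"
        header = fh.readline().strip().split("\t")
        units = ["arbitrary"] * len(header)
        labels = []
        for col in header:
            if "(" in col and col.endswith(")"):
                lab, unit = col[:-1].split("(", 1)
                labels.append(lab)
                units[len(labels) - 1] = unit
            else:
                labels.append(col)
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise ValidationError(f"{path}: {len(labels)} labels but {data.shape[1]} data columns")
    channels = [
        ChannelSeries(lab, data[:, i], infer_modality(lab), units[i])
        for i, lab in enumerate(labels)
    ]
    return Recording(channels, fs=fs, subject_id=subject, group_label=group)


def _write_delimited(rec: Recording, path: Path) -> None:
    header = "\t".join(
        f"{ch.label}({ch.units})" if ch.units != "arbitrary" else ch.label
        for ch in rec.channels
    )
    data = np.column_stack([ch.samples for ch in rec.channels])
    with open(path, "w") as fh:
        fh.write(f"#fs={rec.fs:.10g} subject={rec.subject_id} group={rec.group_label}\n")
        fh.write(header + "\n")
        np.savetxt(fh, data, delimiter="\t", fmt="%.10g")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    orig_units = getattr(raw, "_orig_units", {}) or {}
    # MNE rescales dimensioned channels to SI; restore the file's units
    to_orig = {"uv": 1e6, "µv": 1e6, "mv": 1e3, "v": 1.0}
    channels = []
    for i, label in enumerate(raw.ch_names):
        modality = infer_modality(label)
        if modality == "EEG" and label not in DEFAULT_EEG_LABELS:
            logger.warning("EDF channel %r not in default montage; keeping as EEG", label)
        unit = orig_units.get(label, "arbitrary") or "arbitrary"
        factor = to_orig.get(unit.strip().lower(), 1.0)
        channels.append(ChannelSeries(label, data[i] * factor, modality, unit))
    return Recording(channels, fs=fs, subject_id=path.stem)


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: one data record holding the whole signal.

    Samples are quantized to 16-bit integers over each channel's physical
    range, the precision the format affords.
    """
    nch = rec.n_samples
    header = bytearray()

    def fixed(text: str, width: int) -> bytes:
        # EDF headers are ASCII; transliterate the few non-ASCII unit
        # symbols (µ -> u) rather than fail
        b = text.replace("µ", "u").encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    n_sig = len(rec.channels)
    record_dur = rec.n_samples / rec.fs
    header += fixed("0", 8)                               # version
    header += fixed(f"subject={rec.subject_id}", 80)      # patient id
    header += fixed(f"group={rec.group_label}", 80)       # recording id
    header += fixed("01.01.00", 8)                        # start date
    header += fixed("00.00.00", 8)                        # start time
    header += fixed(str(256 * (1 + n_sig)), 8)            # header bytes
    header += fixed("", 44)                               # reserved
    header += fixed("1", 8)                               # number of records
    header += fixed(f"{record_dur:.7g}", 8)               # record duration (s)
    header += fixed(str(n_sig), 4)

    phys_min, phys_max = [], []
    for ch in rec.channels:
        lo, hi = float(ch.samples.min()), float(ch.samples.max())
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)

    for ch in rec.channels:
        header += fixed(ch.label, 16)
    for ch in rec.channels:
        header += fixed(ch.modality, 80)                  # transducer
    for ch in rec.channels:
        header += fixed(ch.units, 8)
    for lo in phys_min:
        header += fixed(f"{lo:.8g}"[:8], 8)
    for hi in phys_max:
        header += fixed(f"{hi:.8g}"[:8], 8)
    for _ in rec.channels:
        header += fixed("-32768", 8)
    for _ in rec.channels:
        header += fixed("32767", 8)
    for _ in rec.channels:
        header += fixed("", 80)                           # prefiltering
    for _ in rec.channels:
        header += fixed(str(nch), 8)                      # samples per record
    for _ in rec.channels:
        header += fixed("", 32)                           # reserved

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for ch, lo, hi in zip(rec.channels, phys_min, phys_max):
            # re-parse the truncated physical range so scaling matches readers
            lo_r, hi_r = float(f"{lo:.8g}"[:8]), float(f"{hi:.8g}"[:8])
            if hi_r <= lo_r:
                hi_r = lo_r + 1.0
            scale = (hi_r - lo_r) / (32767 - (-32768))
            dig = np.round((ch.samples - lo_r) / scale) + (-32768)
            dig = np.clip(dig, -32768, 32767).astype("<i2")
            fh.write(dig.tobytes())


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF or the TSV dialect.

    The format is inferred from the suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording to EDF or the TSV dialect (suffix-inferred)."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "delimited":
        _write_delimited(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
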