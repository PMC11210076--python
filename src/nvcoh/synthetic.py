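"""Synthetic cohorts of physiological-like recordings with known ground truth.

Every pipeline stage is testable against signals whose band structure,
pairwise phase coupling and group effects are known by construction:

* Oscillatory components live in the canonical cardiovascular bands
  (0.007-2 Hz) and EEG rhythms; each has a centre frequency, amplitude,
  slow frequency drift and, when coupled, a phase lag and phase jitter.
* Frequency drift and phase jitter are Ornstein-Uhlenbeck processes with a
  30 s correlation time -- slow, physiological wandering rather than white
  noise. For a coupled pair with Gaussian phase jitter of standard
  deviation sigma_w the expected phase coherence at the coupling frequency
  is the Gaussian circular moment exp(-sigma_w^2 / 2), which provides a
  closed-form oracle for coherence recovery.
* The ECG-like signal is a train of Gaussian pulses whose instantaneous
  beat rate is modulated by the respiratory cycle (respiratory sinus
  arrhythmia), so ridge-based rate extraction has a known target.
* Recordings contain 1/f plus white noise and, optionally, sparse chorea-
  like artifact bursts that perturb amplitudes but barely touch phases.

All randomness descends from one master seed through numpy SeedSequence
spawning, so any subject or channel can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bandstats import FrequencyBand
from .signal_io import ChannelSeries, Recording

OU_TAU = 30.0  # s; correlation time of drift and jitter processes


def _ou_process(n: int, fs: float, rng: np.random.Generator, tau: float = OU_TAU) -> np.ndarray:
    """Unit-stationary-variance Ornstein-Uhlenbeck samples (exact AR(1) update)."""
    from scipy.signal import lfilter

    alpha = np.exp(-1.0 / (fs * tau))
    innov = rng.standard_normal(n) * np.sqrt(1.0 - alpha**2)
    innov[0] = rng.standard_normal()  # stationary start
    return lfilter([1.0], [1.0, -alpha], innov)


def _se_process(n: int, fs: float, rng: np.random.Generator, ell: float = OU_TAU) -> np.ndarray:
    """Unit-sd Gaussian process with squared-exponential correlation (length
    ``ell`` seconds).

    Used for phase jitter: unlike an AR(1)/OU process, its spectrum has no
    tail above ~1/(2*pi*ell) Hz, so wavelet analysis windows pass the
    jitter unsmoothed and the circular-moment relation
    WPC = exp(-sigma_w^2/2) holds for the measured coherence, not just the
    underlying phases. Each realization is normalized to unit sample
    standard deviation.
    """
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    filt = np.exp(-((2.0 * np.pi * f) ** 2) * ell**2 / 4.0)
    x = np.fft.irfft(np.fft.rfft(white) * filt, n)
    s = x.std()
    return x / s if s > 0 else x


def gen_phase(
    f0: float,
    drift_sd: float,
    duration: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Phase of an oscillator with slowly drifting instantaneous frequency.

    phi(t) = 2*pi * integral of f0*(1 + drift_sd*u(t)), with u an OU process
    of unit variance and 30 s correlation time. The mean phase velocity is
    2*pi*f0.
    """
    n = int(round(duration * fs))
    if drift_sd == 0:
        return 2.0 * np.pi * f0 * np.arange(n) / fs
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = _ou_process(n, fs, rng)
    freq = f0 * (1.0 + drift_sd * u)
    phase = 2.0 * np.pi * np.concatenate([[0.0], np.cumsum(freq[:-1])]) / fs
    return phase


@dataclass
class BandComponentSpec:
    """One oscillatory component of a generated channel."""

    band: FrequencyBand
    center_freq: float
    amplitude: float = 1.0
    freq_drift_sd: float = 0.02   # relative frequency drift
    phase_jitter_sd: float = 0.0  # sigma_w, radians, vs the shared source
    lag: float = 0.0              # Delta_0, radians
    shared: bool = False          # couple to the subject's common source

    def __post_init__(self) -> None:
        if self.center_freq not in self.band:
            raise ValueError(
                f"center {self.center_freq} Hz outside band {self.band.name}"
            )
        if self.phase_jitter_sd < 0 or self.amplitude < 0:
            raise ValueError("negative jitter or amplitude")


def gen_coupled_pair(
    spec: BandComponentSpec,
    duration: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two oscillations sharing a carrier phase, with programmed lag and jitter.

    x = A cos(phi_c);  y = A cos(phi_c + lag + w), with w a slow Gaussian
    process of sd sigma_w. Expected phase coherence at the centre
    frequency: exp(-sigma_w^2/2).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi = gen_phase(spec.center_freq, spec.freq_drift_sd, duration, fs, rng)
    n = phi.size
    w = spec.phase_jitter_sd * _se_process(n, fs, rng) if spec.phase_jitter_sd > 0 else 0.0
    x = spec.amplitude * np.cos(phi)
    y = spec.amplitude * np.cos(phi + spec.lag + w)
    return x, y


def one_over_f_noise(
    n: int, fs: float, rng: np.random.Generator, sd: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * shaping, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def gen_fnirs_channel(
    components: list[BandComponentSpec],
    duration: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
    white_sd: float = 0.1,
    pink_sd: float = 0.1,
    shared_phases: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Sum of band components plus 1/f and white noise.

    ``shared_phases`` maps band name -> precomputed carrier phase; a
    component with ``shared=True`` rides that carrier (plus its own lag and
    jitter), which is how cross-channel coupling is constructed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = np.zeros(n)
    for comp in components:
        if comp.center_freq >= fs / 2:
            raise ValueError(f"component at {comp.center_freq} Hz above Nyquist")
        if comp.shared and shared_phases is not None and comp.band.name in shared_phases:
            phi = shared_phases[comp.band.name]
        else:
            phi = gen_phase(comp.center_freq, comp.freq_drift_sd, duration, fs, rng)
        w = (
            comp.phase_jitter_sd * _se_process(n, fs, rng)
            if comp.phase_jitter_sd > 0
            else 0.0
        )
        x = x + comp.amplitude * np.cos(phi + comp.lag + w)
    if pink_sd > 0:
        x = x + one_over_f_noise(n, fs, rng, pink_sd)
    if white_sd > 0:
        x = x + white_sd * rng.standard_normal(n)
    return x


def gen_ecg(
    rate0: float = 1.2,
    rsa_amp: float = 0.1,
    resp_freq: float = 0.25,
    duration: float = 1200.0,
    fs: float = 100.0,
    seed: int | np.random.Generator | None = None,
    pulse_sd: float = 0.02,
    rate_jitter_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ECG-like pulse train with respiratory sinus arrhythmia.

    Beat times integrate r(t) = rate0 + rsa_amp*sin(2*pi*resp_freq*t)
    (plus optional slow OU jitter); each beat is a Gaussian pulse of
    standard deviation ``pulse_sd`` seconds (default 20 ms).

    Returns (ecg series, true instantaneous rate series).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rate = rate0 + rsa_amp * np.sin(2.0 * np.pi * resp_freq * t)
    if rate_jitter_sd > 0:
        rate = rate + rate_jitter_sd * _ou_process(n, fs, rng)
    cum = np.concatenate([[0.0], np.cumsum(rate[:-1])]) / fs  # beats elapsed
    n_beats = int(np.floor(cum[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), cum, t)
    ecg = np.zeros(n)
    half = int(np.ceil(4 * pulse_sd * fs))
    for bt in beat_times:
        i0 = max(0, int(np.floor((bt - 4 * pulse_sd) * fs)))
        i1 = min(n, i0 + 2 * half)
        ecg[i0:i1] += np.exp(-0.5 * ((t[i0:i1] - bt) / pulse_sd) ** 2)
    return ecg, rate


def gen_respiration(
    resp_freq: float = 0.25,
    duration: float = 1200.0,
    fs: float = 100.0,
    drift_sd: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Respiration effort as a slowly drifting sinusoid."""
    phi = gen_phase(resp_freq, drift_sd, duration, fs, seed)
    return np.cos(phi)


def add_artifact_bursts(
    x: np.ndarray,
    fs: float,
    rate: float,
    amplitude: float = 5.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Add sparse movement-like transients (chorea-style artifacts).

    Burst onsets follow a Poisson process of ``rate`` bursts/min; each
    burst is a Gaussian-envelope transient of 0.2-1 s with peak amplitude
    ``amplitude`` times the signal RMS. Amplitude metrics in affected
    windows are disturbed; phases of sustained oscillations barely move.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return np.asarray(x, dtype=float).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float).copy()
    n = x.size
    t = np.arange(n) / fs
    duration = n / fs
    n_bursts = rng.poisson(rate * duration / 60.0)
    rms = np.sqrt(np.mean(x**2)) or 1.0
    for _ in range(n_bursts):
        t0 = rng.uniform(0, duration)
        width = rng.uniform(0.2, 1.0) / 4.0  # envelope sd; support ~4 sd
        sign = rng.choice([-1.0, 1.0])
        i0 = max(0, int((t0 - 4 * width) * fs))
        i1 = min(n, int((t0 + 4 * width) * fs))
        x[i0:i1] += sign * amplitude * rms * np.exp(
            -0.5 * ((t[i0:i1] - t0) / width) ** 2
        )
    return x


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupEffect:
    """Per-band multipliers applied to one group's component parameters."""

    band_name: str
    jitter_multiplier: float = 1.0
    amplitude_multiplier: float = 1.0


@dataclass
class CohortSpec:
    """Recipe for a two-group synthetic cohort.

    Defaults mirror a presymptomatic-versus-control comparison: 13 disease-
    like and 29 control subjects, three fNIRS-like and three EEG-like
    channels per subject, 1200 s at 10 Hz, with a shared myogenic
    (0.1 Hz) oscillation coupling every channel pair.
    """

    n_group1: int = 13
    n_group2: int = 29
    group1_label: str = "P"
    group2_label: str = "PC"
    fnirs_labels: tuple[str, ...] = ("N1", "N2", "N3")
    eeg_labels: tuple[str, ...] = ("O1", "O2", "Cz")
    fs: float = 10.0
    duration: float = 1200.0
    components: tuple[BandComponentSpec, ...] = ()
    base_jitter_sd: float = 0.7        # per-channel sigma_w for shared bands
    subject_jitter_spread: float = 0.15
    group_effects: tuple[GroupEffect, ...] = ()
    white_sd: float = 0.1
    pink_sd: float = 0.1
    artifact_rate: float = 0.0         # bursts/min
    artifact_amplitude: float = 5.0
    include_cardio: bool = False       # add ECG + respiration channels
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.duration < 600 and any(
            c.center_freq < 0.05 for c in self.components
        ):
            raise ValueError("sub-0.05 Hz components need >= 600 s records")
        if not self.components:
            myo = FrequencyBand("myogenic", 0.052, 0.145)
            self.components = (
                BandComponentSpec(
                    myo, 0.1, amplitude=1.0, freq_drift_sd=0.05, shared=True
                ),
            )


def hd_like_spec(master_seed: int = 0, **overrides) -> CohortSpec:
    """Disease-like preset: myogenic phase jitter raised in group 1.

    The jitter multiplier is chosen so the drop in pair coherence is about
    one within-group standard deviation (Cohen's d near 1): with both
    channels jittered at sigma, pair coherence is exp(-sigma^2); moving
    sigma from 0.70 to 0.85 with a 0.15 subject-level spread gives
    approximately that separation.
    """
    params = dict(
        group_effects=(GroupEffect("myogenic", jitter_multiplier=0.85 / 0.70),),
        master_seed=master_seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


def null_spec(master_seed: int = 0, **overrides) -> CohortSpec:
    """Identical generating distributions in both groups."""
    return CohortSpec(master_seed=master_seed, **overrides)


@dataclass
class CohortLedger:
    """Ground truth for every generated subject, channel and band."""

    # subject -> channel -> band -> {"sigma_w","lag","amplitude","center_freq"}
    entries: dict[str, dict[str, dict[str, dict[str, float]]]] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)

    def expected_pair_coherence(self, subject: str, ch_a: str, ch_b: str, band: str) -> float:
        """Closed-form coherence oracle exp(-(sigma_a^2 + sigma_b^2)/2)."""
        sa = self.entries[subject][ch_a][band]["sigma_w"]
        sb = self.entries[subject][ch_b][band]["sigma_w"]
        return float(np.exp(-(sa**2 + sb**2) / 2.0))

    def to_json_dict(self) -> dict:
        return {"entries": self.entries, "group_of": self.group_of}


def gen_cohort(spec: CohortSpec) -> tuple[list[Recording], CohortLedger]:
    """Generate a reproducible two-group cohort plus its ground-truth ledger."""
    root = np.random.SeedSequence(spec.master_seed)
    ledger = CohortLedger()
    recordings: list[Recording] = []
    n_total = spec.n_group1 + spec.n_group2
    subject_seeds = root.spawn(n_total)

    for si in range(n_total):
        in_group1 = si < spec.n_group1
        group = spec.group1_label if in_group1 else spec.group2_label
        subject = f"{group}{si:03d}"
        sub_rng_root = subject_seeds[si]
        # one spawned stream per purpose keeps channels independently
        # reproducible
        streams = sub_rng_root.spawn(3 + len(spec.fnirs_labels) + len(spec.eeg_labels))
        carrier_rng = np.random.default_rng(streams[0])
        subj_rng = np.random.default_rng(streams[1])
        cardio_rng = np.random.default_rng(streams[2])

        # subject-level shared carriers, one per shared band
        shared_phases: dict[str, np.ndarray] = {}
        for comp in spec.components:
            if comp.shared and comp.band.name not in shared_phases:
                shared_phases[comp.band.name] = gen_phase(
                    comp.center_freq, comp.freq_drift_sd, spec.duration, spec.fs,
                    carrier_rng,
                )

        effects = {e.band_name: e for e in spec.group_effects}
        channels: list[ChannelSeries] = []
        ledger.entries[subject] = {}
        ledger.group_of[subject] = group

        all_labels = [(lab, "FNIRS") for lab in spec.fnirs_labels]
        all_labels += [(lab, "EEG") for lab in spec.eeg_labels]
        for ci, (label, modality) in enumerate(all_labels):
            ch_rng = np.random.default_rng(streams[3 + ci])
            comps = []
            ledger.entries[subject][label] = {}
            for comp in spec.components:
                jit = comp.phase_jitter_sd if not comp.shared else spec.base_jitter_sd
                eff = effects.get(comp.band.name)
                if eff is not None and in_group1:
                    jit *= eff.jitter_multiplier
                amp = comp.amplitude
                if eff is not None and in_group1:
                    amp *= eff.amplitude_multiplier
                # subject-level heterogeneity in coupling strength
                jit = max(0.0, jit + spec.subject_jitter_spread * subj_rng.standard_normal())
                lag = comp.lag
                comps.append(
                    BandComponentSpec(
                        comp.band, comp.center_freq, amp, comp.freq_drift_sd,
                        jit, lag, comp.shared,
                    )
                )
                ledger.entries[subject][label][comp.band.name] = {
                    "sigma_w": jit,
                    "lag": lag,
                    "amplitude": amp,
                    "center_freq": comp.center_freq,
                }
            x = gen_fnirs_channel(
                comps, spec.duration, spec.fs, ch_rng,
                white_sd=spec.white_sd, pink_sd=spec.pink_sd,
                shared_phases=shared_phases,
            )
            if spec.artifact_rate > 0:
                x = add_artifact_bursts(
                    x, spec.fs, spec.artifact_rate, spec.artifact_amplitude, ch_rng
                )
            units = "µmol/mL" if modality == "FNIRS" else "µV"
            channels.append(ChannelSeries(label, x, modality, units))

        if spec.include_cardio:
            resp_freq = 0.25 + 0.02 * cardio_rng.standard_normal()
            rate0 = 1.2 + 0.05 * cardio_rng.standard_normal()
            ecg, _ = gen_ecg(
                rate0, 0.1, resp_freq, spec.duration, spec.fs, cardio_rng
            )
            resp = gen_respiration(resp_freq, spec.duration, spec.fs, 0.0, cardio_rng)
            channels.append(ChannelSeries("ECG", ecg, "ECG"))
            channels.append(ChannelSeries("RESP", resp, "RESP"))

        recordings.append(
            Recording(channels, spec.fs, subject_id=subject, group_label=group)
        )
    return recordings, ledger
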