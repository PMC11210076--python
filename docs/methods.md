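# Methods

`nvcoh` analyses coordinated oscillations in simultaneously recorded brain
and cardiovascular signals — fNIRS oxygenation, EEG, ECG and respiration
effort — across the frequency range 0.007–48 Hz. This note documents the
models, the numerical choices, and what the synthetic test bed does and
does not establish.

## Signal model and frequency bands

Physiological time series are treated as sums of oscillatory modes with
slowly time-varying frequency and amplitude, embedded in 1/f plus white
noise. Modes are interpreted through canonical frequency bands:
six cardiovascular bands tiling 0.007–2 Hz (two endothelial, neurogenic
0.021–0.052, myogenic 0.052–0.145, respiratory 0.145–0.6, cardiac 0.6–2 Hz)
and the EEG rhythms δ–γ up to 48 Hz with the β/γ split selectable at 22 Hz
(default) or 30 Hz. Band intervals are half-open `[lo, hi)` so touching
edges assign each frequency to exactly one band.

## Preprocessing

A continuous analysis segment (default: first 1200 s) is cut from each
recording; channels are detrended by subtracting a least-squares cubic
polynomial, bandpass filtered, and downsampled by a centred moving average
followed by linear interpolation onto the exact output grid (which handles
non-integer rate ratios such as 1000 → 142 Hz). The bandpass is a
2nd-order Butterworth applied forward–backward: the pipeline's core
currency is phase, and a zero-phase realization keeps in-band phase errors
below 0.02 rad through the whole chain (verified by test). Per-analysis
target rates are presets: 31.25 Hz for fNIRS–EEG work, 20 Hz for slow
coherence analyses, 142 Hz for fast EEG rhythms, 100 Hz for ECG and
respiration before rate extraction.

## Time–frequency transforms

Slow oscillations are analysed with a continuous analytic wavelet
transform on a logarithmic grid (default 273 frequencies, 0.007–4 Hz),
computed by FFT-based convolution with reflect padding. Two wavelet
families are provided, both defined in the frequency domain and both
normalized so a unit-amplitude sinusoid at a grid frequency produces unit
coefficient magnitude:

* **Morlet** (default resolution f₀ = 1): Gaussian frequency response of
  relative width 1/(2πf₀); time envelope sd f₀/ν.
* **Lognormal** (default resolution r = 2, used for ridge extraction):
  Gaussian in ln ν with sd 5/(2πr); time envelope sd ≈ r/5 periods. The
  width constant is deliberately short-in-time: rate extraction must track
  respiratory-frequency modulation of the cardiac rhythm (±0.1 Hz at
  0.25 Hz), which a longer envelope low-pass filters away. The broad
  frequency response this implies is harmless because ridge extraction
  band-isolates its input first (see below).

Fast EEG rhythms (4–48 Hz) use a Gaussian-windowed Fourier transform on a
linear grid (default step 0.1 Hz, window 1 s — the window length is a
package default, chosen to resolve the α band while keeping ~1 s time
resolution).

Every transform carries a cone-of-influence mask excluding samples closer
to a record edge than the envelope's amplitude e-folding time; all time
averages (power, coherence) use only mask-valid samples. Band ("total")
power integrates |W|²/(2·ENBW(ν)) over the band, where ENBW is the
analysis filter's equivalent noise bandwidth (∝ ν for wavelets); this
calibrates a unit in-band sinusoid to its mean square 0.5 at any in-band
frequency, so powers are reported in signal-squared units.

## Ridge extraction and instantaneous rates

A single oscillatory mode is followed through the time–frequency plane by
dynamic programming: the path ν(t) maximizes Σ ln|W| − λ(Δ ln ν)² within a
band. The penalty λ defaults to 1/(s·ln2·Δ) with allowed slew s = 0.3
octave/s and Δ the grid's log step — calibrated so that traversing the
grid at the allowed slew costs about one log-amplitude unit per second.
(Calibrating against the grid step matters: a path on a discrete grid
moves in whole steps, so a continuum-style penalty over-prices tracking by
the step/continuum ratio squared.)

The instantaneous heart (or respiration) rate is obtained by: zero-phase
bandpass to the extraction band (0.6–2 Hz for ECG, with a 0.8–3 Hz
fallback for fast hearts; 0.145–0.6 Hz for respiration) — this strips
pulse-train harmonics whose beating otherwise contaminates the ridge;
lognormal-wavelet transform and ridge extraction; rate = derivative of the
unwrapped ridge phase, smoothed by a zero-phase lowpass at half the median
rate. The lowpass removes sub-beat phase ripple — instantaneous rate is
not physically defined at sub-beat timescales — while passing
respiratory-scale modulation. The output has the input's length and
sampling rate, with no beat detection or interpolation. On synthetic ECG
with respiratory sinus arrhythmia (rate 1.2 + 0.1·sin(2π·0.25t) Hz) the
recovered IHR has RMS error ≤ 0.03 Hz and modulation amplitude within 20%.

Cardiac artifact removal from EEG subtracts a band-limited reconstruction
(amplitude·cos(phase), reconstruction gain 1 under the transform's
calibration) of the cardiac-band ridge. A whitened spectral-prominence
gate (band power divided by ν must peak ≥ 1.2× its median) prevents
subtraction when no cardiac component is present. This is a single-mode
simplification: no harmonic stack is identified or removed.

## Wavelet phase coherence and surrogates

At each frequency, coherence is |⟨e^{iΔφ}⟩_t| over samples valid in both
cones of influence, with Δφ = φ₁ − φ₂; the circular mean of Δφ is reported
alongside, with the convention that a positive value means the first
signal leads. The measure is amplitude-invariant by construction. A
time-localized variant averages the phasor in a sliding window of
`window_cycles`/ν seconds (default 10 cycles — long enough to bound the
small-sample coherence bias, short enough to resolve minute-scale coupling
epochs).

Finite records make unrelated signals appear coherent, increasingly so at
low frequencies. The null level is estimated with inter-subject
surrogates: coherence between channel a of subject i and channel b of
subject j ≠ i, both preprocessed identically and truncated to the common
length. By default 176 ordered cross-subject pairs are drawn uniformly
without repetition (seeded), and the per-frequency threshold is the
nearest-rank 95th percentile of the surrogate ensemble. "Effective
coherence" is raw minus threshold, kept signed — clipping at zero would
bias group means upward. Calibration on independent-noise cohorts puts
the fraction of frequencies exceeding the threshold at 5% ± 2% and the
mean band-averaged effective coherence at or below zero.

## Group statistics

Subject × pair tables of band-averaged effective coherence (or power; the
band average is the unweighted mean over grid frequencies in the band,
i.e. log-uniform weighting on the native grid) are compared between two
groups pair-by-pair with the two-sided Wilcoxon rank-sum test: exact
enumeration of all label assignments for pooled n ≤ 12, the tie- and
continuity-corrected normal approximation otherwise. Significant results
can be confirmed by a Monte Carlo permutation test (default 16 000
re-randomizations into the original group sizes; confirmation requires the
observed p to lie below the 5th percentile of the permuted p distribution).
Multiplicity over a family of N pairs is summarized by the exact binomial
tail P(X ≥ k | N, 0.05), evaluated in log space; no per-test FDR
correction is applied — the count-based binomial argument is the
multiplicity control.

## Synthetic cohorts

The generator builds multichannel recordings whose ground truth is known
exactly and recorded in a ledger:

* Oscillatory components with OU-drifting frequency (30 s correlation
  time) in any canonical band; channels sharing a band carrier are
  mutually phase-coupled.
* Phase jitter between coupled channels is a **squared-exponential**
  Gaussian process (30 s correlation length), not an AR(1)/OU process.
  This is deliberate: the wavelet's analysis window partially averages any
  jitter spectrum with a heavy high-frequency tail, which would bias
  measured coherence above the circular-moment prediction e^{−σ_w²/2} by
  up to +0.16 regardless of the correlation time. The squared-exponential
  spectrum has no such tail, and measured coherence matches e^{−σ_w²/2}
  within ±0.02 for σ_w ≤ 1.5 on 1200-s records. Pair coherence with both
  channels jittered at σ is e^{−σ²}.
* ECG-like pulse trains (Gaussian pulses, 20 ms sd) whose beat rate is
  modulated by the respiratory cycle; respiration as a drifting sinusoid.
* 1/f plus white noise; optional chorea-like artifact bursts (Poisson
  onsets, 0.2–1 s Gaussian-envelope transients) that disturb amplitude
  metrics while leaving phase coherence within 0.1.
* Two-group cohorts (default 13 vs 29 subjects, the presymptomatic-style
  split) with per-band group effects on jitter and amplitude. The
  disease-like preset raises myogenic jitter from σ = 0.70 to 0.85 with a
  0.15 subject-level spread, chosen analytically so the pair-coherence
  drop is about one within-group standard deviation (Cohen's d ≈ 1).
* One master seed expands to per-subject, per-channel streams via
  SeedSequence spawning; cohorts are byte-reproducible.

What the synthetic bed does **not** emulate: haemodynamic forward
coupling, realistic ECG morphology, spatially structured noise,
movement-artifact spectra of real chorea, or inter-band cross-talk.
Passing tests therefore demonstrate that the estimators are correctly
calibrated and powered under the stated signal model — not that any
particular biological effect exists in real recordings.

## Problem sizes used in validation

Validation runs use 1200 s records at 20 Hz for coherence calibration
(200 Monte Carlo pairs against a 15-subject, 176-surrogate threshold),
600 s at 100 Hz for rate recovery, 2000 simulations for rank-sum type-I
calibration, 200 replicates of 1000 permutations for permutation-test
calibration, and end-to-end cohorts of 13 vs 29 subjects with three
fNIRS-like and three EEG-like channels at 10 Hz on a 60-frequency grid
over 0.02–0.5 Hz. These sizes give Monte Carlo standard errors comfortably
inside the asserted tolerances.

## Known limitations

* The windowed-Fourier window length and the exact frequency count of the
  reference grid are package defaults; they are configurable but not
  derivable from first principles.
* Cardiac removal handles one mode; signals with strong cardiac harmonics
  inside the analysis band retain them.
* The full fNIRS↔EEG co-location map ships with only the two published
  occipital entries (N3↔O2, N5↔O1); supply a layout JSON for a complete
  montage.
* Effective coherence is signed; downstream users should not interpret
  negative values as anticoherence, only as sub-null coherence.
* EDF output is 16-bit quantized (the format's precision); the TSV dialect
  round-trips losslessly to 1e-6 relative error.
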