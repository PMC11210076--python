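import numpy as np
import pytest

from nvcoh.bandstats import band_by_name
from nvcoh.coherence import wavelet_phase_coherence
from nvcoh.synthetic import (
    BandComponentSpec,
    CohortSpec,
    add_artifact_bursts,
    gen_cohort,
    gen_coupled_pair,
    gen_ecg,
    gen_fnirs_channel,
    gen_phase,
    hd_like_spec,
)
from nvcoh.timefreq import make_log_grid, total_power, wavelet_transform

MYO = band_by_name("myogenic")
FS = 10.0


class TestGenPhase:
    def test_zero_drift_is_linear_phase(self):
        phi = gen_phase(0.1, 0.0, 100.0, FS)
        t = np.arange(phi.size) / FS
        np.testing.assert_allclose(phi, 2 * np.pi * 0.1 * t, atol=1e-9)

    def test_mean_rate_preserved_under_drift(self):
        phi = gen_phase(0.1, 0.1, 2400.0, FS, seed=3)
        mean_rate = (phi[-1] - phi[0]) / (2 * np.pi * (phi.size - 1) / FS)
        assert mean_rate == pytest.approx(0.1, rel=0.02)

    def test_same_seed_identical(self):
        a = gen_phase(0.1, 0.05, 60.0, FS, seed=9)
        b = gen_phase(0.1, 0.05, 60.0, FS, seed=9)
        np.testing.assert_array_equal(a, b)


class TestCoupledPair:
    def test_zero_jitter_perfect_lock(self):
        spec = BandComponentSpec(MYO, 0.1, freq_drift_sd=0.03, phase_jitter_sd=0.0)
        x, y = gen_coupled_pair(spec, 1200.0, FS, seed=1)
        grid = make_log_grid(0.05, 0.5, 40)
        c = wavelet_phase_coherence(
            wavelet_transform(x, FS, grid), wavelet_transform(y, FS, grid)
        )
        k = np.argmin(np.abs(grid.values - 0.1))
        assert c.raw[k] >= 0.99

    def test_jitter_reduces_coherence_per_circular_moment(self):
        grid = make_log_grid(0.05, 0.5, 40)
        k = np.argmin(np.abs(grid.values - 0.1))
        vals = []
        for seed in range(4):
            spec = BandComponentSpec(MYO, 0.1, freq_drift_sd=0.03, phase_jitter_sd=1.0)
            x, y = gen_coupled_pair(spec, 1200.0, FS, seed=seed)
            c = wavelet_phase_coherence(
                wavelet_transform(x, FS, grid), wavelet_transform(y, FS, grid)
            )
            vals.append(c.raw[k])
        assert np.mean(vals) == pytest.approx(np.exp(-0.5), abs=0.05)

    def test_center_outside_band_rejected(self):
        with pytest.raises(ValueError):
            BandComponentSpec(MYO, 0.3)


class TestGenECG:
    def test_beat_count_matches_rate(self):
        ecg, _ = gen_ecg(1.2, 0.0, 0.25, 300.0, 100.0, seed=1)
        # each beat contributes one Gaussian pulse of integral sqrt(2*pi)*sd
        n_beats = ecg.sum() / (np.sqrt(2 * np.pi) * 0.02 * 100.0)
        assert n_beats == pytest.approx(1.2 * 300.0, rel=0.02)

    def test_true_rate_series_returned(self):
        _, rate = gen_ecg(1.2, 0.1, 0.25, 60.0, 100.0, seed=1)
        t = np.arange(rate.size) / 100.0
        np.testing.assert_allclose(rate, 1.2 + 0.1 * np.sin(2 * np.pi * 0.25 * t))

    def test_deterministic(self):
        a, _ = gen_ecg(1.2, 0.1, 0.25, 60.0, 100.0, seed=5)
        b, _ = gen_ecg(1.2, 0.1, 0.25, 60.0, 100.0, seed=5)
        np.testing.assert_array_equal(a, b)


class TestGenChannel:
    def test_single_component_band_power(self):
        comp = BandComponentSpec(MYO, 0.1, amplitude=2.0, freq_drift_sd=0.02)
        x = gen_fnirs_channel([comp], 1200.0, FS, seed=2, white_sd=0.0, pink_sd=0.0)
        grid = make_log_grid(0.02, 1.0, 80)
        tfr = wavelet_transform(x, FS, grid)
        assert total_power(tfr, MYO.lo, MYO.hi) == pytest.approx(2.0**2 / 2, rel=0.10)

    def test_band_power_with_noise_within_quarter(self):
        comp = BandComponentSpec(MYO, 0.1, amplitude=1.0, freq_drift_sd=0.02)
        x = gen_fnirs_channel([comp], 1200.0, FS, seed=3, white_sd=0.15, pink_sd=0.15)
        grid = make_log_grid(0.02, 1.0, 80)
        tfr = wavelet_transform(x, FS, grid)
        assert total_power(tfr, MYO.lo, MYO.hi) == pytest.approx(0.5, rel=0.25)

    def test_component_above_nyquist_rejected(self):
        comp = BandComponentSpec(band_by_name("cardiac"), 1.9)
        with pytest.raises(ValueError, match="Nyquist"):
            gen_fnirs_channel([comp], 60.0, 2.0, seed=1)

    def test_pure_noise_channels_uncoupled(self):
        grid = make_log_grid(0.05, 0.5, 30)
        x = gen_fnirs_channel([], 600.0, FS, seed=10)
        y = gen_fnirs_channel([], 600.0, FS, seed=11)
        c = wavelet_phase_coherence(
            wavelet_transform(x, FS, grid), wavelet_transform(y, FS, grid)
        )
        k = np.argmin(np.abs(grid.values - 0.1))
        assert c.raw[k] < 0.4


class TestArtifacts:
    def test_zero_rate_is_identity(self, rng):
        x = rng.standard_normal(1000)
        np.testing.assert_array_equal(add_artifact_bursts(x, FS, 0.0), x)

    def test_bursts_raise_amplitude_but_spare_phase(self):
        """Chorea-like bursts must disturb power while leaving band
        coherence of a coupled pair nearly unchanged."""
        spec = BandComponentSpec(MYO, 0.1, freq_drift_sd=0.03, phase_jitter_sd=0.5)
        x, y = gen_coupled_pair(spec, 1200.0, FS, seed=21)
        y_art = add_artifact_bursts(y, FS, rate=6.0, amplitude=5.0, seed=22)
        grid = make_log_grid(0.05, 0.5, 30)
        tx = wavelet_transform(x, FS, grid)
        c_clean = wavelet_phase_coherence(tx, wavelet_transform(y, FS, grid))
        c_art = wavelet_phase_coherence(tx, wavelet_transform(y_art, FS, grid))
        k = np.argmin(np.abs(grid.values - 0.1))
        assert abs(c_clean.raw[k] - c_art.raw[k]) <= 0.1
        # amplitude metrics in affected windows ARE disturbed: the peak
        # one-second mean square jumps by far more than the clean signal's
        w = int(FS)
        ms = lambda s: np.convolve(s**2, np.ones(w) / w, mode="valid")
        assert ms(y_art).max() > 5 * ms(y).max()


class TestCohort:
    def test_reproducible_from_master_seed(self):
        spec = CohortSpec(n_group1=2, n_group2=2, duration=120.0)
        c1, l1 = gen_cohort(spec)
        c2, l2 = gen_cohort(spec)
        for a, b in zip(c1, c2):
            assert a.subject_id == b.subject_id
            for ca, cb in zip(a.channels, b.channels):
                np.testing.assert_array_equal(ca.samples, cb.samples)
        assert l1.entries == l2.entries

    def test_group_sizes_and_labels(self):
        spec = CohortSpec(n_group1=3, n_group2=4, duration=120.0)
        cohort, ledger = gen_cohort(spec)
        assert sum(r.group_label == "P" for r in cohort) == 3
        assert sum(r.group_label == "PC" for r in cohort) == 4
        assert set(ledger.group_of.values()) == {"P", "PC"}

    def test_ledger_predicts_pair_coherence(self):
        spec = CohortSpec(
            n_group1=2, n_group2=2, duration=1200.0, white_sd=0.02, pink_sd=0.02,
            subject_jitter_spread=0.0,
        )
        cohort, ledger = gen_cohort(spec)
        rec = cohort[0]
        grid = make_log_grid(0.05, 0.5, 40)
        t1 = wavelet_transform(rec.channel("N1").samples, rec.fs, grid)
        t2 = wavelet_transform(rec.channel("N2").samples, rec.fs, grid)
        c = wavelet_phase_coherence(t1, t2)
        k = np.argmin(np.abs(grid.values - 0.1))
        expected = ledger.expected_pair_coherence(rec.subject_id, "N1", "N2", "myogenic")
        assert c.raw[k] == pytest.approx(expected, abs=0.07)

    def test_disease_preset_raises_group1_jitter(self):
        cohort, ledger = gen_cohort(hd_like_spec(0, n_group1=4, n_group2=4, duration=120.0))
        sig1 = [ledger.entries[s]["N1"]["myogenic"]["sigma_w"]
                for s, g in ledger.group_of.items() if g == "P"]
        sig2 = [ledger.entries[s]["N1"]["myogenic"]["sigma_w"]
                for s, g in ledger.group_of.items() if g == "PC"]
        assert np.mean(sig1) > np.mean(sig2)
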