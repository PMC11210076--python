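import numpy as np
import pytest

from nvcoh.bandstats import FrequencyBand
from nvcoh.coherence import (
    band_phase_difference,
    effective_coherence,
    nearest_rank_percentile,
    surrogate_threshold,
    time_localized_wpc,
    wavelet_phase_coherence,
)
from nvcoh.signal_io import ValidationError
from nvcoh.synthetic import BandComponentSpec, gen_coupled_pair
from nvcoh.timefreq import make_log_grid, wavelet_transform

FS = 20.0
MYOGENIC = FrequencyBand("myogenic", 0.052, 0.145)


@pytest.fixture(scope="module")
def grid():
    return make_log_grid(0.02, 2.0, 80)


def noise_tfr(rng, grid, duration=600.0):
    return wavelet_transform(rng.standard_normal(int(duration * FS)), FS, grid)


class TestWPCBasics:
    def test_self_coherence_is_one(self, rng, grid):
        tfr = noise_tfr(rng, grid)
        spec = wavelet_phase_coherence(tfr, tfr)
        assert np.nanmin(spec.raw) >= 1.0 - 1e-9
        assert np.nanmax(np.abs(spec.phase_diff)) <= 1e-9

    def test_amplitude_scaling_invariance(self, rng, grid):
        from nvcoh.preprocess import detrend_poly

        x = rng.standard_normal(int(600 * FS))
        x -= x.mean()
        y = detrend_poly(5.0 * x + 3.0, FS, order=0)  # affine copy, offset removed
        t1 = wavelet_transform(x, FS, grid)
        t2 = wavelet_transform(y, FS, grid)
        ref = wavelet_phase_coherence(t1, t1)
        scaled = wavelet_phase_coherence(t1, t2)
        np.testing.assert_allclose(scaled.raw, ref.raw, atol=1e-9)
        np.testing.assert_allclose(scaled.phase_diff, 0.0, atol=1e-9)

    def test_symmetry_and_phase_antisymmetry(self, rng, grid):
        t1 = noise_tfr(rng, grid)
        t2 = noise_tfr(rng, grid)
        ab = wavelet_phase_coherence(t1, t2)
        ba = wavelet_phase_coherence(t2, t1)
        np.testing.assert_allclose(ab.raw, ba.raw, atol=1e-12)
        np.testing.assert_allclose(ab.phase_diff, -ba.phase_diff, atol=1e-12)

    def test_independent_noise_low_coherence(self, rng, grid):
        t1 = noise_tfr(rng, grid, duration=1200.0)
        t2 = noise_tfr(rng, grid, duration=1200.0)
        spec = wavelet_phase_coherence(t1, t2)
        k = np.argmin(np.abs(grid.values - 1.0))
        assert spec.raw[k] < 0.15

    def test_mismatched_grids_rejected(self, rng):
        g1 = make_log_grid(0.02, 2.0, 80)
        g2 = make_log_grid(0.02, 2.0, 60)
        t1 = wavelet_transform(rng.standard_normal(2000), FS, g1)
        t2 = wavelet_transform(rng.standard_normal(2000), FS, g2)
        with pytest.raises(ValueError, match="grids"):
            wavelet_phase_coherence(t1, t2)


class TestPhaseDifference:
    def test_delay_maps_to_positive_phase(self, grid):
        # y lags x by 0.5 s; at 0.1 Hz the phase of x leads by 2*pi*0.1*0.5
        fs = FS
        tt = np.arange(int(1200 * fs)) / fs
        x = np.cos(2 * np.pi * 0.1 * tt)
        y = np.cos(2 * np.pi * 0.1 * (tt - 0.5))
        t1 = wavelet_transform(x, fs, grid)
        t2 = wavelet_transform(y, fs, grid)
        spec = wavelet_phase_coherence(t1, t2)
        k = np.argmin(np.abs(grid.values - 0.1))
        assert spec.phase_diff[k] == pytest.approx(2 * np.pi * 0.1 * 0.5, abs=0.05)

    def test_identical_inputs_zero_phase(self, rng, grid):
        tfr = noise_tfr(rng, grid)
        spec = wavelet_phase_coherence(tfr, tfr)
        assert band_phase_difference(spec, 0.05, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_programmed_lag_recovered(self, grid):
        spec_def = BandComponentSpec(
            MYOGENIC, 0.1, freq_drift_sd=0.03, phase_jitter_sd=0.3, lag=np.pi / 4
        )
        x, y = gen_coupled_pair(spec_def, 1200.0, FS, seed=7)
        t1 = wavelet_transform(x, FS, grid)
        t2 = wavelet_transform(y, FS, grid)
        spec = wavelet_phase_coherence(t2, t1)  # y leads by pi/4
        assert band_phase_difference(spec, 0.08, 0.125) == pytest.approx(np.pi / 4, abs=0.1)

    def test_empty_band_rejected(self, rng, grid):
        spec = wavelet_phase_coherence(noise_tfr(rng, grid), noise_tfr(rng, grid))
        with pytest.raises(ValidationError):
            band_phase_difference(spec, 5.0, 8.0)


class TestCouplingStrength:
    def test_coherence_decreases_with_jitter(self, grid):
        k = np.argmin(np.abs(grid.values - 0.1))
        values = []
        for sw in (0.0, 0.8, 1.5):
            spec_def = BandComponentSpec(
                MYOGENIC, 0.1, freq_drift_sd=0.03, phase_jitter_sd=sw
            )
            x, y = gen_coupled_pair(spec_def, 1200.0, FS, seed=11)
            c = wavelet_phase_coherence(
                wavelet_transform(x, FS, grid), wavelet_transform(y, FS, grid)
            )
            values.append(c.raw[k])
        assert values[0] >= 0.99
        assert values[0] > values[1] > values[2]


class TestTimeLocalizedWPC:
    def test_identical_inputs_give_unit_map(self, rng, grid):
        tfr = noise_tfr(rng, grid, duration=300.0)
        m = time_localized_wpc(tfr, tfr, window_cycles=10)
        assert np.nanmin(m) >= 1.0 - 1e-9

    def test_window_longer_than_record_flagged(self, rng, grid):
        tfr = noise_tfr(rng, grid, duration=120.0)
        m = time_localized_wpc(tfr, tfr, window_cycles=10)
        k_low = 0  # 10 cycles at 0.02 Hz = 500 s > record
        assert np.all(np.isnan(m[:, k_low]))

    def test_transient_coupling_localized(self):
        # two oscillators phase-locked only during [300, 600) s
        fs = FS
        n = int(900 * fs)
        tt = np.arange(n) / fs
        rng = np.random.default_rng(3)
        phi = 2 * np.pi * 0.1 * tt
        x = np.cos(phi)
        w = np.cumsum(rng.standard_normal(n)) * 0.15  # random-walk phase
        locked = (tt >= 300) & (tt < 600)
        other = np.where(locked, phi + 0.4, phi + w)
        y = np.cos(other)
        grid2 = make_log_grid(0.05, 0.5, 30)
        m = time_localized_wpc(
            wavelet_transform(x, fs, grid2),
            wavelet_transform(y, fs, grid2),
            window_cycles=10,
        )
        k = np.argmin(np.abs(grid2.values - 0.1))
        inside = np.nanmean(m[int(350 * fs):int(550 * fs), k])
        outside = np.nanmean(m[int(650 * fs):int(850 * fs), k])
        assert inside - outside >= 0.3


class TestSurrogates:
    def test_nearest_rank_percentile_order_statistic(self):
        values = np.arange(0.01, 0.21, 0.01).reshape(-1, 1)
        assert nearest_rank_percentile(values, 95.0)[0] == pytest.approx(0.19)

    def test_default_surrogate_count(self, rng, grid):
        tfrs = [noise_tfr(rng, grid, duration=120.0) for _ in range(15)]
        thr, ens = surrogate_threshold(tfrs, tfrs, seed=0)
        assert ens.n_surrogates == 176
        assert thr.shape == (grid.n,)
        finite = ens.values[np.isfinite(ens.values)]
        assert finite.size and np.all((finite >= 0) & (finite <= 1))

    def test_too_few_subjects_rejected(self, rng, grid):
        tfrs = [noise_tfr(rng, grid, duration=60.0)]
        with pytest.raises(ValidationError):
            surrogate_threshold(tfrs, tfrs, n_surrogates=20)

    def test_more_surrogates_than_pairs_rejected(self, rng, grid):
        tfrs = [noise_tfr(rng, grid, duration=60.0) for _ in range(4)]
        with pytest.raises(ValidationError, match="ordered"):
            surrogate_threshold(tfrs, tfrs, n_surrogates=20)

    def test_seed_reproducibility(self, rng, grid):
        tfrs = [noise_tfr(rng, grid, duration=120.0) for _ in range(8)]
        thr1, _ = surrogate_threshold(tfrs, tfrs, n_surrogates=30, seed=5)
        thr2, _ = surrogate_threshold(tfrs, tfrs, n_surrogates=30, seed=5)
        np.testing.assert_array_equal(thr1, thr2)


class TestEffectiveCoherence:
    def test_subtraction(self, rng, grid):
        spec = wavelet_phase_coherence(noise_tfr(rng, grid), noise_tfr(rng, grid))
        thr = np.full(grid.n, 0.2)
        eff = effective_coherence(spec, thr)
        np.testing.assert_allclose(eff.effective, spec.raw - 0.2, atol=1e-12)
        np.testing.assert_array_equal(eff.raw, spec.raw)

    def test_effective_kept_signed(self, rng, grid):
        spec = wavelet_phase_coherence(noise_tfr(rng, grid), noise_tfr(rng, grid))
        eff = effective_coherence(spec, np.ones(grid.n))
        assert np.all(eff.effective[np.isfinite(eff.effective)] <= 0)

    def test_threshold_length_mismatch_rejected(self, rng, grid):
        spec = wavelet_phase_coherence(noise_tfr(rng, grid), noise_tfr(rng, grid))
        with pytest.raises(ValueError):
            effective_coherence(spec, np.zeros(grid.n - 1))
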