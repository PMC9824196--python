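"""Burst/noise/scene generators: amplitudes, spectra, timing statistics."""
import numpy as np
import pytest
import scipy.signal

from gutsound import (
    BurstSpec,
    NoiseSpec,
    SceneConfig,
    ValidationError,
    generate_burst,
    generate_noise,
    generate_scene,
    simulate_raters,
)
from gutsound.motility import compute_ssi


def spectral_centroid(x, rate, above_db=-20.0):
    """Centroid of the Welch spectrum restricted to bins above a peak-relative floor."""
    freqs, psd = scipy.signal.welch(x, fs=rate, nperseg=min(len(x), 2048))
    keep = psd >= psd.max() * 10 ** (above_db / 10)
    return float(np.sum(freqs[keep] * psd[keep]) / np.sum(psd[keep]))


class TestBurst:
    def test_peak_amplitude_is_normalized(self):
        x = generate_burst(BurstSpec(amplitude=0.5), 48_000, seed=0)
        assert np.abs(x).max() == pytest.approx(0.5)

    def test_sample_count_and_centroid(self):
        spec = BurstSpec(duration_ms=100, f_center_hz=400, bandwidth_hz=200)
        x = generate_burst(spec, 48_000, seed=1)
        assert len(x) == 4800
        assert 300.0 <= spectral_centroid(x, 48_000) <= 500.0

    def test_minimum_duration_sample_count(self):
        x = generate_burst(BurstSpec(duration_ms=10, n_peaks=1), 48_000, seed=2)
        assert len(x) == 480

    @pytest.mark.parametrize(
        "kwargs, fieldname",
        [
            (dict(duration_ms=5), "duration_ms"),
            (dict(n_peaks=0), "n_peaks"),
            (dict(f_center_hz=50), "f_center_hz"),
            (dict(f_center_hz=100, bandwidth_hz=150), "bandwidth_hz"),
            (dict(amplitude=0.0), "amplitude"),
            (dict(amplitude=1.5), "amplitude"),
            (dict(decay_rate=-1.0), "decay_rate"),
        ],
    )
    def test_invalid_spec_names_the_field(self, kwargs, fieldname):
        with pytest.raises(ValidationError, match=fieldname):
            BurstSpec(**kwargs)

    def test_band_energy_concentration(self):
        spec = BurstSpec(duration_ms=150, f_center_hz=600, bandwidth_hz=200, n_peaks=4)
        x = generate_burst(spec, 48_000, seed=3)
        freqs, psd = scipy.signal.periodogram(x, fs=48_000)
        strong = psd >= psd.max() * 10 ** (-20 / 10)
        in_band = (freqs >= 400) & (freqs <= 800)
        # energy above -20 dB of the peak concentrates within f_center +/- bw
        assert psd[strong & ~in_band].sum() <= 0.1 * psd[strong].sum()


class TestNoise:
    def test_circuit_rms_matches_level(self):
        x = generate_noise(NoiseSpec("circuit", level_db_rel=-20.0), 1.0, 48_000, seed=0)
        assert len(x) == 48_000
        rms = np.sqrt(np.mean(x**2))
        assert rms == pytest.approx(0.1, rel=0.05)

    def test_biological_periodicity(self):
        x = generate_noise(
            NoiseSpec("biological", level_db_rel=-20.0, period_s=1.0), 5.0, 48_000, seed=1
        )
        ac = scipy.signal.correlate(x, x, mode="full")[len(x) - 1 :]
        lags = np.arange(len(ac)) / 48_000
        search = (lags >= 0.5) & (lags <= 1.5)
        peak_lag = lags[search][np.argmax(ac[search])]
        assert peak_lag == pytest.approx(1.0, abs=0.025)

    def test_background_energy_below_200hz(self):
        x = generate_noise(NoiseSpec("background", level_db_rel=-20.0), 2.0, 48_000, seed=2)
        freqs, psd = scipy.signal.periodogram(x, fs=48_000)
        assert psd[freqs < 200].sum() > 0.5 * psd.sum()

    def test_zero_duration_forbidden(self):
        with pytest.raises(ValidationError):
            generate_noise(NoiseSpec("circuit"), 0.0, 48_000, seed=0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError, match="kind"):
            NoiseSpec("electrical")

    def test_biological_requires_period(self):
        with pytest.raises(ValidationError, match="period_s"):
            NoiseSpec("biological")


class TestScene:
    def test_determinism(self):
        cfg = SceneConfig(duration_s=5.0, ssi_mean_s=0.5, ssi_sd_s=0.2, seed=7)
        clip1, truth1 = generate_scene(cfg)
        clip2, truth2 = generate_scene(cfg)
        assert np.array_equal(clip1.samples, clip2.samples)
        assert truth1.intervals == truth2.intervals

    def test_truth_invariants(self, small_scene):
        _, _, truth = small_scene
        for iv in truth:
            assert iv.duration_s >= 0.010
            assert 0.0 <= iv.start_s and iv.end_s <= truth.clip_duration_s
        for a, b in zip(truth.intervals, truth.intervals[1:]):
            assert b.start_s > a.end_s  # sorted, disjoint

    def test_gap_statistics_converge(self):
        cfg = SceneConfig(duration_s=600.0, ssi_mean_s=2.0, ssi_sd_s=0.5, seed=1)
        _, truth = generate_scene(cfg)
        gaps = np.array(compute_ssi(truth).ssi_list)
        se = 0.5 / np.sqrt(len(gaps))
        assert abs(gaps.mean() - 2.0) <= 3 * se
        assert abs(gaps.mean() - 2.0) <= 0.2

    def test_silence_outside_forced_burst(self):
        cfg = SceneConfig(duration_s=3.0, noise_specs=(), seed=0)
        spec = BurstSpec(duration_ms=200, amplitude=0.8)
        clip, truth = generate_scene(cfg, events=[(1.0, spec)])
        assert len(truth) == 1
        rate = cfg.sample_rate_hz
        assert np.all(clip.samples[: int(1.0 * rate)] == 0.0)
        assert np.all(clip.samples[int(1.2 * rate) + 1 :] == 0.0)
        assert np.abs(clip.samples).max() == pytest.approx(0.8)

    def test_mixing_is_linear(self):
        # the scene equals its bursts-in-silence plus its noise tracks
        events = [(0.5, BurstSpec(amplitude=0.4)), (2.0, BurstSpec(amplitude=0.3))]
        cfg_clean = SceneConfig(duration_s=3.0, noise_specs=(), seed=5)
        clean, _ = generate_scene(cfg_clean, events=events)
        cfg_noisy = SceneConfig(duration_s=3.0, seed=5)
        noisy, _ = generate_scene(cfg_noisy, events=events)
        residual = noisy.samples - clean.samples
        # the residual is exactly the noise floor: no burst energy leaks in
        burst_region = slice(int(0.5 * 48_000), int(0.7 * 48_000))
        noise_rms = np.sqrt(np.mean(residual**2))
        assert np.sqrt(np.mean(residual[burst_region] ** 2)) < 3 * noise_rms

    def test_too_small_ssi_mean_rejected(self):
        with pytest.raises(ValidationError, match="ssi_mean_s"):
            SceneConfig(ssi_mean_s=0.005)


class TestRaters:
    def test_perfect_raters_equal_truth(self, small_scene):
        _, _, truth = small_scene
        tracks = simulate_raters(truth, n_raters=3, seed=0)
        for t in tracks:
            assert t.intervals == truth.intervals

    def test_full_miss_rate_empties_tracks(self, small_scene):
        _, _, truth = small_scene
        for t in simulate_raters(truth, n_raters=3, miss_rate=1.0, seed=0):
            assert len(t) == 0

    def test_retained_counts_within_binomial_interval(self):
        from gutsound import IntervalTrack, LabelInterval
        from scipy.stats import binom

        n_events = 1000
        ivs = tuple(LabelInterval(i * 1.0, i * 1.0 + 0.5) for i in range(n_events))
        truth = IntervalTrack(ivs, clip_duration_s=float(n_events))
        tracks = simulate_raters(truth, n_raters=3, miss_rate=0.3, seed=2)
        lo, hi = binom.ppf([0.005, 0.995], n_events, 0.7)
        for t in tracks:
            assert lo <= len(t) <= hi

    def test_invalid_rates_rejected(self, small_scene):
        _, _, truth = small_scene
        with pytest.raises(ValidationError):
            simulate_raters(truth, n_raters=2, miss_rate=1.5, seed=0)
        with pytest.raises(ValidationError):
            simulate_raters(truth, n_raters=0, seed=0)
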