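"""Generator tests: waveform calibration, trains, missions, tag tracks."""

import math

import numpy as np
import pytest
from scipy import stats

from gliderpam import (
    PRESETS,
    ClickSpec,
    MissionScenario,
    NoiseModel,
    get_preset,
    iter_mission,
    make_click_train,
    make_click_waveform,
    make_tag_track,
    truth_flags,
)
from gliderpam.features import click_spectrum, lf_rolloff, measure_duration, peak_frequency


class TestClickSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ClickSpec("x", -1.0, 1e4, 2e4, 1.5e4, 0.1, 0.01, True)
        with pytest.raises(ValueError):  # upsweep needs f_start < f_end
            ClickSpec("x", 100.0, 5e4, 2e4, 3e4, 0.1, 0.01, True)
        with pytest.raises(ValueError):  # ICI must exceed click duration
            ClickSpec("x", 500.0, 1e4, 2e4, 1.5e4, 0.0001, 0.01, True)
        with pytest.raises(KeyError):
            get_preset("orca")

    def test_band_orientation_free(self):
        assert PRESETS["delphinid"].band_hz[0] < PRESETS["delphinid"].band_hz[1]


class TestClickWaveform:
    def test_nyquist_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_click_waveform(PRESETS["delphinid"], 96_000.0)

    def test_zero_amplitude_is_silence(self, fs):
        x = make_click_waveform(PRESETS["blainville"], fs, amplitude=0.0)
        assert x.size > 0 and not np.any(x)

    @pytest.mark.parametrize("name", ["blainville", "cuvier", "unknown_bw",
                                      "delphinid", "sperm", "echosounder"])
    def test_duration_within_10pct(self, name, fs):
        spec = PRESETS[name]
        x = make_click_waveform(spec, fs)
        d = measure_duration(x, fs, highpass_hz=None)
        assert d == pytest.approx(spec.duration_us, rel=0.10)

    def test_unknown_click_duration_and_peak(self, fs):
        """530 +/- 95 us duration and ~30 kHz spectral peak."""
        x = make_click_waveform(PRESETS["unknown_bw"], fs)
        d = measure_duration(x, fs, highpass_hz=None)
        assert 530 - 95 <= d <= 530 + 95
        f, m = click_spectrum(x, fs)
        assert peak_frequency(f, m) == pytest.approx(30_000.0, abs=3_000.0)

    def test_blainville_rolloff_near_25k(self, fs):
        x = make_click_waveform(PRESETS["blainville"], fs)
        f, m = click_spectrum(x, fs)
        assert lf_rolloff(f, m) == pytest.approx(25_000.0, rel=0.10)

    @pytest.mark.parametrize("name", ["blainville", "cuvier", "unknown_bw", "sperm"])
    def test_band_confinement(self, name, fs):
        """Spectral level >= 40 dB down outside the sweep band (with margin)."""
        spec = PRESETS[name]
        x = make_click_waveform(spec, fs)
        X = np.abs(np.fft.rfft(x, 8192))
        f = np.fft.rfftfreq(8192, 1 / fs)
        lo, hi = spec.band_hz
        outside = ((f < lo - 5_000) | (f > hi + 10_000)) & (f > 300)
        level_db = 20 * np.log10(X[outside].max() / X.max())
        assert level_db <= -40.0


class TestClickTrain:
    def test_unknown_train_ici_statistics(self, fs):
        """ICIs of the 11-click unknown-species train average 0.12 s."""
        means = []
        for seed in range(10):
            _, truth = make_click_train(
                PRESETS["unknown_bw"], 11, 2.2, fs, seed=seed)
            assert len(truth.onsets_s) == 11
            means.append(np.diff(truth.onsets_s).mean())
        assert np.mean(means) == pytest.approx(0.12, abs=0.01)

    def test_single_click_has_empty_ici(self, fs):
        _, truth = make_click_train(PRESETS["blainville"], 1, 1.0, fs, seed=0)
        assert truth.ici_s.size == 0

    def test_fixed_seed_reproducible(self, fs):
        w1, t1 = make_click_train(PRESETS["cuvier"], 4, 2.0, fs, seed=3)
        w2, t2 = make_click_train(PRESETS["cuvier"], 4, 2.0, fs, seed=3)
        assert np.array_equal(w1, w2)
        assert np.array_equal(t1.onsets_s, t2.onsets_s)

    def test_train_too_long_rejected(self, fs):
        with pytest.raises(ValueError, match="cannot fit"):
            make_click_train(PRESETS["sperm"], 20, 2.0, fs, seed=0)

    def test_snr_calibration(self, fs):
        """Clicks are scaled so the band-limited SNR_0-p hits the target
        against the realised noise (checked from the clean scaling)."""
        from scipy import signal as sg
        from gliderpam.synth import band_rms, snr_calibration_band

        wave, truth = make_click_train(
            PRESETS["unknown_bw"], 5, 1.5, fs, seed=11, snr_db=15.0)
        noise_only, _ = make_click_train(
            PRESETS["unknown_bw"], 5, 1.5, fs, seed=11, snr_db=-200.0)
        band = snr_calibration_band(PRESETS["unknown_bw"])
        clean = wave - noise_only  # clicks alone (same seed -> same noise)
        sos = sg.butter(4, band, "bandpass", fs=fs, output="sos")
        peak = np.abs(sg.sosfiltfilt(sos, clean)).max()
        rms = band_rms(noise_only, fs, band)
        measured = 20 * np.log10(peak / rms)
        assert measured == pytest.approx(15.0, abs=1.0)


class TestNoise:
    def test_rms_and_determinism(self, fs):
        from gliderpam import make_noise

        rng = np.random.default_rng(5)
        x = make_noise(100_000, fs, NoiseModel(rms=0.02), rng)
        assert np.sqrt(np.mean(x * x)) == pytest.approx(0.02, rel=1e-9)

    def test_spectral_slope_tilts_spectrum(self, fs):
        from gliderpam import make_noise

        rng = np.random.default_rng(5)
        x = make_noise(200_000, fs, NoiseModel(rms=0.01, slope_db_per_octave=-3.0), rng)
        X = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(len(x), 1 / fs)
        low = X[(f > 5_000) & (f < 10_000)].mean()
        high = X[(f > 40_000) & (f < 80_000)].mean()
        assert low > 2 * high  # pinkish noise emphasises low frequencies


class TestMission:
    def test_all_zero_prevalence_gives_silence_truth(self):
        scen = MissionScenario(
            n_dives=2, files_per_dive=2,
            prevalence={"delphinid": 0.0}, file_duration_s=1.0)
        items = list(iter_mission(scen, seed=0))
        assert len(items) == 4
        for _, _, truth in items:
            assert truth.empty
        flags = truth_flags(
            __import__("pandas").concat([t for _, _, t in items]),
            [m.file_id for m, _, _ in items])
        assert not flags.to_numpy().any()

    def test_prevalence_binomial(self):
        """Class presence count over 200 files stays within 3 binomial SDs
        (and the 3-SD band itself is checked against the exact CDF)."""
        p, n = 0.5, 200
        scen = MissionScenario(
            n_dives=10, files_per_dive=20,
            prevalence={"delphinid": p}, file_duration_s=2.5,
            clicks_range=(4, 6))
        import pandas as pd
        counts = 0
        truths = []
        for meta, _, truth in iter_mission(scen, seed=5):
            truths.append(truth)
            counts += int(not truth.empty)
        sd = np.sqrt(n * p * (1 - p))
        lo, hi = n * p - 3 * sd, n * p + 3 * sd
        # exact binomial check that [lo, hi] holds >= 99 % of the mass
        assert stats.binom.cdf(hi, n, p) - stats.binom.cdf(lo - 1, n, p) > 0.99
        assert lo <= counts <= hi

    def test_nyquist_validation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            MissionScenario(1, 1, {"delphinid": 0.1}, sample_rate_hz=100_000.0)

    def test_bad_prevalence(self):
        with pytest.raises(ValueError):
            MissionScenario(1, 1, {"delphinid": 1.5})

    def test_diel_profile_recovered_from_truth(self):
        """A diel prevalence profile peaking at 22:00 local is recovered
        (argmax within an hour) from the generated truth flags."""
        import pandas as pd
        from gliderpam import diel_profile

        mult = [0.0] * 24
        for h in range(24):
            # raised-cosine bump centred on 22:00 local, peak multiplier 2.0
            d = min((h - 22) % 24, (22 - h) % 24)
            mult[h] = 2.0 * max(0.0, math.cos(math.pi * d / 8.0)) if d < 4 else 0.1
        scen = MissionScenario(
            n_dives=55, files_per_dive=15,
            prevalence={"delphinid": 0.5},
            diel_profile={"delphinid": mult},
            file_duration_s=1.2, file_stride_s=60.0,
            clicks_range=(3, 4), surface_gap_min=16.2,
        )
        items = list(iter_mission(scen, seed=12))
        rows = []
        for meta, _, truth in items:
            rows.append({"file_id": meta.file_id, "dive_id": meta.dive_id,
                         "start_utc": meta.start_utc,
                         "delphinid": not truth.empty})
        flags = pd.DataFrame(rows)
        prof = diel_profile(flags, "delphinid", utc_offset_h=-10.0)
        peak_hour = int(prof.loc[prof["percentage"].idxmax(), "hour"])
        assert min((peak_hour - 22) % 24, (22 - peak_hour) % 24) <= 1

    def test_file_schedule_scale(self):
        """85 dives x ~137 files reproduces the survey's file-count scale."""
        scen = MissionScenario(85, 137, {"delphinid": 0.0})
        assert scen.n_files == 11_645  # ~11,615 one-minute files


class TestTagTrack:
    def test_zero_error_fixes_on_true_track(self):
        fixes, track = make_tag_track(2, seed=1, argos_error_km=0.0)
        for _, fix in fixes.iterrows():
            i = (track["time"] - fix["time"]).abs().idxmin()
            assert track.loc[i, "depth_m"] == 0.0
            assert abs(track.loc[i, "lat"] - fix["lat"]) < 1e-6

    def test_fix_spacing_is_dive_cycle(self):
        params = {"deep_dive_duration_s": 3000.0, "surface_duration_s": 200.0}
        fixes, _ = make_tag_track(3, dive_params=params, seed=0)
        dt = fixes["time"].diff().dropna().dt.total_seconds()
        assert np.allclose(dt, 3200.0)

    def test_deep_dives_only_profile(self):
        _, track = make_tag_track(3, seed=0)
        # u-shaped: reaches deep depths and returns to surface between dives
        assert track["depth_m"].max() > 500.0
        assert (track["depth_m"] == 0.0).sum() >= 4
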