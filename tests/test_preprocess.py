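"""Cleaning chain: referencing, filtering, line removal, bad channels,
spherical-spline interpolation, epoching, rejection, resampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from emoload.preprocess import (average_rereference, bandpass,
                                detect_bad_channels, epoch,
                                reject_epochs_amplitude, remove_channel_mean,
                                remove_line_noise, resample,
                                spherical_spline_interpolate)
from emoload.synth import generate_epochs, pink_noise

SRATE = 256.0


class TestReferencing:
    def test_balanced_pair_unchanged(self):
        x = np.array([[1.0, 1.0, 1.0], [-1.0, -1.0, -1.0]])
        assert np.allclose(average_rereference(x), x)

    def test_common_offset_removed(self):
        x = np.full((4, 100), 5.0)
        assert np.allclose(average_rereference(x), 0.0)

    def test_column_means_zero(self, rng):
        x = rng.standard_normal((16, 500))
        out = average_rereference(x)
        assert np.abs(out.mean(axis=0)).max() < 1e-9

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="two channels"):
            average_rereference(np.ones((1, 10)))

    def test_idempotent(self, rng):
        x = rng.standard_normal((8, 200))
        once = average_rereference(x)
        assert np.allclose(average_rereference(once), once, atol=1e-9)

    def test_channel_mean_removal(self, rng):
        x = rng.standard_normal((8, 200)) + rng.normal(0, 5, (8, 1))
        out = remove_channel_mean(x)
        assert np.abs(out.mean(axis=-1)).max() < 1e-9
        assert np.allclose(remove_channel_mean(out), out, atol=1e-9)


class TestBandpass:
    def test_passband_probe(self):
        t = np.arange(int(SRATE * 30)) / SRATE
        x = np.sin(2 * np.pi * 10 * t)[None]
        y = bandpass(x, SRATE)[0]
        core = slice(len(t) // 4, -len(t) // 4)
        design = np.column_stack([np.sin(2 * np.pi * 10 * t[core]),
                                  np.cos(2 * np.pi * 10 * t[core])])
        coef, *_ = np.linalg.lstsq(design, y[core], rcond=None)
        gain_db = 20 * np.log10(np.hypot(*coef))
        assert abs(gain_db) < 1.0

    def test_drift_attenuated(self):
        t = np.arange(int(SRATE * 60)) / SRATE
        x = np.sin(2 * np.pi * 0.01 * t)[None]
        y = bandpass(x, SRATE)[0]
        att_db = 20 * np.log10(np.abs(y).max() / 1.0)
        assert att_db < -20

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros((2, 1000)), SRATE), 0.0)

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            bandpass(np.zeros((2, 100)), SRATE, lo=50, hi=10)

    def test_nyquist_clipping(self, caplog):
        # 200 Hz recording: the 100 Hz edge is clipped to 95 Hz, 10 Hz survives
        t = np.arange(int(200.0 * 8)) / 200.0
        x = np.sin(2 * np.pi * 10 * t)[None]
        import logging

        with caplog.at_level(logging.WARNING, logger="emoload.preprocess"):
            y = bandpass(x, 200.0)[0]
        assert any("clipping" in r.message for r in caplog.records)
        core = slice(len(t) // 4, -len(t) // 4)
        assert abs(20 * np.log10(np.abs(y[core]).max())) < 1.0


class TestLineNoise:
    def _line_db(self, x, srate=SRATE):
        f, pxx = signal.periodogram(x, fs=srate)
        band = (f >= 59) & (f <= 61)
        return 10 * np.log10(pxx[band].sum())

    def test_stationary_line_removed(self, rng):
        n = int(SRATE * 20)
        t = np.arange(n) / SRATE
        clean = pink_noise((1, n), SRATE, rng)[0]
        x = clean + 20 * np.sin(2 * np.pi * 60 * t)
        y = remove_line_noise(x[None], SRATE)[0]
        assert self._line_db(x) - self._line_db(y) >= 20

    def test_broadband_untouched(self, rng):
        n = int(SRATE * 20)
        x = pink_noise((1, n), SRATE, rng)[0]
        y = remove_line_noise(x[None], SRATE)[0]
        f, pxx_x = signal.welch(x, fs=SRATE, nperseg=1024)
        _, pxx_y = signal.welch(y, fs=SRATE, nperseg=1024)
        keep = (f > 2) & ((f < 58) | (f > 62)) & (f < 118)
        diff_db = np.abs(10 * np.log10(pxx_y[keep] / pxx_x[keep]))
        assert np.median(diff_db) < 1.0

    def test_drifting_line_tracked(self, rng):
        n = int(SRATE * 20)
        t = np.arange(n) / SRATE
        amp = 10 * (1 + 0.5 * np.sin(2 * np.pi * 0.05 * t))
        line = amp * np.sin(2 * np.pi * 60 * t)
        x = pink_noise((1, n), SRATE, rng)[0] + line
        y = remove_line_noise(x[None], SRATE)[0]
        resid = y - (x - line)
        assert np.sqrt((resid ** 2).mean()) < 0.1 * np.sqrt((line ** 2).mean())


class TestBadChannels:
    def _clean(self, rng, n_ch=16, secs=20):
        return pink_noise((n_ch, int(SRATE * secs)), SRATE, rng)

    def test_flatline_flagged(self, rng):
        x = self._clean(rng)
        x[3, 1000:1000 + int(6 * SRATE)] = 1.234
        out = detect_bad_channels(x, SRATE)
        assert "flatline" in out.get(3, [])

    def test_line_contamination_flagged(self, rng):
        x = self._clean(rng, n_ch=32)
        t = np.arange(x.shape[1]) / SRATE
        x[7] += 200 * np.sin(2 * np.pi * 60 * t)
        out = detect_bad_channels(x, SRATE)
        assert "line_noise" in out.get(7, [])

    def test_homogeneous_channels_clean(self, rng):
        assert detect_bad_channels(self._clean(rng), SRATE) == {}

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="8 channels"):
            detect_bad_channels(self._clean(rng, n_ch=4), SRATE)

    def test_all_bad_rejected(self):
        x = np.ones((8, int(SRATE * 10)))
        with pytest.raises(ValueError, match="unusable"):
            detect_bad_channels(x, SRATE)


class TestSplineInterpolation:
    def test_constant_field_reproduced(self, low32):
        x = np.full((32, 50), 7.5)
        out = spherical_spline_interpolate(x, low32, ["Cz"])
        assert np.allclose(out[low32.index("Cz")], 7.5, atol=1e-6)

    def test_smooth_dipolar_field_recovered(self, low32):
        # potential of a deep tangential dipole (smooth scalp topography)
        dip_pos = np.array([0.0, 0.3, 0.8])
        dip_mom = np.array([1.0, 0.5, 0.2])
        rel = low32.positions - 0.4 * dip_pos / np.linalg.norm(dip_pos)
        v = (rel @ dip_mom) / np.linalg.norm(rel, axis=1) ** 3
        field = np.tile(v[:, None], (1, 20))
        for bad in ("Cz", "C3", "Pz"):
            idx = low32.index(bad)
            out = spherical_spline_interpolate(field, low32, [bad])
            rel_err = abs(out[idx, 0] - v[idx]) / np.std(v)
            assert rel_err < 0.3, bad
        # correlation of reconstruction across all leave-one-out channels
        recon = np.array([
            spherical_spline_interpolate(field, low32, [lab])[low32.index(lab), 0]
            for lab in low32.labels])
        assert np.corrcoef(recon, v)[0, 1] > 0.95

    def test_zero_field_zero_interp(self, low32):
        out = spherical_spline_interpolate(np.zeros((32, 10)), low32, ["Pz"])
        assert np.allclose(out, 0.0)

    def test_good_channels_untouched(self, low32, rng):
        x = rng.standard_normal((32, 30))
        out = spherical_spline_interpolate(x, low32, ["Oz"])
        good = [i for i in range(32) if i != low32.index("Oz")]
        assert np.array_equal(out[good], x[good])

    def test_all_bad_rejected(self, low32):
        with pytest.raises(ValueError):
            spherical_spline_interpolate(np.ones((32, 5)), low32,
                                         list(low32.labels))


class TestEpoching:
    def _recording(self, rng, secs=40, n_ch=4):
        return pink_noise((n_ch, int(SRATE * secs)), SRATE, rng)

    def test_all_events_epoched(self, rng):
        data = self._recording(rng, secs=480)
        onsets = 2.0 + np.arange(144) * 3.11
        events = pd.DataFrame({"onset_s": onsets,
                               "emotion": ["anger"] * 144,
                               "load": ["MOT4"] * 144})
        eps = epoch(data, events, SRATE)
        assert eps.n_epochs == 144
        assert eps.data.shape[-1] == 797

    def test_edge_event_dropped(self, rng):
        data = self._recording(rng, secs=10)
        events = pd.DataFrame({"onset_s": [0.5, 5.0],
                               "emotion": ["fear", "anger"],
                               "load": ["MOT4"] * 2})
        eps = epoch(data, events, SRATE)
        assert eps.n_epochs == 1 and eps.emotions[0] == "anger"

    def test_empty_events_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            epoch(self._recording(rng), pd.DataFrame(columns=["onset_s", "emotion"]),
                  SRATE)


class TestRejection:
    def test_clean_set_untouched(self, low32):
        ep = generate_epochs(low32.subset(("Cz", "Pz")), n_epochs_per_cell=2, seed=0)
        kept, report = reject_epochs_amplitude(ep)
        assert report.n_epochs_kept == report.n_epochs_in == ep.n_epochs

    def test_spike_epoch_removed(self, low32):
        ep = generate_epochs(low32.subset(("Cz", "Pz")), n_epochs_per_cell=2, seed=0)
        ep.data[5, 0, 100] = 500.0
        kept, report = reject_epochs_amplitude(ep)
        assert report.n_epochs_kept == ep.n_epochs - 1
        assert kept.emotions[5] != ep.emotions[5] or ep.n_epochs - 1 == 5

    def test_infinite_threshold_identity(self, low32):
        ep = generate_epochs(low32.subset(("Cz", "Pz")), n_epochs_per_cell=2, seed=0)
        ep.data[0, 0, 0] = 400.0
        kept, _ = reject_epochs_amplitude(ep, threshold_uv=np.inf)
        assert kept.n_epochs == ep.n_epochs


class TestResample:
    def _tone_epochs(self, srate, freq=10.0, secs=3.0, n_ep=3):
        from emoload.synth import EpochSet

        t = np.arange(int(secs * srate)) / srate - 1.0
        x = np.sin(2 * np.pi * freq * t)
        data = np.tile(x, (n_ep, 2, 1))
        return EpochSet(data, t, srate, ("Cz", "Pz"),
                        np.array(["anger"] * n_ep, dtype=object), "MOT4")

    def test_tone_preserved(self):
        ep = self._tone_epochs(500.0)
        out = resample(ep, 256.0)
        # sinusoid-fit oracle: amplitude and frequency by least squares
        t = out.times
        core = (t > -0.6) & (t < 1.4)

        def fit(freq):
            design = np.column_stack([np.sin(2 * np.pi * freq * t[core]),
                                      np.cos(2 * np.pi * freq * t[core])])
            coef, res, *_ = np.linalg.lstsq(design, out.data[0, 0, core], rcond=None)
            return np.hypot(*coef), res[0] if len(res) else 0.0

        amp, _ = fit(10.0)
        assert abs(amp - 1.0) < 0.01
        # frequency error < 0.05 Hz: fit residual minimized at 10 Hz
        freqs = np.arange(9.8, 10.21, 0.05)
        resids = [fit(f)[1] for f in freqs]
        assert abs(freqs[int(np.argmin(resids))] - 10.0) < 0.05

    def test_identity_at_same_rate(self, low32):
        ep = generate_epochs(low32.subset(("Cz", "Pz")), n_epochs_per_cell=1, seed=0)
        assert resample(ep, 256.0) is ep

    def test_sample_count(self):
        ep = self._tone_epochs(500.0)
        out = resample(ep, 256.0)
        expected = round(ep.data.shape[-1] * 256 / 500)
        assert abs(out.data.shape[-1] - expected) <= 1

    def test_upsampling_rejected(self):
        ep = self._tone_epochs(200.0)
        with pytest.raises(ValueError, match="[Uu]psampling"):
            resample(ep, 256.0)
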