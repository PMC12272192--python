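"""Band-pass filtering, epoching, artifact screening, and the Hilbert TFA."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from apnoea_eeg.eeg import (
    CENTRE_FREQS,
    LOG_FLOOR,
    bandpass_eeg,
    change_map,
    epoch_eeg,
    reject_epochs,
    tfa,
    tfa_window,
)

FS = 250.0


def bp_gain_analytic(f, lo=0.1, hi=30.0, order=2, passes=2):
    """filtfilt magnitude of an analytic Butterworth band-pass (lowpass
    prototype of given order mapped with the standard s -> (s^2+w0^2)/(B s))."""
    w, w1, w2 = 2 * np.pi * f, 2 * np.pi * lo, 2 * np.pi * hi
    w0sq, B = w1 * w2, w2 - w1
    x = (w * w - w0sq) / (B * w)
    h2 = 1.0 / (1.0 + x ** (2 * order))  # squared single-pass magnitude
    return h2 ** (passes / 2.0)


def tone(f, dur_s=30.0, fs=FS):
    t = np.arange(int(dur_s * fs)) / fs
    return np.sin(2 * np.pi * f * t)


class TestBandpass:
    def test_50hz_attenuated_at_least_analytic(self):
        # long tone: the 0.1 Hz corner's zero-phase transient rings for tens
        # of seconds, so steady state is measured deep in the interior
        y = bandpass_eeg(tone(50.0, 200.0), FS)
        interior = np.abs(y[int(60 * FS) : int(140 * FS)]).max()
        assert interior <= bp_gain_analytic(50.0) * 1.10

    def test_10hz_passed(self):
        y = bandpass_eeg(tone(10.0, 200.0), FS)
        interior = np.abs(y[int(60 * FS) : int(140 * FS)]).max()
        assert interior == pytest.approx(1.0, abs=0.05)

    def test_zero_phase(self):
        x = tone(5.0, 60.0)
        y = bandpass_eeg(x, FS)
        xc = sp_signal.correlate(y, x, mode="full")
        lag = np.argmax(xc) - (x.size - 1)
        assert lag == 0

    def test_nonfinite_rejected(self):
        x = tone(5.0)
        x[10] = np.inf
        with pytest.raises(ValueError):
            bandpass_eeg(x, FS)


class TestEpoching:
    def test_full_window_extracted(self):
        eeg = np.zeros((int(1000 * FS), 2))
        epochs, kept = epoch_eeg(eeg, FS, [100.0], (-90.0, 150.0))
        assert kept == [0]
        assert epochs[0].shape == (int(240 * FS), 2)

    def test_event_near_edge_dropped(self):
        eeg = np.zeros((int(1000 * FS), 2))
        _, kept = epoch_eeg(eeg, FS, [50.0], (-90.0, 150.0))
        assert kept == []

    def test_order_preserved(self):
        eeg = np.zeros((int(1000 * FS), 1))
        _, kept = epoch_eeg(eeg, FS, [200.0, 400.0], (-90.0, 90.0))
        assert kept == [0, 1]


class TestRejectEpochs:
    def test_under_limit_kept(self):
        ep = np.full((100, 3), 499.0)
        assert reject_epochs([ep]).all()

    def test_single_channel_rejected(self):
        ep = np.zeros((100, 3))
        ep[50, 0] = 501.0
        mask = reject_epochs([ep])
        assert not mask[0, 0] and mask[0, 1] and mask[0, 2]

    def test_all_channels_exceed(self):
        ep = np.full((100, 3), 600.0)
        assert not reject_epochs([ep]).any()


class TestTFA:
    def test_unit_tone_envelope(self):
        a = tfa(tone(10.5, 60.0), FS)
        fi = int(np.argmin(np.abs(CENTRE_FREQS - 10.5)))
        interior = a[int(5 * FS) : int(55 * FS), fi, 0]
        assert np.abs(interior).max() < 0.02
        far = a[int(5 * FS) : int(55 * FS), np.abs(CENTRE_FREQS - 10.5) >= 3, 0]
        assert far.max() <= -1.0

    def test_zero_signal_floored(self):
        a = tfa(np.zeros(int(20 * FS)), FS)
        assert np.allclose(a, np.log10(LOG_FLOOR))

    def test_amplitude_step_recovers_log2(self):
        x = tone(10.5, 60.0)
        x[int(30 * FS) :] *= 0.5
        a = tfa(x, FS)
        fi = int(np.argmin(np.abs(CENTRE_FREQS - 10.5)))
        before = a[int(20 * FS) : int(28 * FS), fi, 0].mean()
        after = a[int(32 * FS) : int(40 * FS), fi, 0].mean()
        assert before - after == pytest.approx(np.log10(2), abs=0.02)

    @pytest.mark.parametrize("c", [0.1, 3.0])
    def test_scaling_adds_log10_c(self, c, rng):
        x = rng.standard_normal(int(20 * FS))
        a1 = tfa(x, FS)
        a2 = tfa(c * x, FS)
        # away from the floor, TFA(c*x) = TFA(x) + log10(c)
        ok = a1 > np.log10(LOG_FLOOR) + 1
        assert np.allclose(a2[ok] - a1[ok], np.log10(c), atol=1e-9)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            tfa(np.zeros(int(5 * FS)), FS)

    def test_matches_stft_bin_on_am_tone(self):
        """Hilbert envelope agrees with the short-time Fourier magnitude at
        the matching bin within 5% (interior) on a narrowband AM signal."""
        n = int(120 * FS)
        t = np.arange(n) / FS
        env_true = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        x = env_true * np.sin(2 * np.pi * 10.5 * t)
        a = tfa(x, FS)
        fi = int(np.argmin(np.abs(CENTRE_FREQS - 10.5)))
        env = 10 ** a[:, fi, 0]
        nper = int(2 * FS)  # 0.5 Hz bins: the AM sidebands stay in the main lobe
        f, tt, Z = sp_signal.stft(x, fs=FS, nperseg=nper, noverlap=nper // 2, window="hann")
        bi = int(np.argmin(np.abs(f - 10.5)))
        stft_amp = 2 * np.abs(Z[bi])
        idx = (tt > 20) & (tt < 100)
        env_t = np.interp(tt[idx], t, env)
        assert env_t.mean() / stft_amp[idx].mean() == pytest.approx(1.0, abs=0.05)
        assert np.corrcoef(env_t, stft_amp[idx])[0, 1] > 0.98

    def test_band_power_matches_welch_oracle(self, rng):
        """On white noise, mean squared envelope equals twice the input PSD
        integrated over the band filter's squared zero-phase response."""
        n = int(200 * FS)
        x = rng.standard_normal(n)
        a = tfa(x, FS, centre_freqs=np.array([10.5]))
        env2 = (10 ** a[int(10 * FS) : int(190 * FS), 0, 0]) ** 2
        f, S = sp_signal.welch(x, fs=FS, nperseg=int(8 * FS))
        sos = sp_signal.butter(2, [9.5, 11.5], btype="bandpass", fs=FS, output="sos")
        w, h = sp_signal.sosfreqz(sos, worN=f, fs=FS)
        band_power = np.trapezoid(S * np.abs(h) ** 4, f)  # |H|^4: filtfilt
        assert env2.mean() / (2 * band_power) == pytest.approx(1.0, abs=0.05)


class TestChangeMap:
    def test_identical_segments_zero(self, rng):
        seg = rng.standard_normal((100, 29, 9))
        assert np.allclose(change_map(seg, seg), 0.0)

    def test_log_arithmetic(self, rng):
        base = rng.standard_normal((100, 29, 9))
        ev = base - 0.2
        assert np.allclose(change_map(ev, base), -0.2)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            change_map(np.zeros((10, 29, 9)), np.zeros((11, 29, 9)))

    def test_time_averaged_baseline_switch(self, rng):
        base = np.tile(rng.standard_normal((1, 4, 2)), (50, 1, 1))
        ev = base + 0.3
        out = change_map(ev, base, time_average_baseline=True)
        assert np.allclose(out, 0.3)


def test_tfa_window_slices_interior(rng):
    x = tone(10.5, 120.0)
    seg = tfa_window(x, FS, 50.0, 60.0)
    assert seg.shape[0] == int(10 * FS)
    fi = int(np.argmin(np.abs(CENTRE_FREQS - 10.5)))
    assert np.abs(seg[:, fi, 0]).max() < 0.02
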