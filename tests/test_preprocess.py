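"""Filters and BSS-CCA: frequency responses, identities, source properties."""

import numpy as np
import pytest

from eegtrp import CcaSpec, Recording, bss_cca_denoise, default_montage, \
    fir_bandpass, highpass_dc_remove
from eegtrp.montage import ELECTRODES
from eegtrp.preprocess import cca_window_sources, design_fir_bandpass, \
    filter_array, highpass_array

FS = 128.0


def _recording(x):
    return Recording(np.broadcast_to(x, (14, x.size)).copy(), FS, ELECTRODES)


def _sine(freq, dur=30.0, amp=1.0):
    t = np.arange(int(dur * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestHighpass:
    def test_dc_offset_attenuated(self):
        rec = _recording(np.full(int(60 * FS), 4200.0))
        out = highpass_dc_remove(rec)
        tail = out.samples[0, -int(10 * FS):]
        assert abs(tail.mean()) < 1.0

    def test_zero_in_zero_out(self):
        out = highpass_dc_remove(_recording(np.zeros(1280)))
        assert not out.samples.any()

    def test_10hz_passband_gain(self):
        # |H| = f / sqrt(f^2 + fc^2): at 10 Hz with fc=0.16, gain ~ 0.99987
        out = highpass_dc_remove(_recording(_sine(10.0, dur=60.0)))
        steady = out.samples[0, int(10 * FS):]
        amp = np.max(np.abs(steady))
        assert amp == pytest.approx(1.0, rel=1e-3)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            highpass_dc_remove(_recording(np.zeros(256)), fc=0.0)


class TestFirBandpass:
    def test_passband_sine_preserved(self):
        out = fir_bandpass(_recording(_sine(10.0)))
        mid = out.samples[0, int(5 * FS):-int(5 * FS)]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.02)

    def test_stopband_sine_suppressed(self):
        out = fir_bandpass(_recording(_sine(1.0)))
        rms_out = np.sqrt(np.mean(out.samples[0] ** 2))
        rms_in = 1.0 / np.sqrt(2)
        assert rms_out <= 0.1 * rms_in

    def test_taps_symmetric_linear_phase(self):
        taps = design_fir_bandpass(4.0, 45.0, FS)
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-15)
        assert len(taps) % 2 == 1

    def test_stopband_attenuation_beyond_transition(self):
        from scipy.signal import freqz
        spec_taps = design_fir_bandpass(4.0, 45.0, FS)
        w, h = freqz(spec_taps, worN=8192, fs=FS)
        tr = 2.0  # low-edge transition width, Hz
        stop = (w > 0.1) & (w < 4.0 - tr)
        assert np.max(20 * np.log10(np.abs(h[stop]) + 1e-12)) <= -20.0

    def test_output_length_and_delay_compensation(self):
        x = _sine(10.0, dur=10.0)
        taps = design_fir_bandpass(4.0, 45.0, FS)
        y = filter_array(x, taps)[0]
        assert y.size == x.size
        # zero-phase: peak alignment with the input (no group delay)
        mid = slice(int(2 * FS), int(8 * FS))
        lagless = np.corrcoef(x[mid], y[mid])[0, 1]
        assert lagless > 0.999

    def test_too_short_signal_rejected(self):
        taps = design_fir_bandpass(4.0, 45.0, FS)
        with pytest.raises(ValueError):
            filter_array(np.zeros(len(taps) - 10), taps)

    def test_channel_permutation_commutes(self, rng):
        x = rng.normal(size=(14, 2000))
        taps = design_fir_bandpass(4.0, 45.0, FS)
        perm = rng.permutation(14)
        np.testing.assert_allclose(filter_array(x, taps)[perm],
                                   filter_array(x[perm], taps), atol=1e-12)


class TestBssCca:
    def _structured_recording(self, rng, dur=20.0):
        from eegtrp.simulate import synth_band_oscillation
        n = int(dur * FS)
        src = synth_band_oscillation("alpha", dur, FS, 10.0,
                                     seed=int(rng.integers(2 ** 31)))
        weights = rng.uniform(0.8, 1.2, 14)
        x = np.outer(weights, src) + rng.normal(0, 2.0, (14, n))
        return Recording(x, FS, ELECTRODES)

    def test_k_zero_is_identity(self, rng):
        rec = self._structured_recording(rng)
        out = bss_cca_denoise(rec, CcaSpec(k_remove=0))
        np.testing.assert_allclose(out.samples, rec.samples, atol=1e-9)

    def test_sources_mutually_uncorrelated(self, rng):
        # uncorrelated about the window mean: the leading-sample second
        # moment of the sources is the identity by construction
        rec = self._structured_recording(rng, dur=3.0)
        win = rec.samples[:, :int(2.5 * FS)]
        win = win - win.mean(axis=1, keepdims=True)
        sources, _mix, _rho = cca_window_sources(win)
        s1 = sources[:, :-1]
        c = s1 @ s1.T / s1.shape[1]
        c = c / np.sqrt(np.outer(np.diag(c), np.diag(c)))
        off = c - np.diag(np.diag(c))
        assert np.max(np.abs(off)) < 1e-6

    def test_autocorrelation_ordering(self, rng):
        rec = self._structured_recording(rng, dur=3.0)
        win = rec.samples[:, :int(2.5 * FS)]
        win = win - win.mean(axis=1, keepdims=True)
        sources, _mix, rho = cca_window_sources(win)
        assert np.all(np.diff(rho) <= 1e-12)
        # eigenvalues equal the sources' empirical lag-1 autocovariance
        for i in range(sources.shape[0]):
            s = sources[i]
            emp = np.mean(s[:-1] * s[1:])
            assert emp == pytest.approx(rho[i], abs=1e-9)
        # the removed set (lowest k) therefore has the k smallest
        k = 4
        removed = rho[-k:]
        assert np.max(removed) <= np.min(rho[:-k]) + 1e-12

    def test_reconstruction_exact_with_all_sources(self, rng):
        rec = self._structured_recording(rng, dur=3.0)
        win = rec.samples[:, :int(2.5 * FS)]
        winc = win - win.mean(axis=1, keepdims=True)
        sources, mixing, _ = cca_window_sources(winc)
        np.testing.assert_allclose(mixing @ sources, winc, atol=1e-8)

    def test_burst_removed_alpha_preserved(self, rng):
        from eegtrp.preprocess import design_fir_bandpass, filter_array
        from eegtrp.simulate import inject_artifacts
        raw = self._structured_recording(rng, dur=20.0)
        dirty, log = inject_artifacts(
            raw, ["emg_burst"],
            {"emg_burst": {"n": 1, "duration_s": 1.0, "rms_uV": 30.0,
                           "channels": ["T7", "FC5"]}}, seed=3)
        ev = log[0]
        i0 = int(ev.onset_s * FS)
        sl = slice(i0, i0 + int(ev.duration_s * FS))
        # pipeline stage order: broadband filter precedes BSS-CCA
        rec = fir_bandpass(raw)
        dirty = fir_bandpass(dirty)
        clean = bss_cca_denoise(dirty, CcaSpec())
        taps_b = design_fir_bandpass(20, 45, FS)
        e_added = np.sum(filter_array(dirty.samples - rec.samples,
                                      taps_b)[:, sl] ** 2)
        e_resid = np.sum(filter_array(clean.samples - rec.samples,
                                      taps_b)[:, sl] ** 2)
        assert e_resid <= 0.5 * e_added
        # alpha power outside the burst neighbourhood barely moves
        taps_a = design_fir_bandpass(8, 12, FS)
        outside = np.ones(rec.n_samples, bool)
        outside[max(0, i0 - int(FS)):i0 + int(2 * FS)] = False
        pa_clean = np.mean(filter_array(clean.samples, taps_a)[:, outside] ** 2)
        pa_orig = np.mean(filter_array(rec.samples, taps_a)[:, outside] ** 2)
        assert pa_clean == pytest.approx(pa_orig, rel=0.10)

    def test_no_seam_discontinuities(self, rng):
        # smooth input: band-limited oscillations plus steep-spectrum noise,
        # broadband-filtered as in the pipeline; window seams must not add
        # jumps beyond the signal's own sample-to-sample variation
        from eegtrp.simulate import pink_noise, synth_band_oscillation
        dur = 12.0
        n = int(dur * FS)
        x = np.empty((14, n))
        for c in range(14):
            x[c] = (synth_band_oscillation("alpha", dur, FS, 10.0, seed=100 + c)
                    + synth_band_oscillation("theta", dur, FS, 8.0, seed=200 + c)
                    + pink_noise(n, FS, 2.0, 1.5, rng))
        rec = fir_bandpass(Recording(x, FS, ELECTRODES))
        out = bss_cca_denoise(rec, CcaSpec()).samples
        jumps = np.abs(np.diff(out, axis=1))
        shift = int(round(1.2 * FS))
        seam_cols = np.arange(shift - 1, out.shape[1] - 1, shift)
        seam_max = jumps[:, seam_cols].max()
        assert seam_max <= 5 * np.median(jumps)

    def test_k_remove_too_large_rejected(self, rng):
        rec = self._structured_recording(rng, dur=5.0)
        with pytest.raises(ValueError):
            bss_cca_denoise(rec, CcaSpec(k_remove=14))
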