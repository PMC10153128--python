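"""LFP conditioning, CSD, layer alignment/partition, and av-rec."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminar_oddball import (
    AnalysisConfig,
    EpochTensor,
    ProbeGeometry,
    Recording,
    ValidationError,
    avrec,
    align_layer4,
    compute_csd,
    epoch,
    layer_partition,
    lowpass_lfp,
)
from laminar_oddball.laminar import _depth_kernel, bin_means
from laminar_oddball.synth import dipole_profile, profile_to_voltage

from conftest import random_recording


def _sine_recording(freq, fs=10000.0, dur=2.0, n_contacts=16):
    t = np.arange(int(dur * fs)) / fs
    sig = np.tile(np.sin(2 * np.pi * freq * t), (n_contacts, 1))
    return Recording(signal=sig, fs=fs,
                     geometry=ProbeGeometry(n_contacts=n_contacts))


class TestLowpass:
    def test_passband_preserved(self):
        out = lowpass_lfp(_sine_recording(10.0))
        mid = out.signal[0, 5000:15000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated_40db(self):
        out = lowpass_lfp(_sine_recording(500.0))
        mid = out.signal[0, 5000:15000]
        assert np.abs(mid).max() < 10 ** (-40 / 20)

    def test_white_noise_spectrum_matches_design(self, rng):
        """Periodogram of filtered white noise follows the squared magnitude
        response of the zero-phase design within Monte-Carlo tolerance."""
        import scipy.signal

        rec = random_recording(rng, n_contacts=4, n_samples=200000)
        out = lowpass_lfp(rec)
        f, pxx = scipy.signal.welch(out.signal, fs=rec.fs, nperseg=4096, axis=1)
        sos = scipy.signal.ellip(7, 0.01, 60.0, 110.0, btype="low", fs=rec.fs,
                                 output="sos")
        _, h = scipy.signal.sosfreqz(sos, worN=f, fs=rec.fs)
        # unit-variance white input: one-sided PSD 2/fs, shaped by |H|^4
        expected = np.abs(h) ** 4 * 2.0 / rec.fs
        sel = (f > 5) & (f < 130)
        ratio = pxx.mean(axis=0)[sel] / expected[sel]
        assert np.median(np.abs(np.log(ratio))) < 0.15

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            lowpass_lfp(_sine_recording(10.0, fs=200.0), cutoff_hz=110.0)


class TestEpoch:
    def test_shapes_and_time_axis(self, rng):
        rec = random_recording(rng, n_samples=40000)
        onsets = np.array([5000, 15000, 25000])
        ep = epoch(rec, onsets, (-250.0, 750.0))
        assert ep.data.shape == (3, 16, 10000)
        assert ep.time_ms[0] == -250.0 and ep.time_ms[-1] < 750.0

    def test_out_of_bounds_trials_listed(self, rng):
        rec = random_recording(rng, n_samples=20000)
        with pytest.raises(ValidationError, match=r"\[0\]"):
            epoch(rec, np.array([0, 10000]), (-250.0, 750.0))

    def test_constant_signal_gives_identical_epochs(self, geometry):
        rec = Recording(signal=np.full((16, 30000), 3.5), fs=10000.0,
                        geometry=geometry)
        ep = epoch(rec, np.array([5000, 15000]), (-100.0, 100.0))
        np.testing.assert_array_equal(ep.data[0], ep.data[1])


def _csd_loop_oracle(v, pitch, kernel, boundary):
    """Independent explicit-loop finite difference + depth convolution."""
    n_tr, n_ch, n_t = v.shape
    if boundary == "vaknin":
        vv = np.empty((n_tr, n_ch + 2, n_t))
        vv[:, 0] = v[:, 0]
        vv[:, -1] = v[:, -1]
        vv[:, 1:-1] = v
    else:
        vv = v
    out = np.empty((n_tr, vv.shape[1] - 2, n_t))
    for tr in range(n_tr):
        for k in range(1, vv.shape[1] - 1):
            out[tr, k - 1] = -(vv[tr, k - 1] - 2 * vv[tr, k] + vv[tr, k + 1]) / pitch**2
    sm = np.empty_like(out)
    r = len(kernel) // 2
    for tr in range(n_tr):
        for k in range(out.shape[1]):
            acc = np.zeros(n_t)
            for j, w in enumerate(kernel):
                kk = min(max(k + j - r, 0), out.shape[1] - 1)  # edge replication
                acc += w * out[tr, kk]
            sm[tr, k] = acc
    return sm


class TestCSD:
    @given(
        a=st.floats(-50.0, 50.0),
        b=st.floats(-10.0, 10.0),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_depth_profile_gives_zero(self, a, b, scale):
        """Any voltage affine in depth carries no current sources: the
        second spatial difference of a + b*depth vanishes at every interior
        contact, for every time course."""
        geometry = ProbeGeometry()
        rng = np.random.default_rng(99)
        depth = np.arange(16)
        tc = scale * rng.standard_normal(50)
        v = np.einsum("c,t->ct", a + b * depth, np.ones(50)) * tc
        ep = EpochTensor(data=v[None], time_ms=np.arange(50.0), domain="lfp")
        csd = compute_csd(ep, geometry, boundary="drop", smooth=False)
        assert np.allclose(csd.data, 0.0, atol=1e-9 * max(1.0, abs(a), abs(b)))

    def test_unit_impulse_second_difference(self):
        """A lone voltage peak is a current source at its contact flanked by
        matching sinks: -d2V/dz2 of (0,0,1,0,0) is (-1, 2, -1) interior."""
        v = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        ep = EpochTensor(data=v[None, :, None], time_ms=np.array([0.0]),
                         domain="lfp")
        csd = compute_csd(ep, ProbeGeometry(n_contacts=5, pitch_um=1.0),
                          boundary="drop", smooth=False)
        np.testing.assert_allclose(csd.data[0, :, 0], [-1.0, 2.0, -1.0])

    @pytest.mark.parametrize("boundary", ["vaknin", "drop"])
    @pytest.mark.parametrize("smoother", ["hamming", "gaussian"])
    def test_matches_explicit_loop_oracle(self, rng, geometry, boundary, smoother):
        v = rng.standard_normal((3, 16, 200))
        ep = EpochTensor(data=v, time_ms=np.arange(200.0), domain="lfp")
        csd = compute_csd(ep, geometry, smoother=smoother, boundary=boundary)
        oracle = _csd_loop_oracle(v, geometry.pitch_um, _depth_kernel(smoother),
                                  boundary)
        scale = np.abs(oracle).max()
        assert np.abs(csd.data - oracle).max() / scale < 1e-10

    def test_forward_model_roundtrip_through_smoothing(self, geometry):
        """CSD of the double-cumulative-sum voltage equals the injected
        zero-sum profile convolved with the known 5-point kernel (1e-6)."""
        prof = dipole_profile(16, 8)
        v = profile_to_voltage(prof) * geometry.pitch_um**2
        ep = EpochTensor(data=np.tile(v[None, :, None], (1, 1, 4)),
                         time_ms=np.arange(4.0), domain="lfp")
        csd = compute_csd(ep, geometry, smoother="hamming", boundary="drop")
        kern = _depth_kernel("hamming")
        import scipy.ndimage

        expected = scipy.ndimage.convolve1d(prof[1:-1], kern, mode="nearest")
        np.testing.assert_allclose(csd.data[0, :, 0], expected, atol=1e-6)

    def test_needs_five_contacts(self):
        ep = EpochTensor(data=np.zeros((1, 4, 10)), time_ms=np.arange(10.0),
                         domain="lfp")
        with pytest.raises(ValidationError, match="5 contacts"):
            compute_csd(ep, ProbeGeometry(n_contacts=4))


class TestLayerPartition:
    def test_l4_at_8_gives_canonical_partition(self, geometry):
        lm = layer_partition(8, geometry)
        assert lm.kept_contacts == tuple(range(1, 13))
        assert lm.contacts_in("L1") == (1, 2)
        assert lm.contacts_in("L2/3") == (3, 4, 5, 6, 7)
        assert lm.contacts_in("L4") == (8, 9)
        assert lm.contacts_in("L5") == (10, 11, 12)

    def test_shallow_l4_rejected(self, geometry):
        with pytest.raises(ValidationError, match="re-insertion"):
            layer_partition(7, geometry)

    @pytest.mark.parametrize("l4", [8, 9, 10, 11, 12])
    def test_always_keeps_twelve(self, geometry, l4):
        assert len(layer_partition(l4, geometry).kept_contacts) == 12


class TestAlignLayer4:
    def _flat_power(self, n=16):
        return np.ones((n, 50)), np.linspace(1, 100, 50)

    def test_superficial_tie_break(self):
        """All criteria tied between two contacts -> the shallower one wins."""
        t = np.arange(0.0, 150.0)
        mua = np.zeros((16, t.size))
        csd = np.zeros((16, t.size))
        for c in (7, 8):  # 0-based rows for contacts 8 and 9
            mua[c] = np.exp(-((t - 60) ** 2) / 50.0)
            csd[c] = -np.exp(-((t - 55) ** 2) / 50.0)
        power, freqs = self._flat_power()
        contact, votes = align_layer4(mua, csd, power, t, t, freqs)
        assert contact == 8

    def test_single_informative_criterion_dominates(self):
        """Flat MUA and flat spectra: a lone CSD sink decides."""
        t = np.arange(0.0, 150.0)
        mua = np.ones((16, t.size))
        csd = np.zeros((16, t.size))
        csd[6] = -np.exp(-((t - 70) ** 2) / 80.0)  # contact 7
        power, freqs = self._flat_power()
        contact, _ = align_layer4(mua, csd, power, t, t, freqs)
        assert contact == 7

    def test_crossover_criterion_follows_relative_profile(self):
        """Gamma dominance superficially, alpha/beta at depth, crossing at
        contact 8, with flat MUA/CSD."""
        t = np.arange(0.0, 150.0)
        mua = np.ones((16, t.size))
        csd = np.zeros((16, t.size))
        freqs = np.linspace(1, 100, 200)
        power = np.ones((16, freqs.size))
        gsel = (freqs >= 30) & (freqs <= 80)
        absel = (freqs >= 8) & (freqs < 30)
        for c in range(16):
            power[c, gsel] += 2.0 if c < 7 else 0.0
            power[c, absel] += 0.0 if c < 7 else 2.0 + 0.01 * (15 - c)
        contact, votes = align_layer4(mua, csd, power, t, t, freqs)
        assert votes["crossover"] == 8
        assert contact == 8


class TestAvRec:
    def _layers(self, geometry):
        return layer_partition(8, geometry)

    def test_constant_positive_csd(self, geometry):
        from laminar_oddball.laminar import CSDProfile

        csd = CSDProfile(data=np.full((3, 12, 20), 2.5),
                         time_ms=np.arange(20.0),
                         contact_labels=tuple(range(1, 13)))
        av = avrec(csd, self._layers(geometry))
        for wf in av.waveforms.values():
            np.testing.assert_allclose(wf, 2.5)

    def test_rectification_beats_cancellation(self, geometry):
        """Opposite-sign channels within a layer do not cancel."""
        from laminar_oddball.laminar import CSDProfile

        data = np.zeros((1, 12, 10))
        data[0, 7] = +3.0  # contact 8 (L4)
        data[0, 8] = -3.0  # contact 9 (L4)
        csd = CSDProfile(data=data, time_ms=np.arange(10.0),
                         contact_labels=tuple(range(1, 13)))
        av = avrec(csd, self._layers(geometry))
        np.testing.assert_allclose(av.waveforms["L4"], 3.0)

    def test_matches_order_of_operations_oracle(self, rng, geometry):
        from laminar_oddball.laminar import CSDProfile

        data = rng.standard_normal((5, 12, 30))
        csd = CSDProfile(data=data, time_ms=np.arange(30.0),
                         contact_labels=tuple(range(1, 13)))
        layers = self._layers(geometry)
        av = avrec(csd, layers)
        for layer in ("L1", "L2/3", "L4", "L5"):
            rows = [c - 1 for c in layers.contacts_in(layer)]
            oracle = np.zeros(30)
            for t in range(30):
                acc = 0.0
                for r in rows:
                    acc += abs(sum(data[tr, r, t] for tr in range(5)) / 5.0)
                oracle[t] = acc / len(rows)
            np.testing.assert_allclose(av.waveforms[layer], oracle, atol=1e-12)

    def test_sign_flip_invariance_and_lower_bound(self, rng, geometry):
        from laminar_oddball.laminar import CSDProfile

        data = rng.standard_normal((4, 12, 20))
        layers = self._layers(geometry)
        flip = data.copy()
        flip[:, 3] *= -1.0  # flip a whole channel
        av1 = avrec(CSDProfile(data=data, time_ms=np.arange(20.0),
                               contact_labels=tuple(range(1, 13))), layers)
        av2 = avrec(CSDProfile(data=flip, time_ms=np.arange(20.0),
                               contact_labels=tuple(range(1, 13))), layers)
        np.testing.assert_allclose(av1.waveforms["L2/3"], av2.waveforms["L2/3"])
        # av-rec never below |layer mean of trial-mean CSD|
        rows = [c - 1 for c in layers.contacts_in("L2/3")]
        layer_mean = np.abs(data.mean(axis=0)[rows].mean(axis=0))
        assert np.all(av1.waveforms["L2/3"] >= layer_mean - 1e-12)


def test_bin_means_partitions_waveform():
    t = np.arange(0.0, 120.0)
    wf = np.ones(120)
    wf[30:60] = 3.0
    vals = bin_means(wf, t, [(0.0, 30.0), (30.0, 60.0)])
    np.testing.assert_allclose(vals, [1.0, 3.0])
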