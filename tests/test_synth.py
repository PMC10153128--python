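"""Stimulus sequences and the synthetic forward model."""

import numpy as np
import pytest

from laminar_oddball import (
    EpochTensor,
    ProbeGeometry,
    ValidationError,
    compute_csd,
    epoch,
)
from laminar_oddball.synth import (
    EffectSpec,
    EvokedDipole,
    GroundTruth,
    MUAEvokedModel,
    NoiseModel,
    SequenceSpec,
    _burst_wave,
    default_oddball_truth,
    dipole_profile,
    generate_cohort,
    generate_flip_flop_pair,
    generate_stimulus_sequence,
    profile_to_voltage,
    simulate_recording,
)


class TestSequences:
    def test_many_standards_balanced(self):
        ev = generate_stimulus_sequence(
            SequenceSpec(kind="many_standards", n_trials=250, seed=3)
        )
        counts = ev.df["orientation_deg"].value_counts()
        assert sorted(counts.index) == [30, 45, 60, 90, 120, 135, 150, 180]
        assert set(counts.values) <= {31, 32}
        props = counts / 250.0
        assert np.all(np.abs(props - 0.125) <= 0.004)  # 12.5% +- 0.4 pp

    def test_oddball_counts_and_first_trial(self):
        ev = generate_stimulus_sequence(
            SequenceSpec(kind="oddball", n_trials=150, seed=5)
        )
        ctx = ev.df["context"]
        assert (ctx == "deviant").sum() == 19  # round(0.125 * 150)
        assert (ctx == "redundant").sum() == 131
        assert ctx.iloc[0] == "redundant"

    def test_flip_flop_roles_exchanged(self):
        a, b = generate_flip_flop_pair(
            SequenceSpec(kind="oddball", n_trials=80, deviant_orientation=45,
                         redundant_orientation=135, seed=2)
        )
        dev_a = a.df.loc[a.df["context"] == "deviant", "orientation_deg"].iloc[0]
        red_a = a.df.loc[a.df["context"] == "redundant", "orientation_deg"].iloc[0]
        dev_b = b.df.loc[b.df["context"] == "deviant", "orientation_deg"].iloc[0]
        assert dev_b == red_a and dev_a != dev_b

    def test_non_orthogonal_pair_rejected(self):
        with pytest.raises(ValidationError, match="orthogonal"):
            SequenceSpec(kind="oddball", deviant_orientation=45,
                         redundant_orientation=60)

    def test_isi_jitter_within_bounds(self):
        ev = generate_stimulus_sequence(
            SequenceSpec(kind="many_standards", n_trials=50, seed=1)
        )
        gaps_ms = np.diff(ev.df["onset_sample"]) / 10.0
        assert gaps_ms.min() >= 950 - 1 and gaps_ms.max() <= 1050 + 1


class TestForwardModel:
    def test_zero_truth_gives_zero_signal(self, small_events):
        truth = GroundTruth(
            effects=[], noise=NoiseModel(sd_uv=0.0), spectral=None,
            dipoles=[], mua=MUAEvokedModel(baseline_rate_hz=0.0, peak_gain=0.0),
        )
        rec = simulate_recording(small_events, truth, seed=0)
        assert not rec.signal.any()

    def test_seed_determinism(self, small_events):
        truth = default_oddball_truth()
        r1 = simulate_recording(small_events, truth, seed=9)
        r2 = simulate_recording(small_events, truth, seed=9)
        np.testing.assert_array_equal(r1.signal, r2.signal)

    def test_injected_sink_recovered_by_csd(self, small_events, geometry):
        """A lone noiseless L4 dipole at 50-80 ms shows its CSD extremum at
        the sink contact inside that window (the analysis chain is the
        measuring instrument)."""
        truth = GroundTruth(
            effects=[], noise=NoiseModel(sd_uv=0.0), spectral=None,
            dipoles=[EvokedDipole(sink_contact=8, latency_ms=65.0, width_ms=8.0,
                                  amplitude_uv=50.0)],
            mua=MUAEvokedModel(baseline_rate_hz=0.0, peak_gain=0.0),
        )
        rec = simulate_recording(small_events, truth, seed=0)
        eps = epoch(rec, small_events, (-50.0, 200.0))
        csd = compute_csd(eps, geometry)
        mean_map = csd.data.mean(axis=0)  # contacts x time
        c_idx, t_idx = np.unravel_index(np.argmin(mean_map), mean_map.shape)
        assert c_idx + 1 == 8  # sink (negative CSD) at the injected contact
        assert 50.0 <= csd.time_ms[t_idx] <= 80.0

    def test_dipole_profile_conserves_current(self):
        prof = dipole_profile(16, 8)
        assert prof.sum() == 0.0
        assert np.dot(prof, np.arange(16)) == 0.0  # zero dipole moment
        v = profile_to_voltage(prof)
        # voltage constant outside the dipole support -> zero CSD there
        assert np.allclose(v[:5], v[0]) and np.allclose(v[-5:], v[-1])

    def test_burst_energy_concentrates_in_band(self):
        """>= 80% of each catalogue burst's power lies within its band +- 2 Hz."""
        fs = 10000.0
        for eff in default_oddball_truth().effects:
            if eff.kind not in ("burst", "coupling"):
                continue
            w = _burst_wave(eff, fs, phase=0.7).astype(float)
            spec = np.abs(np.fft.rfft(w, 8 * w.size)) ** 2
            f = np.fft.rfftfreq(8 * w.size, 1 / fs)
            lo, hi = eff.band_hz[0] - 2.0, eff.band_hz[1] + 2.0
            frac = spec[(f >= lo) & (f <= hi)].sum() / spec.sum()
            assert frac >= 0.80, (eff.name, frac)

    def test_context_gain_scales_injected_power_linearly(self, geometry):
        """Injected induced-power difference vs control is proportional to
        (gain - 1): gains act multiplicatively on burst power."""
        from laminar_oddball.oscillations import WaveletGrid, morlet_decompose

        fs = 10000.0
        diffs = {}
        for gain in (2.0, 3.0):
            eff = EffectSpec(
                name="g", kind="burst", contacts=(5,), window_ms=(100.0, 300.0),
                band_hz=(18.0, 22.0), amplitude=10.0, gains={"deviant": gain},
            )
            import pandas as pd

            from laminar_oddball.core import EventTable

            powers = {}
            for ctx, run in (("control", "control"), ("deviant", "oddball_A")):
                if ctx == "control":
                    contexts = [ctx] * 4
                    orients = [45] * 4
                else:
                    contexts = ["redundant", "deviant", "deviant", "deviant"]
                    orients = [135, 45, 45, 45]
                df = pd.DataFrame(
                    {
                        "onset_sample": 20000 + 15000 * np.arange(4),
                        "orientation_deg": orients,
                        "context": contexts,
                        "run": run,
                        "duration_samples": 5000,
                    }
                )
                ev = EventTable(df)
                truth = GroundTruth(
                    effects=[eff], noise=NoiseModel(sd_uv=0.0), spectral=None,
                    dipoles=[],
                    mua=MUAEvokedModel(baseline_rate_hz=0.0, peak_gain=0.0),
                )
                rec = simulate_recording(ev, truth, seed=3)
                sel = ev.df["context"].isin([ctx]).to_numpy()
                eps = epoch(rec, ev.df["onset_sample"].to_numpy()[sel],
                            (-250.0, 750.0))
                tf = morlet_decompose(eps, WaveletGrid(), (0.0, 500.0))
                pw = np.abs(tf.data[:, 4, 18, :]) ** 2  # 20 Hz bin, contact 5
                powers[ctx] = pw.mean()
            diffs[gain] = powers["deviant"] - powers["control"]
        ratio = diffs[3.0] / diffs[2.0]
        assert ratio == pytest.approx((3.0 - 1.0) / (2.0 - 1.0), rel=0.1)


class TestGroundTruth:
    def test_default_catalogue_valid(self):
        truth = default_oddball_truth()
        truth.validate()
        by_name = {e.name: e for e in truth.effects}
        assert by_name["l4_mua_ssa"].gains["redundant"] < 1
        assert by_name["l23_mua_dd"].gains["deviant"] > 1
        assert by_name["l1_highbeta_dd"].gains["deviant"] < 1
        assert by_name["l1_deep23_lowgamma_decoupling"].gains["deviant"] < 1

    def test_effect_needs_a_modulated_context(self):
        with pytest.raises(ValidationError, match="differ from 1"):
            EffectSpec(name="x", kind="burst", contacts=(1,),
                       window_ms=(0.0, 100.0), band_hz=(5.0, 10.0),
                       gains={"deviant": 1.0})

    def test_window_outside_epoch_rejected(self):
        truth = GroundTruth(
            effects=[
                EffectSpec(name="x", kind="mua_rate", contacts=(8,),
                           window_ms=(700.0, 900.0), gains={"deviant": 2.0})
            ]
        )
        with pytest.raises(ValidationError, match="outside epoch"):
            truth.validate()


class TestCohort:
    def test_zero_sd_gives_identical_gains(self):
        cohort = generate_cohort(2, between_subject_sd=0.0, seed=1,
                                 n_control=16, n_oddball=8)
        g0 = [e.gains for e in cohort[0][2].effects]
        g1 = [e.gains for e in cohort[1][2].effects]
        assert g0 == g1

    def test_reproducible_and_distinct_subjects(self):
        a = generate_cohort(2, seed=4, n_control=16, n_oddball=8)
        b = generate_cohort(2, seed=4, n_control=16, n_oddball=8)
        np.testing.assert_array_equal(a[0][0].signal, b[0][0].signal)
        assert not np.array_equal(a[0][0].signal[:, :10000],
                                  a[1][0].signal[:, :10000])

    def test_cohort_needs_two_subjects(self):
        with pytest.raises(ValidationError):
            generate_cohort(1, n_control=16, n_oddball=8)
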