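"""Synthetic laminar-recording generator with known injected context effects.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage of the pipeline has a recovery oracle:

* spatially correlated 1/f background noise,
* ongoing band-limited laminar activity whose gamma vs alpha/beta balance
  crosses over at the granular layer (used by layer-4 alignment),
* stimulus-evoked dipolar sink/source currents, built by double cumulative
  summation of a zero-sum, zero-dipole-moment current-density depth profile
  (1-D forward model, unit conductivity) so that the second-spatial-derivative
  CSD estimator is an exact inverse up to boundary terms,
* band-limited oscillatory bursts with random phase per trial (induced, not
  evoked) whose injected *power* is multiplied by a per-context gain,
* Poisson-timed biphasic spiking transients (500-4000 Hz energy) whose
  evoked-rate increment is multiplied by a per-context gain,
* an inter-contact phase-coupling effect: a narrowband burst whose phase is
  shared between seed and target contacts with a context-dependent
  probability, so surrogate-corrected synchrony differs between contexts.

Amplitudes are expressed in uV against a background noise SD of
``NoiseModel.sd_uv``; context gains are multiplicative relative to the
control context (gain 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .core import (
    EventTable,
    ProbeGeometry,
    Recording,
    VALID_ORIENTATIONS,
    logger,
)
from .errors import ValidationError

DEFAULT_ORIENTATIONS = (30, 45, 60, 90, 120, 135, 150, 180)


# ---------------------------------------------------------------------------
# Stimulus sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceSpec:
    """One stimulus run: many-standards control or oddball."""

    kind: str  # "many_standards" | "oddball"
    n_trials: int = 250
    orientations: tuple[int, ...] = DEFAULT_ORIENTATIONS
    deviant_orientation: int = 45
    redundant_orientation: int = 135
    stim_ms: float = 500.0
    isi_ms: float = 500.0
    isi_jitter_ms: float = 50.0
    fs: float = 10000.0
    start_pad_ms: float = 1000.0
    run: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("many_standards", "oddball"):
            raise ValidationError("kind must be 'many_standards' or 'oddball'")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.kind == "oddball":
            if (self.deviant_orientation - self.redundant_orientation) % 180 != 90:
                raise ValidationError(
                    "deviant and redundant orientations must be orthogonal "
                    "(90 degrees apart)"
                )
        bad = set(self.orientations) - set(VALID_ORIENTATIONS)
        if bad:
            raise ValidationError(f"invalid orientations: {sorted(bad)}")


def _onsets(spec: SequenceSpec, rng: np.random.Generator) -> np.ndarray:
    """Trial onsets in samples: stimulus duration plus jittered ISI."""
    isi = spec.isi_ms + rng.uniform(-spec.isi_jitter_ms, spec.isi_jitter_ms,
                                    size=spec.n_trials)
    gaps_ms = spec.stim_ms + isi
    starts_ms = spec.start_pad_ms + np.concatenate([[0.0], np.cumsum(gaps_ms[:-1])])
    return np.round(starts_ms * spec.fs / 1000.0).astype(np.int64)


def generate_stimulus_sequence(spec: SequenceSpec) -> EventTable:
    """Generate one run's event table.

    Many-standards: every orientation appears equally often (counts differ by
    at most 1, i.e. ~12.5% each for 8 orientations), in shuffled order.
    Oddball: round(0.125 * n) deviants, remainder redundant, shuffled with the
    constraint that the first trial is redundant.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials
    if spec.kind == "many_standards":
        orients = np.array(spec.orientations)
        base, extra = divmod(n, orients.size)
        counts = np.full(orients.size, base)
        counts[rng.permutation(orients.size)[:extra]] += 1
        labels = np.repeat(orients, counts)
        rng.shuffle(labels)
        context = np.array(["control"] * n)
        run = "control" if spec.run == "control" else spec.run
    else:
        n_dev = int(round(0.125 * n))
        labels = np.full(n, spec.redundant_orientation)
        context = np.array(["redundant"] * n)
        # deviants are placed uniformly among positions 1..n-1
        pos = rng.choice(np.arange(1, n), size=n_dev, replace=False)
        labels[pos] = spec.deviant_orientation
        context[pos] = "deviant"
        run = spec.run if spec.run != "control" else "oddball_A"
    onset = _onsets(spec, rng)
    dur = int(round(spec.stim_ms * spec.fs / 1000.0))
    df = pd.DataFrame(
        {
            "onset_sample": onset,
            "orientation_deg": labels.astype(int),
            "context": context,
            "run": run,
            "duration_samples": dur,
        }
    )
    return EventTable(df)


def generate_flip_flop_pair(spec: SequenceSpec) -> tuple[EventTable, EventTable]:
    """Two oddball runs with deviant/redundant roles exchanged."""
    a = dataclasses_replace(spec, kind="oddball", run="oddball_A", seed=spec.seed)
    b = dataclasses_replace(
        spec,
        kind="oddball",
        run="oddball_B",
        seed=spec.seed + 1,
        deviant_orientation=spec.redundant_orientation,
        redundant_orientation=spec.deviant_orientation,
    )
    return generate_stimulus_sequence(a), generate_stimulus_sequence(b)


def dataclasses_replace(spec, **kw):
    import dataclasses

    return dataclasses.replace(spec, **kw)


def generate_session(
    n_control: int = 250,
    n_oddball: int = 150,
    orientations: tuple[int, ...] = DEFAULT_ORIENTATIONS,
    oddball_pair: tuple[int, int] = (45, 135),
    fs: float = 10000.0,
    seed: int = 0,
    run_gap_ms: float = 2000.0,
) -> EventTable:
    """Full session: many-standards control then the flip-flop oddball pair,
    concatenated on one time axis with a gap between runs."""
    dev, red = oddball_pair
    ctl = generate_stimulus_sequence(
        SequenceSpec(
            kind="many_standards", n_trials=n_control, orientations=orientations,
            fs=fs, seed=seed, run="control",
        )
    )
    odd_spec = SequenceSpec(
        kind="oddball", n_trials=n_oddball, orientations=orientations,
        deviant_orientation=dev, redundant_orientation=red, fs=fs, seed=seed + 10,
    )
    run_a, run_b = generate_flip_flop_pair(odd_spec)
    gap = int(round(run_gap_ms * fs / 1000.0))
    tables = []
    offset = 0
    for t in (ctl, run_a, run_b):
        df = t.df.copy()
        df["onset_sample"] += offset
        offset = int(df["onset_sample"].iloc[-1] + df["duration_samples"].iloc[-1] + gap)
        tables.append(EventTable(df))
    return EventTable.concat(tables)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """1/f background: exponent, per-contact SD (uV), spatial correlation."""

    exponent: float = 1.0
    sd_uv: float = 20.0
    corr_len_contacts: float = 2.0


@dataclass
class LaminarSpectralProfile:
    """Ongoing band-limited activity whose gamma vs alpha/beta balance
    crosses over at the granular layer (drives layer-4 alignment)."""

    gamma_band_hz: tuple[float, float] = (30.0, 80.0)
    alphabeta_band_hz: tuple[float, float] = (8.0, 30.0)
    amplitude_uv: float = 5.0
    crossover_contact: int = 8  # first contact from the top with gamma < alpha/beta
    slope_contacts: float = 0.75

    def amplitudes(self, n_contacts: int) -> tuple[np.ndarray, np.ndarray]:
        k = np.arange(1, n_contacts + 1, dtype=float)
        mid = self.crossover_contact - 0.5
        gamma = self.amplitude_uv / (1.0 + np.exp((k - mid) / self.slope_contacts))
        ab = self.amplitude_uv / (1.0 + np.exp((mid - k) / self.slope_contacts))
        return gamma, ab


@dataclass
class EvokedDipole:
    """Stimulus-locked sink flanked by return sources (zero net current)."""

    sink_contact: int = 8
    latency_ms: float = 50.0
    width_ms: float = 12.0
    amplitude_uv: float = 60.0
    gains: dict = field(default_factory=dict)  # per-context amplitude gain


@dataclass
class MUAEvokedModel:
    """Evoked spiking-rate model: baseline Poisson rate plus a transient peak
    (layer-dependent latency; granular earliest) and a sustained plateau."""

    baseline_rate_hz: float = 30.0
    peak_gain: float = 10.0
    sustain_gain: float = 3.0
    peak_sigma_ms: float = 15.0
    sustain_window_ms: tuple[float, float] = (30.0, 480.0)
    latency_l4_ms: float = 45.0
    latency_l23_ms: float = 60.0
    latency_l1_ms: float = 70.0
    latency_l5_ms: float = 55.0
    pulse_amp_uv: float = 60.0
    pulse_freq_hz: float = 1500.0
    pulse_sigma_ms: float = 0.25
    tuning_kappa: float = 0.8
    preferred_deg: int | None = None  # None: untuned

    def latency_for(self, contact: int, l4_contact: int) -> float:
        d = contact - l4_contact
        if d in (0, 1):
            return self.latency_l4_ms
        if -5 <= d <= -1:
            return self.latency_l23_ms
        if d <= -6:
            return self.latency_l1_ms
        return self.latency_l5_ms

    def tuning(self, orientation_deg: float) -> float:
        if self.preferred_deg is None:
            return 1.0
        delta = np.deg2rad(orientation_deg - self.preferred_deg)
        return float(np.exp(self.tuning_kappa * (np.cos(2 * delta) - 1.0)))


@dataclass
class EffectSpec:
    """One injected context effect.

    kind:
      * ``mua_rate`` — the per-context gain multiplies the evoked spiking-rate
        increment at the stated contacts within the stated window (broadband).
      * ``burst`` — Hann-windowed sinusoid at the band centre, random phase per
        trial, added at the stated contacts; the gain multiplies injected
        *power* (amplitude scales with sqrt(gain)).
      * ``coupling`` — narrowband burst whose phase is shared between seed and
        target contacts with probability ``coupling``; the gain multiplies the
        sharing probability, altering surrogate-corrected synchrony only.
    """

    name: str
    kind: str
    contacts: tuple[int, ...]
    window_ms: tuple[float, float]
    gains: dict[str, float]
    band_hz: tuple[float, float] | None = None  # None == broadband
    amplitude: float = 1.0
    duration_ms: float | None = None  # bursts: None -> window length
    seed_contacts: tuple[int, ...] = ()
    target_contact: int | None = None
    coupling: float = 0.95

    def __post_init__(self) -> None:
        if self.kind not in ("mua_rate", "burst", "coupling"):
            raise ValidationError(f"unknown effect kind {self.kind!r}")
        if any(g <= 0 for g in self.gains.values()):
            raise ValidationError(f"effect {self.name!r}: gains must be > 0")
        if not any(abs(g - 1.0) > 1e-12 for g in self.gains.values()):
            raise ValidationError(
                f"effect {self.name!r}: at least one context gain must differ from 1"
            )

    def gain(self, context: str) -> float:
        return float(self.gains.get(context, 1.0))

    @property
    def center_hz(self) -> float:
        if self.band_hz is None:
            raise ValidationError(f"effect {self.name!r} is broadband")
        return 0.5 * (self.band_hz[0] + self.band_hz[1])

    @property
    def burst_duration_ms(self) -> float:
        if self.duration_ms is not None:
            return self.duration_ms
        return self.window_ms[1] - self.window_ms[0]


@dataclass
class GroundTruth:
    """Injected-effect catalogue plus noise/evoked models (recovery oracle)."""

    effects: list[EffectSpec] = field(default_factory=list)
    noise: NoiseModel = field(default_factory=NoiseModel)
    spectral: LaminarSpectralProfile = field(default_factory=LaminarSpectralProfile)
    dipoles: list[EvokedDipole] = field(default_factory=list)
    mua: MUAEvokedModel = field(default_factory=MUAEvokedModel)
    l4_contact: int = 8
    epoch_ms: tuple[float, float] = (-250.0, 750.0)

    def validate(self) -> "GroundTruth":
        for e in self.effects:
            lo, hi = e.window_ms
            if lo < self.epoch_ms[0] or hi > self.epoch_ms[1]:
                raise ValidationError(
                    f"effect {e.name!r}: window {e.window_ms} outside epoch "
                    f"{self.epoch_ms}"
                )
        return self

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


def default_oddball_truth() -> GroundTruth:
    """Effect catalogue with the laminar oddball signature:

    * granular (L4) MUA adaptation to redundants at 50-80 ms,
    * supragranular (L2/3) MUA deviance detection at 140-230 ms,
    * L2/3 delta/theta (2-7 Hz) induced-power increase to deviants,
    * L2/3 high-gamma (68-77 Hz) increase to deviants,
    * L1 high-beta (26-36 Hz) decrease to deviants,
    * deviant-specific loss of L1 <-> deep-L2/3 phase coupling at 34-41 Hz.

    Contact numbers assume layer 4 aligned at contact 8 on a 16-contact probe
    (kept window 1-12: L1={1,2}, L2/3={3-7}, L4={8,9}, L5={10,11,12}).
    """
    effects = [
        EffectSpec(
            name="l4_mua_ssa", kind="mua_rate", contacts=(8, 9),
            window_ms=(50.0, 80.0), gains={"redundant": 0.45},
        ),
        EffectSpec(
            name="l23_mua_dd", kind="mua_rate", contacts=(3, 4, 5, 6, 7),
            window_ms=(140.0, 230.0), gains={"deviant": 1.9},
        ),
        EffectSpec(
            name="l23_theta_dd", kind="burst", contacts=(3, 4, 5, 6, 7),
            window_ms=(100.0, 150.0), band_hz=(2.0, 7.0), amplitude=26.0,
            duration_ms=250.0, gains={"deviant": 2.5},
        ),
        EffectSpec(
            name="l23_highgamma_dd", kind="burst", contacts=(3, 4, 5, 6, 7),
            window_ms=(110.0, 260.0), band_hz=(68.0, 77.0), amplitude=8.0,
            duration_ms=150.0, gains={"deviant": 2.5},
        ),
        EffectSpec(
            name="l1_highbeta_dd", kind="burst", contacts=(1, 2),
            window_ms=(90.0, 120.0), band_hz=(26.0, 36.0), amplitude=20.0,
            duration_ms=160.0, gains={"deviant": 0.2},
        ),
        EffectSpec(
            # the decoupling spans the deep-L2/3 / dorsal-L4 border
            name="l1_deep23_lowgamma_decoupling", kind="coupling",
            contacts=(1, 2, 7, 8), seed_contacts=(1, 2), target_contact=7,
            window_ms=(50.0, 250.0), band_hz=(34.0, 41.0), amplitude=34.0,
            duration_ms=280.0, coupling=1.0, gains={"deviant": 0.05},
        ),
    ]
    dipoles = [
        EvokedDipole(sink_contact=8, latency_ms=50.0, width_ms=12.0,
                     amplitude_uv=60.0),
        EvokedDipole(sink_contact=4, latency_ms=85.0, width_ms=18.0,
                     amplitude_uv=35.0),
    ]
    return GroundTruth(effects=effects, dipoles=dipoles).validate()


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def dipole_profile(n_contacts: int, sink_contact: int) -> np.ndarray:
    """Zero-sum, zero-first-moment current-density depth profile:
    sink (-1) at ``sink_contact`` flanked by +0.5 return sources."""
    k = sink_contact - 1
    if k < 1 or k > n_contacts - 2:
        raise ValidationError("sink contact must be an interior contact")
    c = np.zeros(n_contacts)
    c[k] = -1.0
    c[k - 1] = 0.5
    c[k + 1] = 0.5
    return c


def profile_to_voltage(profile: np.ndarray) -> np.ndarray:
    """1-D forward model: double cumulative summation of a current-density
    depth profile (unit conductivity), arranged so the central second
    difference -(V[k-1] - 2 V[k] + V[k+1]) recovers the profile at interior
    contacts.  Outside a zero-sum, zero-moment profile's support the voltage
    is constant (zero CSD)."""
    n = profile.size
    d2 = -np.asarray(profile, float)  # -d2V/dz2 convention, sinks negative
    f = np.concatenate([[0.0], np.cumsum(d2[1:n - 1])])
    v = np.concatenate([[0.0], np.cumsum(f)])
    return v


def _shaped_noise(
    rng: np.random.Generator,
    n_contacts: int,
    n_samples: int,
    fs: float,
    noise: NoiseModel,
    spectral: LaminarSpectralProfile | None,
) -> np.ndarray:
    """Per-contact noise with a 1/f component plus laminar band-limited
    components, shaped in one FFT pass per channel, then spatially mixed."""
    import scipy.fft

    nfft = scipy.fft.next_fast_len(n_samples, real=True)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    out = np.empty((n_contacts, n_samples), np.float32)

    def _norm(w: np.ndarray) -> float:
        # expected output SD for unit-variance white input shaped by w
        w2 = w.astype(float) ** 2
        s = 2.0 * w2[1:-1].sum() + w2[0] + w2[-1]
        return float(np.sqrt(s / nfft))

    # 1/f weight (DC removed)
    pink_w = np.zeros_like(freqs)
    pink_w[1:] = freqs[1:] ** (-noise.exponent / 2.0)
    pn = _norm(pink_w)
    pink_w = pink_w / pn if pn > 0 else pink_w

    band_ws = []
    amps = []
    if spectral is not None and spectral.amplitude_uv > 0:
        g_amp, ab_amp = spectral.amplitudes(n_contacts)
        for band, amp in ((spectral.gamma_band_hz, g_amp),
                          (spectral.alphabeta_band_hz, ab_amp)):
            w = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
            bn = _norm(w)
            band_ws.append(w / bn if bn > 0 else w)
            amps.append(amp)

    for ch in range(n_contacts):
        x = rng.standard_normal(nfft)
        X = scipy.fft.rfft(x)
        w = noise.sd_uv * pink_w
        for bw, amp in zip(band_ws, amps):
            w = w + amp[ch] * bw
        out[ch] = scipy.fft.irfft(X * w, nfft)[:n_samples].astype(np.float32)

    if noise.corr_len_contacts > 0:
        idx = np.arange(n_contacts)
        kern = np.exp(-((idx[:, None] - idx[None, :]) ** 2)
                      / (2.0 * noise.corr_len_contacts**2))
        kern /= np.sqrt((kern**2).sum(axis=1, keepdims=True))
        out = (kern.astype(np.float32) @ out)
    return out


def simulate_recording(
    events: EventTable,
    truth: GroundTruth,
    geometry: ProbeGeometry | None = None,
    fs: float = 10000.0,
    seed: int = 0,
    subject_id: str = "synthetic",
    pad_s: float = 1.0,
) -> Recording:
    """Render a continuous laminar recording for an event table.

    Reproducible from ``seed``.  See the module docstring for the model.
    """
    geometry = geometry or ProbeGeometry()
    truth.validate()
    events.validate()
    rng = np.random.default_rng(seed)
    n_contacts = geometry.n_contacts
    last = int(events.df["onset_sample"].iloc[-1] + events.df["duration_samples"].iloc[-1])
    n_samples = last + int(pad_s * fs)
    dt = 1.0 / fs

    zero_noise = truth.noise.sd_uv == 0 and (
        truth.spectral is None or truth.spectral.amplitude_uv == 0
    )
    if zero_noise:
        sig = np.zeros((n_contacts, n_samples), np.float32)
    else:
        sig = _shaped_noise(rng, n_contacts, n_samples, fs, truth.noise, truth.spectral)

    onsets = events.df["onset_sample"].to_numpy()
    contexts = events.df["context"].to_numpy()
    orients = events.df["orientation_deg"].to_numpy()

    # --- evoked dipolar currents -----------------------------------------
    for dip in truth.dipoles:
        if dip.amplitude_uv == 0:
            continue
        prof = dipole_profile(n_contacts, dip.sink_contact)
        v = profile_to_voltage(prof)
        v = dip.amplitude_uv * v / np.abs(v).max()
        t = np.arange(-3 * dip.width_ms, 3 * dip.width_ms + 1e-9, 1000.0 * dt)
        g = np.exp(-(t**2) / (2.0 * dip.width_ms**2))
        t0 = int(round(dip.latency_ms / 1000.0 * fs)) - t.size // 2
        wave = np.outer(v, g).astype(np.float32)
        for o, ctx in zip(onsets, contexts):
            a = float(dip.gains.get(ctx, 1.0))
            s = o + t0
            if s >= 0 and s + g.size <= n_samples:
                sig[:, s:s + g.size] += a * wave

    # --- oscillatory bursts and phase coupling ---------------------------
    for eff in truth.effects:
        if eff.kind == "burst":
            _add_bursts(sig, eff, onsets, contexts, fs, rng)
        elif eff.kind == "coupling":
            _add_coupled_bursts(sig, eff, onsets, contexts, fs, rng)

    # --- spiking transients ----------------------------------------------
    _add_mua(sig, truth, onsets, contexts, orients, fs, rng)

    rec = Recording(signal=sig, fs=fs, geometry=geometry, subject_id=subject_id)
    logger.info(
        "simulate_recording: subject=%s n=%d samples (%.1f s), %d trials, seed=%d",
        subject_id, n_samples, n_samples / fs, len(events), seed,
    )
    return rec.validate()


def _burst_wave(eff: EffectSpec, fs: float, phase: float) -> np.ndarray:
    dur = eff.burst_duration_ms / 1000.0
    n = max(int(round(dur * fs)), 2)
    t = np.arange(n) / fs
    env = np.hanning(n)
    return (env * np.cos(2 * np.pi * eff.center_hz * t + phase)).astype(np.float32)


def _burst_start(eff: EffectSpec, onset: int, fs: float) -> int:
    center_ms = 0.5 * (eff.window_ms[0] + eff.window_ms[1])
    n = max(int(round(eff.burst_duration_ms / 1000.0 * fs)), 2)
    return onset + int(round(center_ms / 1000.0 * fs)) - n // 2


def _add_bursts(sig, eff, onsets, contexts, fs, rng) -> None:
    rows = [c - 1 for c in eff.contacts]
    for o, ctx in zip(onsets, contexts):
        amp = eff.amplitude * np.sqrt(eff.gain(ctx))
        w = _burst_wave(eff, fs, rng.uniform(0, 2 * np.pi)) * amp
        s = _burst_start(eff, o, fs)
        if s >= 0 and s + w.size <= sig.shape[1]:
            sig[rows, s:s + w.size] += w


def _add_coupled_bursts(sig, eff, onsets, contexts, fs, rng) -> None:
    seeds = [c - 1 for c in eff.seed_contacts]
    targets = [c - 1 for c in eff.contacts if c not in eff.seed_contacts]
    for o, ctx in zip(onsets, contexts):
        kappa = min(1.0, eff.coupling * eff.gain(ctx))
        phi = rng.uniform(0, 2 * np.pi)
        phi_t = phi if rng.uniform() < kappa else rng.uniform(0, 2 * np.pi)
        w_seed = _burst_wave(eff, fs, phi) * eff.amplitude
        w_tgt = _burst_wave(eff, fs, phi_t) * eff.amplitude
        s = _burst_start(eff, o, fs)
        if s >= 0 and s + w_seed.size <= sig.shape[1]:
            sig[seeds, s:s + w_seed.size] += w_seed
            sig[targets, s:s + w_tgt.size] += w_tgt


def _add_mua(sig, truth, onsets, contexts, orients, fs, rng) -> None:
    m = truth.mua
    if m.baseline_rate_hz == 0 and m.peak_gain == 0:
        return
    if m.pulse_amp_uv == 0:
        return
    n_contacts, n_samples = sig.shape
    dt = 1.0 / fs
    ep_n = int(round(0.75 * fs))  # rate template covers 0..750 ms post-onset
    t_ms = np.arange(ep_n) / fs * 1000.0
    sus_lo, sus_hi = m.sustain_window_ms
    plateau = ((t_ms >= sus_lo) & (t_ms <= sus_hi)).astype(float)
    # soften plateau edges (10 ms cosine ramps)
    ramp = int(round(0.01 * fs))
    if ramp > 1:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        on = np.searchsorted(t_ms, sus_lo)
        off = np.searchsorted(t_ms, sus_hi)
        plateau[on:on + ramp] = win[: max(0, min(ramp, ep_n - on))]
        if off < ep_n:
            plateau[max(0, off - ramp):off] = win[::-1][: min(ramp, off)]

    # biphasic pulse kernel, energy near pulse_freq_hz
    tk = np.arange(-4 * m.pulse_sigma_ms, 4 * m.pulse_sigma_ms + 1e-9, 1000.0 * dt)
    tk /= 1000.0
    kern = -np.sin(2 * np.pi * m.pulse_freq_hz * tk) * np.exp(
        -(tk**2) / (2.0 * (m.pulse_sigma_ms / 1000.0) ** 2)
    )
    kern = (m.pulse_amp_uv * kern / np.abs(kern).max()).astype(np.float32)

    rate_effects = [e for e in truth.effects if e.kind == "mua_rate"]
    for ch in range(n_contacts):
        lam = np.full(n_samples, m.baseline_rate_hz * dt, np.float64)
        lat = m.latency_for(ch + 1, truth.l4_contact)
        peak = m.peak_gain * np.exp(-((t_ms - lat) ** 2) / (2.0 * m.peak_sigma_ms**2))
        base_prof = peak + m.sustain_gain * plateau
        for o, ctx, theta in zip(onsets, contexts, orients):
            prof = base_prof * m.tuning(theta)
            for e in rate_effects:
                if (ch + 1) in e.contacts:
                    g = e.gain(ctx)
                    if g != 1.0:
                        wsel = (t_ms >= e.window_ms[0]) & (t_ms < e.window_ms[1])
                        prof = np.where(wsel, prof * g, prof)
            hi = min(o + ep_n, n_samples)
            lam[o:hi] += m.baseline_rate_hz * dt * prof[: hi - o]
        spikes = rng.poisson(lam)
        nz = np.flatnonzero(spikes)
        if nz.size:
            train = np.zeros(n_samples, np.float32)
            train[nz] = spikes[nz] * rng.uniform(0.7, 1.3, size=nz.size)
            sig[ch] += scipy.signal.oaconvolve(train, kern, mode="same")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _jitter_truth(
    truth: GroundTruth, rng: np.random.Generator, sd: float,
    orientations: tuple[int, ...],
) -> GroundTruth:
    import copy

    t = copy.deepcopy(truth)
    for e in t.effects:
        e.gains = {
            ctx: float(g * np.exp(rng.normal(0.0, sd))) for ctx, g in e.gains.items()
        }
    t.mua.preferred_deg = int(rng.choice(orientations))
    return t


def iter_cohort(
    n_subjects: int,
    truth: GroundTruth | None = None,
    between_subject_sd: float = 0.25,
    seed: int = 0,
    n_control: int = 250,
    n_oddball: int = 150,
    oddball_pair: tuple[int, int] = (45, 135),
    fs: float = 10000.0,
    geometry: ProbeGeometry | None = None,
):
    """Yield (Recording, EventTable, GroundTruth) per subject.

    Per-subject effect gains are log-normal around the truth gains with the
    stated between-subject SD; per-subject seeds derive deterministically from
    the master seed.
    """
    if n_subjects < 2:
        raise ValidationError("a cohort needs >= 2 subjects")
    truth = truth or default_oddball_truth()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sub_truth = _jitter_truth(truth, rng, between_subject_sd, DEFAULT_ORIENTATIONS)
        ev_seed = int(rng.integers(0, 2**31 - 1))
        sim_seed = int(rng.integers(0, 2**31 - 1))
        events = generate_session(
            n_control=n_control, n_oddball=n_oddball, oddball_pair=oddball_pair,
            fs=fs, seed=ev_seed,
        )
        rec = simulate_recording(
            events, sub_truth, geometry=geometry, fs=fs, seed=sim_seed,
            subject_id=f"sub{i:02d}",
        )
        yield rec, events, sub_truth


def generate_cohort(*args, **kwargs):
    """List version of :func:`iter_cohort` (small cohorts only; recordings
    are large, prefer the iterator in pipelines)."""
    return list(iter_cohort(*args, **kwargs))
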