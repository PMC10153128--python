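"""Morlet time-frequency decomposition, induced power, and surrogate-corrected
inter-electrode synchrony (IES).

The wavelet grid is 100 frequencies (2-101 Hz, 1-Hz steps) with cycle counts
increasing linearly from 0.5 to 20, evaluated every 4 ms.  Wavelets are
amplitude-normalized so a unit-amplitude sinusoid at a grid frequency yields
|W| = 1 at its bin; power values are therefore in relative units, which is
irrelevant to the context contrasts the pipeline reports.

IES: for a contact pair (a, b) and frequency, the phase-locking factor R is
the resultant length of exp(i * (phi_a - phi_b)) over trials and window
timepoints.  A surrogate R computed with contact b's phases taken from the
trial two positions ahead (wrapping) removes coherence that is merely
stimulus-locked; IES = R - R_surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .config import AnalysisConfig
from .core import EpochTensor, LayerMap
from .errors import ValidationError


@dataclass
class WaveletGrid:
    """Frequencies (Hz), cycle counts, and output hop (ms)."""

    freqs_hz: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 102.0)
    )
    cycles: np.ndarray = field(
        default_factory=lambda: np.linspace(0.5, 20.0, 100)
    )
    hop_ms: float = 4.0
    support_sigmas: float = 3.5

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.cycles = np.asarray(self.cycles, float)
        if self.freqs_hz.size != self.cycles.size:
            raise ValidationError("freqs and cycles must have equal length")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValidationError("cycles must be strictly increasing")

    @classmethod
    def from_config(cls, cfg: AnalysisConfig) -> "WaveletGrid":
        return cls(
            freqs_hz=cfg.wavelet_freqs_hz,
            cycles=np.linspace(*cfg.wavelet_cycles, cfg.wavelet_n_freqs),
            hop_ms=cfg.wavelet_hop_ms,
        )

    def sigma_t(self, i: int) -> float:
        """Temporal SD (s) of wavelet i: cycles / (2 pi f)."""
        return float(self.cycles[i] / (2 * np.pi * self.freqs_hz[i]))


@dataclass
class TFPower:
    """Layer x frequency x time baseline-subtracted induced power."""

    data: np.ndarray
    layers: tuple[str, ...]
    freqs_hz: np.ndarray
    time_ms: np.ndarray
    baseline: np.ndarray  # layer x frequency scalar shifts
    context: str = ""


@dataclass
class IESSpectra:
    """Contact x contact x frequency synchrony, raw and surrogate-corrected."""

    raw: np.ndarray
    surrogate: np.ndarray
    ies: np.ndarray
    freqs_hz: np.ndarray
    contact_labels: tuple[int, ...]
    window_ms: tuple[float, float]
    context: str = ""

    @property
    def diagonal_mask(self) -> np.ndarray:
        """True on non-informative self-pairs."""
        n = self.raw.shape[0]
        return np.eye(n, dtype=bool)


def morlet_decompose(
    epochs: EpochTensor,
    grid: WaveletGrid | None = None,
    out_window_ms: tuple[float, float] | None = None,
) -> EpochTensor:
    """Complex Morlet coefficients: trials x contacts x frequencies x times.

    Coefficients are evaluated every ``grid.hop_ms`` on a grid anchored at
    stimulus onset (t = 0).  Output times whose wavelet support extends past
    the epoch are flagged in ``meta['edge_valid']`` (frequencies x times).
    """
    grid = grid or WaveletGrid()
    fs = epochs.fs
    if fs <= 0:
        raise ValidationError("epochs must carry their sampling rate")
    hop = grid.hop_ms * fs / 1000.0
    if abs(hop - round(hop)) > 1e-9:
        raise ValidationError(
            f"hop of {grid.hop_ms} ms is not a whole number of samples at {fs} Hz"
        )
    hop = int(round(hop))
    t = epochs.time_ms
    if out_window_ms is None:
        out_window_ms = (t[0], t[-1])
    # output grid: multiples of hop_ms relative to onset, inside the window
    i0 = int(np.argmin(np.abs(t)))
    ks = np.arange(-(i0 // hop), (t.size - i0 - 1) // hop + 1)
    out_idx = i0 + ks * hop
    out_t = t[out_idx]
    sel = (out_t >= out_window_ms[0] - 1e-9) & (out_t <= out_window_ms[1] + 1e-9)
    out_idx, out_t = out_idx[sel], out_t[sel]
    if out_idx.size == 0:
        raise ValidationError("no output timepoints inside the requested window")

    n_tr, n_ch, _ = epochs.data.shape
    n_f = grid.freqs_hz.size
    coeffs = np.empty((n_tr, n_ch, n_f, out_idx.size), np.complex64)
    edge_valid = np.empty((n_f, out_idx.size), bool)
    x = epochs.data.astype(np.float64)
    for i in range(n_f):
        f = grid.freqs_hz[i]
        sig = grid.sigma_t(i)
        half = grid.support_sigmas * sig
        tk = np.arange(-half, half + 1e-12, 1.0 / fs)
        gauss = np.exp(-(tk**2) / (2.0 * sig**2))
        w = np.exp(2j * np.pi * f * tk) * gauss
        w *= 2.0 / gauss.sum()  # unit response to a unit sinusoid at f
        full = scipy.signal.fftconvolve(x, w[None, None, :], mode="same", axes=2)
        coeffs[:, :, i, :] = full[:, :, out_idx]
        edge_valid[i] = (out_t / 1000.0 - half >= t[0] / 1000.0 - 0.5 / fs) & (
            out_t / 1000.0 + half <= t[-1] / 1000.0 + 0.5 / fs
        )
    return EpochTensor(
        data=coeffs, time_ms=out_t, domain="tf_complex", context=epochs.context,
        contact_labels=epochs.contact_labels, fs=1000.0 / grid.hop_ms,
        meta={
            "freqs_hz": grid.freqs_hz.copy(),
            "edge_valid": edge_valid,
            "normalization": "unit response to unit-amplitude sinusoid",
        },
    )


def induced_power(
    tf_by_context: dict[str, EpochTensor],
    layers: LayerMap,
    baseline_window_ms: tuple[float, float] = (-200.0, -50.0),
) -> dict[str, TFPower]:
    """Across-trial average |W|^2 per layer, minus a global per-(layer,
    frequency) baseline pooled over ALL contexts and trials.

    The baseline shift is identical across contexts, so context differences
    are exactly invariant to it.
    """
    layer_power = {}
    freqs = time_ms = None
    for ctx, tf in tf_by_context.items():
        freqs = tf.meta["freqs_hz"]
        time_ms = tf.time_ms
        pw = np.abs(tf.data.astype(np.complex128)) ** 2
        pw = pw.mean(axis=0)  # contacts x freqs x times
        row_of = {c: i for i, c in enumerate(tf.contact_labels)}
        per_layer = []
        for layer in LayerMap.LAYERS:
            rows = [row_of[c] for c in layers.contacts_in(layer) if c in row_of]
            if not rows:
                raise ValidationError(f"layer {layer} missing from the TF tensor")
            per_layer.append(pw[rows].mean(axis=0))
        layer_power[ctx] = np.stack(per_layer)  # layers x freqs x times
    bsel = (time_ms >= baseline_window_ms[0]) & (time_ms <= baseline_window_ms[1])
    if not bsel.any():
        raise ValidationError("baseline window contains no timepoints")
    baseline = np.mean(
        [lp[:, :, bsel].mean(axis=2) for lp in layer_power.values()], axis=0
    )
    out = {}
    for ctx, lp in layer_power.items():
        out[ctx] = TFPower(
            data=lp - baseline[:, :, None],
            layers=LayerMap.LAYERS,
            freqs_hz=freqs,
            time_ms=time_ms,
            baseline=baseline,
            context=ctx,
        )
    return out


def ies(
    tf: EpochTensor,
    window_ms: tuple[float, float],
    surrogate_offset: int = 2,
    symmetrize: bool = False,
) -> IESSpectra:
    """Surrogate-corrected inter-electrode synchrony for all contact pairs.

    Raw R is the across-trial/timepoint resultant length of the inter-contact
    phase difference; the surrogate pairs contact b's phases from the trial
    ``surrogate_offset`` positions ahead (mod n_trials), using every trial
    exactly once.  Raw R is symmetric in (a, b); the surrogate's one-sided
    pairing is not, so ``symmetrize`` averages the surrogate over both
    pairing directions, making the corrected IES exactly symmetric.
    """
    n_tr = tf.data.shape[0]
    if n_tr < 4:
        raise ValidationError("IES needs >= 4 trials (surrogate pairing degenerate)")
    sel = (tf.time_ms >= window_ms[0] - 1e-9) & (tf.time_ms <= window_ms[1] + 1e-9)
    if not sel.any():
        raise ValidationError("IES window contains no timepoints")
    w = tf.data[..., sel].astype(np.complex128)
    mag = np.abs(w)
    z = np.where(mag > 0, w / np.where(mag > 0, mag, 1.0), 0.0)
    denom = n_tr * z.shape[-1]
    raw = np.abs(np.einsum("tafn,tbfn->abf", z, z.conj())) / denom
    z_shift = np.roll(z, -surrogate_offset, axis=0)
    surr = np.abs(np.einsum("tafn,tbfn->abf", z, z_shift.conj())) / denom
    if symmetrize:
        surr = 0.5 * (surr + surr.transpose(1, 0, 2))
    return IESSpectra(
        raw=raw, surrogate=surr, ies=raw - surr,
        freqs_hz=np.asarray(tf.meta["freqs_hz"]),
        contact_labels=tf.contact_labels,
        window_ms=tuple(window_ms), context=tf.context,
    )


def ies_seed_map(
    spectra: IESSpectra, seed_contacts: tuple[int, ...]
) -> np.ndarray:
    """Target-contact x frequency map: mean over seed contacts of the
    corrected IES rows.  Seed contacts are 1-based contact labels."""
    row_of = {c: i for i, c in enumerate(spectra.contact_labels)}
    missing = [c for c in seed_contacts if c not in row_of]
    if missing:
        raise ValidationError(f"seed contacts {missing} not in the spectra")
    rows = [row_of[c] for c in seed_contacts]
    return spectra.ies[rows].mean(axis=0)
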