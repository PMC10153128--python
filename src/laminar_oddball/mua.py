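"""Multiunit-activity envelope extraction and best-orientation selection.

The MUA chain: zero-phase band-pass 500-4000 Hz per channel, common average
reference excluding the channel itself, full-wave rectification, Gaussian
smoothing in 10-ms windows (FWHM by default), anti-alias low-pass, and
decimation to 1000 Hz.  Envelopes are normalized by the ongoing standard
deviation pooled over all channels and timepoints within a recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .config import AnalysisConfig
from .core import EpochTensor, Recording, logger
from .errors import ValidationError


@dataclass
class MUAEnvelope:
    """Epoched, normalized MUA at 1000 Hz plus the ongoing SD used."""

    epochs: EpochTensor
    ongoing_sd: float


def compute_mua(rec: Recording, config: AnalysisConfig | None = None) -> Recording:
    """Continuous MUA envelope at the configured output rate (default 1 kHz).

    The common average reference is computed after band-passing (so no
    low-frequency content leaks into the reference) and excludes the channel
    itself: ref_i = (sum_j x_j - x_i) / (n - 1).
    """
    config = config or AnalysisConfig()
    lo, hi = config.mua_band_hz
    if rec.fs < 2 * hi:
        raise ValidationError(
            f"sampling rate {rec.fs} Hz cannot support the {lo}-{hi} Hz MUA band"
        )
    sos = scipy.signal.butter(4, (lo, hi), btype="bandpass", fs=rec.fs, output="sos")
    n_ch = rec.signal.shape[0]
    bp = scipy.signal.sosfiltfilt(sos, rec.signal.astype(np.float64), axis=1)
    total = bp.sum(axis=0)
    car = bp - (total - bp) / (n_ch - 1)
    env = np.abs(car)
    sigma_ms = config.mua_smooth_ms / 2.3548 if config.mua_smooth_is_fwhm \
        else config.mua_smooth_ms
    sigma = sigma_ms / 1000.0 * rec.fs
    q = rec.fs / config.mua_rate_hz
    if abs(q - round(q)) > 1e-9:
        raise ValidationError("mua_rate_hz must divide the sampling rate")
    q = int(round(q))
    # Gaussian smoothing and decimation in one polyphase pass.  The Gaussian
    # is itself the anti-alias filter: at a 10-ms window its attenuation at
    # the 500-Hz output Nyquist is > 250 dB, so plain subsampling of the
    # smoothed envelope is alias-free.
    radius = q * int(np.ceil(3.0 * sigma / q))  # multiple of q keeps phase
    tk = np.arange(-radius, radius + 1)
    kern = np.exp(-(tk**2) / (2.0 * sigma**2))
    kern /= kern.sum()
    n = env.shape[1]
    if q > 1:
        full = scipy.signal.upfirdn(kern, env, up=1, down=q, axis=1)
        env = full[:, radius // q: radius // q + int(np.ceil(n / q))]
    else:
        env = scipy.signal.oaconvolve(env, kern[None, :], mode="same", axes=1)
    env = np.clip(env, 0.0, None)  # numerically tiny negatives can appear
    logger.info("compute_mua: %s -> %d ch x %d samples @ %g Hz",
                rec.subject_id, env.shape[0], env.shape[1], config.mua_rate_hz)
    return Recording(
        signal=env.astype(np.float32), fs=config.mua_rate_hz,
        geometry=rec.geometry, subject_id=rec.subject_id, domain="mua",
    )


def normalize_mua(obj: Recording | EpochTensor):
    """Divide by one scalar per recording: the SD of the MUA signal pooled
    over all channels and timepoints.  Returns (normalized object, sd)."""
    if isinstance(obj, Recording):
        sd = float(obj.signal.std())
        if sd == 0:
            raise ValidationError("MUA signal has zero pooled SD")
        out = Recording(
            signal=(obj.signal / sd).astype(np.float32), fs=obj.fs,
            geometry=obj.geometry, subject_id=obj.subject_id, domain="mua",
        )
        return out, sd
    sd = float(obj.data.std())
    if sd == 0:
        raise ValidationError("MUA epochs have zero pooled SD")
    out = EpochTensor(
        data=obj.data / sd, time_ms=obj.time_ms, domain=obj.domain,
        context=obj.context, contact_labels=obj.contact_labels, fs=obj.fs,
        meta={**obj.meta, "ongoing_sd": sd},
    )
    return out, sd


def select_best_orientation(
    mua_by_orientation: dict[int, EpochTensor | list[EpochTensor]],
    config: AnalysisConfig | None = None,
    response_window_ms: tuple[float, float] = (0.0, 100.0),
) -> tuple[int, dict]:
    """Pick the orientation with the strongest mean MUA response in the first
    100 ms after onset, averaged over trials, contacts and contexts.

    Returns (orientation, flags).  ``flags['no_clear_response']`` mirrors the
    exclusion of a subject whose best response stays below the configured
    floor; ``flags['tie']`` marks an exact tie (first orientation in a fixed
    ordering is returned).
    """
    if not mua_by_orientation:
        raise ValidationError("no orientations supplied")
    config = config or AnalysisConfig()
    scores = {}
    for orient in sorted(mua_by_orientation):
        tensors = mua_by_orientation[orient]
        if isinstance(tensors, EpochTensor):
            tensors = [tensors]
        vals = []
        for ep in tensors:
            sel = (ep.time_ms >= response_window_ms[0]) & \
                  (ep.time_ms < response_window_ms[1])
            vals.append(ep.data[..., sel].mean())
        scores[orient] = float(np.mean(vals))
    ordered = sorted(scores)
    best = max(ordered, key=lambda o: scores[o])
    flags = {"scores": scores, "tie": False, "no_clear_response": False}
    top = scores[best]
    if sum(1 for o in ordered if scores[o] == top) > 1:
        flags["tie"] = True
        best = next(o for o in ordered if scores[o] == top)
    if top < config.mua_response_floor:
        flags["no_clear_response"] = True
        logger.warning("select_best_orientation: max response %.3f below floor %.3f",
                       top, config.mua_response_floor)
    return best, flags
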