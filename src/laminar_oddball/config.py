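"""Analysis configuration: every tunable of the pipeline with its default.

Defaults mirror the recording/analysis conventions of the laminar oddball
protocol this package implements: 16-contact probe digitized at 10 kHz, LFP
low-passed below 110 Hz, MUA band 500-4000 Hz smoothed in 10-ms Gaussian
windows at a 1000-Hz output rate, a 100-wavelet Morlet grid (2-101 Hz, 0.5->20
cycles) applied every 4 ms, 30-ms statistics bins, inter-electrode synchrony
windows at 50-250 and 250-450 ms with a 2-trial surrogate offset, and a
2500-permutation cluster test at alpha = 0.025 per tail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class AnalysisConfig:
    # LFP conditioning
    lowpass_hz: float = 110.0
    # MUA chain
    mua_band_hz: tuple[float, float] = (500.0, 4000.0)
    mua_smooth_ms: float = 10.0
    mua_smooth_is_fwhm: bool = True  # alternative: treat as Gaussian SD
    mua_rate_hz: float = 1000.0
    mua_response_floor: float = 0.5  # normalized units; "no clear response" flag
    # Epoching
    epoch_window_ms: tuple[float, float] = (-250.0, 750.0)
    tf_epoch_pad_ms: float = 150.0  # extra context so wavelet support fits
    stim_ms: float = 500.0
    # Morlet grid
    wavelet_fmin_hz: float = 2.0
    wavelet_n_freqs: int = 100
    wavelet_cycles: tuple[float, float] = (0.5, 20.0)
    wavelet_hop_ms: float = 4.0
    # Induced power
    baseline_window_ms: tuple[float, float] = (-200.0, -50.0)
    # IES
    ies_early_ms: tuple[float, float] = (50.0, 250.0)
    ies_late_ms: tuple[float, float] = (250.0, 450.0)
    surrogate_offset: int = 2
    # Windowed statistics
    bin_width_ms: float = 30.0
    bins_start_ms: float = 50.0
    bins_stop_ms: float = 260.0
    ssa_latest_ms: float = 140.0  # a-priori: SSA early, DD later
    # Cluster permutation
    n_permutations: int = 2500
    cluster_alpha: float = 0.025  # per tail
    z_crit: float = 1.96
    adjacency: str = "4"  # or "8"
    # CSD
    csd_smoother: str = "hamming"  # or "gaussian"; 5-point depth kernel
    csd_boundary: str = "vaknin"  # or "drop"
    # Layer-4 alignment: gamma vs alpha/beta crossover bands
    crossover_gamma_hz: tuple[float, float] = (30.0, 80.0)
    crossover_alphabeta_hz: tuple[float, float] = (8.0, 30.0)
    # ROI band conventions: "results" (26-35, 68-77) or "caption" (26-36, 67-76)
    roi_band_convention: str = "results"
    # Event-table handling
    merge_0_and_180_deg: bool = False
    # Multiple-ROI correction across the six ROIs (off: planned/ROI logic)
    holm_across_rois: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")
        if self.wavelet_n_freqs < 2:
            raise ValidationError("wavelet_n_freqs must be >= 2")
        if self.adjacency not in ("4", "8"):
            raise ValidationError("adjacency must be '4' or '8'")
        if self.csd_smoother not in ("hamming", "gaussian"):
            raise ValidationError("csd_smoother must be 'hamming' or 'gaussian'")
        if self.csd_boundary not in ("vaknin", "drop"):
            raise ValidationError("csd_boundary must be 'vaknin' or 'drop'")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(fields)
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    # convenience -----------------------------------------------------------
    @property
    def wavelet_freqs_hz(self):
        import numpy as np

        return np.arange(
            self.wavelet_fmin_hz, self.wavelet_fmin_hz + self.wavelet_n_freqs
        ).astype(float)

    @property
    def roi_high_beta_hz(self) -> tuple[float, float]:
        return (26.0, 35.0) if self.roi_band_convention == "results" else (26.0, 36.0)

    @property
    def roi_high_gamma_hz(self) -> tuple[float, float]:
        return (68.0, 77.0) if self.roi_band_convention == "results" else (67.0, 76.0)

    def analysis_bins_ms(self) -> list[tuple[float, float]]:
        """Contiguous 30-ms statistics bins covering the evoked-response span."""
        bins = []
        t = self.bins_start_ms
        while t + self.bin_width_ms <= self.bins_stop_ms + 1e-9:
            bins.append((t, t + self.bin_width_ms))
            t += self.bin_width_ms
        return bins
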