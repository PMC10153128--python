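"""Core domain types for laminar recordings and epoched data.

Contact indexing convention: contacts are numbered 1..n_contacts, with
contact 1 the most superficial and numbers increasing with depth.  All
stored arrays use this order along their contact axis (row 0 == contact 1).
Time convention: stimulus onset = 0 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("laminar_oddball")

#: Grating orientations used by the paradigm (degrees).  0 is admitted as a
#: distinct label; it is merged with 180 only when the user opts in.
VALID_ORIENTATIONS = (0, 30, 45, 60, 90, 120, 135, 150, 180)
VALID_CONTEXTS = ("control", "redundant", "deviant")
VALID_RUNS = ("control", "oddball_A", "oddball_B")
EVENT_COLUMNS = (
    "onset_sample",
    "orientation_deg",
    "context",
    "run",
    "duration_samples",
)


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear probe geometry: contact count and inter-contact pitch (um)."""

    n_contacts: int = 16
    pitch_um: float = 50.0

    def __post_init__(self) -> None:
        if self.n_contacts < 4:
            raise ValidationError("n_contacts must be >= 4")
        if self.pitch_um <= 0:
            raise ValidationError("pitch_um must be > 0")

    @property
    def span_um(self) -> float:
        return (self.n_contacts - 1) * self.pitch_um


@dataclass
class Recording:
    """Multichannel continuous voltage: contacts x samples, in uV."""

    signal: np.ndarray
    fs: float
    geometry: ProbeGeometry
    subject_id: str = "subject"
    domain: str = "raw"  # raw | lfp | mua

    def validate(self) -> "Recording":
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (contacts x samples)")
        if self.signal.shape[0] != self.geometry.n_contacts:
            raise ValidationError(
                f"signal has {self.signal.shape[0]} rows but geometry declares "
                f"{self.geometry.n_contacts} contacts"
            )
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite values")
        return self

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


class EventTable:
    """Per-trial event table: onset, orientation, context, run, duration.

    Thin wrapper over a pandas DataFrame enforcing paradigm invariants:
    onsets strictly increasing within a run, control context only in the
    control run, and each oddball run carrying exactly one deviant and one
    redundant orientation separated by 90 degrees.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        self.df = df.reset_index(drop=True)[list(EVENT_COLUMNS)]
        if validate:
            self.validate()

    def validate(self) -> "EventTable":
        df = self.df
        if len(df) == 0:
            raise ValidationError("event table is empty")
        bad_orient = set(df["orientation_deg"]) - set(VALID_ORIENTATIONS)
        if bad_orient:
            raise ValidationError(f"invalid orientations: {sorted(bad_orient)}")
        bad_ctx = set(df["context"]) - set(VALID_CONTEXTS)
        if bad_ctx:
            raise ValidationError(f"invalid contexts: {sorted(bad_ctx)}")
        bad_run = set(df["run"]) - set(VALID_RUNS)
        if bad_run:
            raise ValidationError(f"invalid runs: {sorted(bad_run)}")
        for run, sub in df.groupby("run"):
            onsets = sub["onset_sample"].to_numpy()
            if not np.all(np.diff(onsets) > 0):
                raise ValidationError(f"onsets not strictly increasing in run {run!r}")
            if run == "control":
                if not (sub["context"] == "control").all():
                    raise ValidationError("control run must contain only control context")
            else:
                if (sub["context"] == "control").any():
                    raise ValidationError(
                        f"context='control' outside the control run ({run!r})"
                    )
                dev = sub.loc[sub["context"] == "deviant", "orientation_deg"].unique()
                red = sub.loc[sub["context"] == "redundant", "orientation_deg"].unique()
                if len(dev) != 1 or len(red) != 1:
                    raise ValidationError(
                        f"oddball run {run!r} must have exactly one deviant and one "
                        f"redundant orientation (got {dev} / {red})"
                    )
                if not _orthogonal(int(dev[0]), int(red[0])):
                    raise ValidationError(
                        f"deviant ({dev[0]}) and redundant ({red[0]}) orientations "
                        "must be 90 degrees apart"
                    )
        return self

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, **conditions) -> pd.DataFrame:
        mask = np.ones(len(self.df), bool)
        for col, val in conditions.items():
            mask &= (self.df[col] == val).to_numpy()
        return self.df[mask]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path))

    @classmethod
    def concat(cls, tables: list["EventTable"]) -> "EventTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


def _orthogonal(a: int, b: int) -> bool:
    return (a - b) % 180 == 90


@dataclass
class EpochTensor:
    """Trials x contacts x timepoints in a named signal domain."""

    data: np.ndarray
    time_ms: np.ndarray
    domain: str  # lfp | csd | mua | tf_complex
    context: str = ""
    contact_labels: tuple[int, ...] = ()
    fs: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.time_ms = np.asarray(self.time_ms, float)
        if not np.all(np.diff(self.time_ms) > 0):
            raise ValidationError("time axis must be strictly increasing")
        if self.data.shape[-1] != self.time_ms.size:
            raise ValidationError("last data axis must match the time axis")
        if not self.contact_labels:
            self.contact_labels = tuple(range(1, self.data.shape[1] + 1))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_slice(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Boolean mask over the time axis selecting [t_lo, t_hi)."""
        return (self.time_ms >= t_lo - 1e-9) & (self.time_ms < t_hi - 1e-9)


@dataclass
class LayerMap:
    """12-contact window around layer 4 and its 2/5/2/3 layer partition."""

    l4_contact: int
    kept_contacts: tuple[int, ...]
    layer_of_contact: dict[int, str]

    LAYERS = ("L1", "L2/3", "L4", "L5")

    def __post_init__(self) -> None:
        if len(self.kept_contacts) != 12:
            raise ValidationError("a layer map must keep exactly 12 contacts")

    def contacts_in(self, layer: str) -> tuple[int, ...]:
        return tuple(c for c in self.kept_contacts if self.layer_of_contact[c] == layer)


def match_trial_counts(
    epochs_by_context: dict[str, EpochTensor], seed: int
) -> tuple[dict[str, EpochTensor], dict[str, np.ndarray]]:
    """Subsample every context to the minimum trial count (seeded, uniform).

    Trial counts are held constant across contexts so that estimator variance
    is comparable between them.  Selection is a uniform draw without
    replacement rather than "first n", to avoid early-session adaptation bias.
    Returns the matched tensors and the selected trial indices per context.
    """
    for ctx, ep in epochs_by_context.items():
        if ep.n_trials == 0:
            raise ValidationError(f"context {ctx!r} has no trials")
    n_min = min(ep.n_trials for ep in epochs_by_context.values())
    rng = np.random.default_rng(seed)
    out, picks = {}, {}
    for ctx in sorted(epochs_by_context):
        ep = epochs_by_context[ctx]
        if ep.n_trials == n_min:
            idx = np.arange(n_min)
        else:
            idx = np.sort(rng.choice(ep.n_trials, size=n_min, replace=False))
        picks[ctx] = idx
        out[ctx] = EpochTensor(
            data=ep.data[idx],
            time_ms=ep.time_ms,
            domain=ep.domain,
            context=ep.context,
            contact_labels=ep.contact_labels,
            fs=ep.fs,
            meta={**ep.meta, "matched_from": ep.n_trials, "trial_indices": idx.tolist()},
        )
        logger.info(
            "match_trial_counts: context=%s kept %d/%d trials (seed=%d)",
            ctx, n_min, ep.n_trials, seed,
        )
    return out, picks
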