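"""Statistical surfaces: 30-ms windowed paired contrasts, layer x context
repeated-measures ANOVA on time-frequency ROIs, and the depth x frequency
cluster-mass permutation test.

Conventions follow the analysis this package reproduces: MUA contrasts are
one-tailed in the hypothesized direction (adaptation = reduction to
redundants, deviance detection = increase to deviants), CSD contrasts are
two-tailed; the cluster test sign-flips within-subject difference maps,
z-scores the observed map pointwise against the permutation distribution,
forms contiguous supra-threshold clusters, and compares each cluster's mass
to the permutation distribution of maximum cluster masses (alpha = 0.025 per
tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.ndimage
import scipy.stats

from .config import AnalysisConfig
from .errors import ValidationError

CONTRAST_CONTEXT = {"DD": "deviant", "SSA": "redundant"}
#: hypothesized one-tailed direction of each contrast (sign of other - control)
CONTRAST_DIRECTION = {"DD": +1, "SSA": -1}


@dataclass
class WindowContrast:
    domain: str
    layer: str
    window_ms: tuple[float, float]
    contrast: str  # DD | SSA
    tail: str  # one | two
    t: float
    df: int
    p: float
    mean_diff: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class ROIDefinition:
    name: str
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]


def default_rois(cfg: AnalysisConfig | None = None) -> list[ROIDefinition]:
    """The six time-frequency regions of interest of the protocol."""
    cfg = cfg or AnalysisConfig()
    return [
        ROIDefinition("early_delta_theta", (2.0, 7.0), (100.0, 150.0)),
        ROIDefinition("early_low_beta", (12.0, 22.0), (65.0, 180.0)),
        ROIDefinition("early_high_beta", cfg.roi_high_beta_hz, (90.0, 120.0)),
        ROIDefinition("mid_high_gamma", cfg.roi_high_gamma_hz, (110.0, 260.0)),
        ROIDefinition("mid_alpha_desync", (6.0, 12.0), (240.0, 310.0)),
        ROIDefinition("late_delta_theta_desync", (2.0, 7.0), (350.0, 560.0)),
    ]


@dataclass
class ClusterResult:
    tail: str  # positive | negative
    mass: float
    p: float
    significant: bool
    bins: list[tuple[int, int]]  # (depth index, frequency index)

    def depth_indices(self) -> set[int]:
        return {b[0] for b in self.bins}

    def freq_indices(self) -> set[int]:
        return {b[1] for b in self.bins}


# ---------------------------------------------------------------------------
# Windowed paired t-tests
# ---------------------------------------------------------------------------

def windowed_ttest(
    values: pd.DataFrame,
    contrast: str,
    tail: str,
    domain: str = "mua",
    layer: str = "",
    window_ms: tuple[float, float] = (0.0, 30.0),
) -> WindowContrast:
    """Paired t-test of one context against control for one layer/window.

    ``values``: one row per subject with columns named after the contexts
    (must include 'control' and the contrast's context).  One-tailed tests
    use the hypothesized direction of the contrast (DD increase, SSA
    reduction).
    """
    ctx = CONTRAST_CONTEXT[contrast]
    for col in ("control", ctx):
        if col not in values.columns:
            raise ValidationError(f"values table missing context column {col!r}")
    diffs = (values[ctx] - values["control"]).astype(float)
    incomplete = values.index[diffs.isna()].tolist()
    if incomplete:
        raise ValidationError(f"missing pairs for subjects: {incomplete}")
    d = diffs.to_numpy()
    n = d.size
    if n < 3:
        raise ValidationError("windowed_ttest needs >= 3 subjects")
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0
        p = 1.0 if tail == "two" else 0.5
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        dist = scipy.stats.t(df=n - 1)
        if tail == "two":
            p = 2.0 * dist.sf(abs(t))
        else:
            direction = CONTRAST_DIRECTION[contrast]
            p = dist.sf(t) if direction > 0 else dist.cdf(t)
    return WindowContrast(
        domain=domain, layer=layer, window_ms=tuple(window_ms), contrast=contrast,
        tail=tail, t=float(t), df=n - 1, p=float(p), mean_diff=float(d.mean()),
    )


# ---------------------------------------------------------------------------
# ROI repeated-measures ANOVA with planned contrasts
# ---------------------------------------------------------------------------

@dataclass
class ROIStats:
    roi: str
    anova: pd.DataFrame
    interaction_p: float
    interaction_F: float
    contrasts: pd.DataFrame  # layer, contrast, t, df, p, mean_diff, gated


def roi_anova(
    power: pd.DataFrame,
    roi_name: str = "",
    apriori: tuple[str, str] | None = None,
    sphericity_correction: bool = True,
    alpha: float = 0.05,
) -> ROIStats:
    """Two-way repeated-measures ANOVA (layer x context) for one ROI.

    ``power``: long table with columns subject, layer, context, value;
    must be complete (every subject x layer x context cell).  Planned paired
    t-tests per layer (deviant vs control = DD, redundant vs control = SSA)
    are reported for all layers but marked as gated unless the interaction is
    significant; the single a-priori contrast (``apriori=(layer, contrast)``)
    is always ungated.
    """
    required = {"subject", "layer", "context", "value"}
    if not required <= set(power.columns):
        raise ValidationError(f"power table needs columns {sorted(required)}")
    counts = power.groupby(["subject", "layer", "context"]).size()
    if (counts != 1).any() or counts.size != (
        power["subject"].nunique() * power["layer"].nunique()
        * power["context"].nunique()
    ):
        raise ValidationError("power table must be complete (one value per cell)")

    import warnings

    with warnings.catch_warnings():
        # pingouin flags two-way epsilon estimates as approximate; the GG
        # correction here is deliberately conservative either way
        warnings.simplefilter("ignore", UserWarning)
        aov = pg.rm_anova(
            data=power, dv="value", within=["layer", "context"],
            subject="subject", detailed=True,
        )
    inter = aov[aov["Source"].str.contains("\\*")].iloc[0]
    pcol = "p_GG_corr" if (
        sphericity_correction and "p_GG_corr" in aov.columns
        and np.isfinite(inter.get("p_GG_corr", np.nan))
    ) else "p_unc"
    interaction_p = float(inter[pcol])
    interaction_F = float(inter["F"])
    gate_open = interaction_p < alpha

    rows = []
    wide = power.pivot_table(index="subject", columns=["layer", "context"],
                             values="value")
    for layer in sorted(power["layer"].unique()):
        for contrast, ctx in CONTRAST_CONTEXT.items():
            a = wide[(layer, ctx)].to_numpy(float)
            b = wide[(layer, "control")].to_numpy(float)
            d = a - b
            n = d.size
            sd = d.std(ddof=1)
            t = 0.0 if sd == 0 else float(d.mean() / (sd / np.sqrt(n)))
            p = 1.0 if sd == 0 else float(2 * scipy.stats.t(df=n - 1).sf(abs(t)))
            is_apriori = apriori is not None and (layer, contrast) == tuple(apriori)
            rows.append(
                {
                    "roi": roi_name, "layer": layer, "contrast": contrast,
                    "t": t, "df": n - 1, "p": p, "mean_diff": float(d.mean()),
                    "gated": not (gate_open or is_apriori),
                    "apriori": is_apriori,
                }
            )
    return ROIStats(
        roi=roi_name, anova=aov, interaction_p=interaction_p,
        interaction_F=interaction_F, contrasts=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Cluster-mass permutation test
# ---------------------------------------------------------------------------

def _adjacency_structure(kind: str) -> np.ndarray:
    if kind == "4":
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    if kind == "8":
        return np.ones((3, 3), bool)
    raise ValidationError(f"unknown adjacency {kind!r}")


def _cluster_masses(z: np.ndarray, z_crit: float, structure: np.ndarray):
    """Connected supra-threshold components per sign: (mass, bins) list."""
    out = []
    for sign in (+1, -1):
        mask = z > z_crit if sign > 0 else z < -z_crit
        lab, n = scipy.ndimage.label(mask, structure=structure)
        for k in range(1, n + 1):
            sel = lab == k
            mass = float(z[sel].sum())
            bins = [tuple(b) for b in np.argwhere(sel)]
            out.append((mass, bins))
    return out


def cluster_permutation(
    diff_maps: np.ndarray,
    n_perm: int = 2500,
    z_crit: float = 1.96,
    alpha: float = 0.025,
    adjacency: str = "4",
    seed: int = 0,
) -> list[ClusterResult]:
    """Sign-flip cluster-mass permutation test on within-subject difference
    maps (subjects x depth x frequency).

    The observed mean map is z-scored pointwise against the distribution of
    sign-flipped permutation means, thresholded at |z| > z_crit, and clustered
    under the declared adjacency separately per sign.  The null is the
    per-permutation maximum absolute cluster mass; each observed cluster's
    p = (1 + #{null >= |mass|}) / (n_perm + 1), significant at ``alpha`` per
    tail.
    """
    diff_maps = np.asarray(diff_maps, float)
    if diff_maps.ndim != 3:
        raise ValidationError("diff_maps must be subjects x depth x frequency")
    n_sub = diff_maps.shape[0]
    if n_sub < 5:
        raise ValidationError("cluster test needs >= 5 subjects")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if not diff_maps.any():
        return []
    structure = _adjacency_structure(adjacency)
    shape = diff_maps.shape[1:]
    flat = diff_maps.reshape(n_sub, -1)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    perms = (signs @ flat) / n_sub  # n_perm x bins
    mu = perms.mean(axis=0)
    sd = perms.std(axis=0)
    sd_safe = np.where(sd > 0, sd, np.inf)
    z_obs = ((flat.mean(axis=0) - mu) / sd_safe).reshape(shape)

    null_max = np.empty(n_perm)
    for i in range(n_perm):
        zp = ((perms[i] - mu) / sd_safe).reshape(shape)
        masses = _cluster_masses(zp, z_crit, structure)
        null_max[i] = max((abs(m) for m, _ in masses), default=0.0)

    results = []
    for mass, bins in _cluster_masses(z_obs, z_crit, structure):
        p = float((1 + np.sum(null_max >= abs(mass))) / (n_perm + 1))
        results.append(
            ClusterResult(
                tail="positive" if mass > 0 else "negative",
                mass=mass, p=p, significant=p < alpha, bins=bins,
            )
        )
    results.sort(key=lambda c: c.p)
    return results
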