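"""Figure/table report over a results directory.

Renders three figure analogues — per-layer av-rec/MUA traces with shaded
significant 30-ms bins, layer x context time-frequency maps with ROI
contrasts, and seed-referenced IES maps with the significant cluster contour
— plus the statistics and recovery tables, into one standalone HTML document
with the figures saved alongside as PNGs.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError

_CTX_COLORS = {"control": "0.3", "redundant": "tab:blue", "deviant": "tab:red"}


def make_report(results_dir: str | Path, out_name: str = "report.html") -> Path:
    """Build the report; returns the path of the HTML document."""
    results_dir = Path(results_dir)
    required = ["traces.csv", "windowed_stats.csv", "roi_values.csv",
                "roi_contrasts.csv", "ies_clusters.csv", "manifest.json"]
    missing = [f for f in required if not (results_dir / f).exists()]
    if missing:
        raise ValidationError(f"results directory missing inputs: {missing}")
    traces = pd.read_csv(results_dir / "traces.csv")
    windowed = pd.read_csv(results_dir / "windowed_stats.csv")
    roi_contrasts = pd.read_csv(results_dir / "roi_contrasts.csv")
    clusters = pd.read_csv(results_dir / "ies_clusters.csv")
    manifest = json.loads((results_dir / "manifest.json").read_text())

    figs = []
    figs.append(_fig_traces(traces, windowed, results_dir))
    figs.append(_fig_roi(roi_contrasts, results_dir))
    figs.append(_fig_ies(results_dir, clusters))

    tables = [("Windowed contrasts", windowed), ("ROI contrasts", roi_contrasts)]
    rec_path = results_dir / "recovery_report.csv"
    if rec_path.exists():
        tables.append(("Effect recovery", pd.read_csv(rec_path)))

    html = ["<html><head><title>Laminar oddball report</title></head><body>"]
    html.append(f"<h1>Laminar oddball analysis report</h1>"
                f"<p>config hash {manifest['config_hash']}, seed "
                f"{manifest['seed']}, {manifest['n_subjects']} subjects</p>")
    for title, png in figs:
        html.append(f"<h2>{title}</h2><img src='{png.name}' width='900'>")
    for title, df in tables:
        html.append(f"<h2>{title}</h2>")
        html.append(df.to_html(index=False, float_format=lambda v: f"{v:.4g}"))
    html.append("</body></html>")
    out = results_dir / out_name
    out.write_text("\n".join(html))
    return out


def _fig_traces(traces: pd.DataFrame, windowed: pd.DataFrame, out_dir: Path):
    layers = ["L1", "L2/3", "L4", "L5"]
    fig, axes = plt.subplots(2, 4, figsize=(16, 6), sharex=True)
    for row, domain in enumerate(("csd", "mua")):
        sub = traces[traces["domain"] == domain]
        for col, layer in enumerate(layers):
            ax = axes[row, col]
            for ctx, g in sub[sub["layer"] == layer].groupby("context"):
                m = g.groupby("time_ms")["value"].mean()
                ax.plot(m.index, m.values, color=_CTX_COLORS.get(ctx, "k"),
                        label=ctx, lw=1)
            sig = windowed[(windowed["domain"] == domain)
                           & (windowed["layer"] == layer)
                           & windowed["significant"]]
            for _, r in sig.iterrows():
                ax.axvspan(r["bin_lo"], r["bin_hi"], alpha=0.15, color="gold")
            if row == 0:
                ax.set_title(layer)
            if col == 0:
                ax.set_ylabel("av-rec CSD" if domain == "csd" else "MUA (norm.)")
    axes[0, 0].legend(fontsize=8)
    axes[1, 0].set_xlabel("time (ms)")
    fig.suptitle("Per-layer av-rec CSD and MUA by context "
                 "(shaded: significant 30-ms bins)")
    p = out_dir / "fig_traces.png"
    fig.savefig(p, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return "Evoked responses by layer and context", p


def _fig_roi(roi_contrasts: pd.DataFrame, out_dir: Path):
    fig, ax = plt.subplots(figsize=(10, 4))
    piv = roi_contrasts.pivot_table(index="roi", columns=["layer", "contrast"],
                                    values="t")
    im = ax.imshow(piv.to_numpy(), cmap="RdBu_r", vmin=-6, vmax=6, aspect="auto")
    ax.set_yticks(range(len(piv.index)), piv.index, fontsize=8)
    ax.set_xticks(range(len(piv.columns)),
                  [f"{l}\n{c}" for l, c in piv.columns], fontsize=7)
    fig.colorbar(im, ax=ax, label="paired t")
    ax.set_title("Time-frequency ROI contrasts (t statistics)")
    p = out_dir / "fig_roi.png"
    fig.savefig(p, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return "Induced-power ROI contrasts", p


def _fig_ies(results_dir: Path, clusters: pd.DataFrame):
    diff = np.load(results_dir / "ies_diff_maps.npy").mean(axis=0)
    fig, ax = plt.subplots(figsize=(10, 4))
    lim = max(1e-9, np.abs(diff).max())
    im = ax.imshow(diff, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim,
                   extent=(2, 101, diff.shape[0] + 0.5, 0.5))
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("kept contact (superficial to deep)")
    note = ""
    if len(clusters) and clusters["significant"].any():
        note = " (significant cluster(s) present; see table)"
    ax.set_title("Deviant - control seed-referenced IES" + note)
    fig.colorbar(im, ax=ax, label="delta IES")
    p = results_dir / "fig_ies.png"
    fig.savefig(p, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return "Inter-electrode synchrony difference", p
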