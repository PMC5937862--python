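"""Optional QC figures: PCA biplot, dendrogram, SOM layer maps, bands, radar.

All figures are side artifacts of the pipeline; nothing downstream depends
on them.  The SOM panels mirror the usual super-SOM presentation: one
hexagon heat map per element layer plus one panel with the class
background — ten panels for the default nine-element configuration.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from matplotlib.patches import RegularPolygon

CLASS_COLOURS = {
    "no deficiency": "#1a7a1a",
    "slight deficiency": "#8fd18f",
    "moderate deficiency": "#f5a623",
    "strong deficiency": "#d0342c",
    "Fe-specific deficiency": "#3a6fd8",
}


def _hex_panel(ax, model, values=None, labels=None, title=""):
    coords = model.grid_.coordinates()
    if values is not None:
        vmin, vmax = float(np.min(values)), float(np.max(values))
        span = (vmax - vmin) or 1.0
    for i, (x, y) in enumerate(coords):
        if values is not None:
            colour = plt.cm.viridis((values[i] - vmin) / span)
        else:
            colour = CLASS_COLOURS.get(labels[i], "#bbbbbb")
        ax.add_patch(RegularPolygon((x, y), numVertices=6, radius=0.55,
                                    orientation=np.pi / 6, facecolor=colour,
                                    edgecolor="white"))
    ax.set_xlim(-1, model.grid_.n_cols + 1)
    ax.set_ylim(-1, model.grid_.n_rows)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title, fontsize=9)


def som_panels(report, out_dir: Path) -> list[Path]:
    """One PNG per element layer plus one class panel (10 files by default)."""
    model = report.model
    lec = model.codebook_raw("LEC")
    paths = []
    for feat in lec.columns:
        fig, ax = plt.subplots(figsize=(4.5, 2.6))
        _hex_panel(ax, model, values=lec[feat].to_numpy(), title=feat)
        p = out_dir / f"som_LEC_{feat}.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    fig, ax = plt.subplots(figsize=(4.5, 2.6))
    _hex_panel(ax, model, labels=report.classmap.unit_labels, title="classes")
    p = out_dir / "som_classes.png"
    fig.savefig(p, dpi=110, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths


def pca_biplot(pca_model, out_path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    s = pca_model.scores_
    ax.scatter(s[:, 0], s[:, 1], s=12, alpha=0.6)
    scale = np.abs(s[:, :2]).max() * 0.9
    for name, (lx, ly) in zip(pca_model.feature_names_, pca_model.loadings_[:, :2]):
        ax.annotate("", xy=(lx * scale, ly * scale), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="crimson"))
        ax.text(lx * scale * 1.05, ly * scale * 1.05, name, fontsize=8)
    pv = pca_model.proportion_variance_
    ax.set_xlabel(f"PC1 ({100 * pv[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * pv[1]:.1f}%)")
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def dendrogram_plot(linkage, out_path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 3))
    sch.dendrogram(linkage, ax=ax, no_labels=True, color_threshold=0)
    ax.set_ylabel("height")
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def band_plot(band_curves: pd.DataFrame, out_path: Path) -> None:
    phases = list(band_curves["phase"].unique())
    fig, axes = plt.subplots(1, len(phases), figsize=(3.2 * len(phases), 2.8))
    axes = np.atleast_1d(axes)
    for ax, phase in zip(axes, phases):
        sub = band_curves[band_curves["phase"] == phase]
        for cls, grp in sub.groupby("group"):
            ax.semilogx(grp["time_s"], grp["delta_W"], label=cls,
                        color=CLASS_COLOURS.get(cls, "grey"))
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(phase, fontsize=9)
        ax.set_xlabel("time (s)")
    axes[0].set_ylabel(r"$\Delta W$")
    axes[-1].legend(fontsize=6)
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def jip_radar(samples: pd.DataFrame, features, out_path: Path) -> None:
    """Radar chart of per-class JIP means, each feature divided by its max."""
    means = samples.groupby("class")[list(features)].mean()
    norm = means / means.max(axis=0)
    angles = np.linspace(0, 2 * np.pi, len(features), endpoint=False)
    fig, ax = plt.subplots(figsize=(4.5, 4.5), subplot_kw={"polar": True})
    for cls, row in norm.iterrows():
        vals = np.concatenate([row.to_numpy(), row.to_numpy()[:1]])
        ax.plot(np.concatenate([angles, angles[:1]]), vals,
                label=cls, color=CLASS_COLOURS.get(cls, "grey"))
    ax.set_xticks(angles)
    ax.set_xticklabels(features, fontsize=7)
    ax.legend(fontsize=6, loc="lower right", bbox_to_anchor=(1.3, 0))
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def write_all(report, elements: pd.DataFrame, out: Path, pca_model, km) -> None:
    plots_dir = Path(out) / "plots"
    plots_dir.mkdir(exist_ok=True)
    som_panels(report, plots_dir)
    pca_biplot(pca_model, plots_dir / "pca_biplot.png")
    dendrogram_plot(km.linkage_, plots_dir / "dendrogram.png")
    curves_path = Path(out) / "band_curves.csv"
    if curves_path.exists():
        band_plot(pd.read_csv(curves_path), plots_dir / "bands.png")
    chlf_features = [c for c in report.samples.columns
                     if c in ("F_o", "M_o", "PI_total", "delta_Ro", "phi_Po",
                              "phi_Ro", "phi_Eo", "gamma_RC")]
    jip_radar(report.samples, chlf_features, plots_dir / "jip_radar.png")
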