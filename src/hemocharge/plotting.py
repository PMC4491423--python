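"""Diagnostic plots: conservation and dN-dS tracks, titration curves, PCA
scatter. All functions take an Axes or create one; ``report_plots`` writes
the standard set for an analysis report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .charge import ChargeProfile


def conservation_track(per_site, ax=None):
    ax = ax or plt.subplots(figsize=(8, 2.5))[1]
    ax.plot(per_site.canonical_position, per_site.windowed_jsd, lw=0.8, color="tab:blue")
    ax.set_xlabel("canonical position")
    ax.set_ylabel("windowed JSD")
    ax.set_ylim(0, 1)
    return ax


def dnds_track(per_site, ax=None):
    ax = ax or plt.subplots(figsize=(8, 2.5))[1]
    ax.bar(per_site.canonical_position, per_site.dnds_diff_norm, width=1.0, color="tab:gray")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("canonical position")
    ax.set_ylabel("(dN - dS) / T")
    return ax


def titration_plot(profiles: list[ChargeProfile], reference_ph: float = 7.27, ax=None):
    ax = ax or plt.subplots(figsize=(5, 4))[1]
    for prof in profiles:
        ax.plot(prof.ph_grid, prof.net_charge, label=prof.label or None)
    ax.axvline(reference_ph, ls="--", color="k", lw=0.8)
    ax.set_xlabel("pH")
    ax.set_ylabel("net charge (e)")
    if any(p.label for p in profiles):
        ax.legend(fontsize=8)
    return ax


def pca_scatter(scores, ax=None):
    ax = ax or plt.subplots(figsize=(5, 4))[1]
    for climate, group in scores.groupby("climate"):
        ax.scatter(group.PC1, group.PC2, s=14, label=climate)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    return ax


def report_plots(report, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    written: list[Path] = []
    if report.per_site is not None and "windowed_jsd" in report.per_site:
        ax = conservation_track(report.per_site.dropna(subset=["windowed_jsd"]))
        ax.figure.savefig(out / "conservation.png", dpi=100, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(out / "conservation.png")
    if report.per_site is not None and "dnds_diff_norm" in report.per_site:
        ax = dnds_track(report.per_site.dropna(subset=["dnds_diff_norm"]))
        ax.figure.savefig(out / "dnds.png", dpi=100, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(out / "dnds.png")
    if report.pca_scores is not None and "PC2" in report.pca_scores:
        ax = pca_scatter(report.pca_scores)
        ax.figure.savefig(out / "pca.png", dpi=100, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(out / "pca.png")
    return written
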