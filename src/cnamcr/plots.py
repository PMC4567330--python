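"""Static figures: genome-wide aberration frequency, call-length density,
and the sample dendrogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .common_regions import coverage_matrix
from .types import ProbeDesign

__all__ = ["plot_frequency", "plot_length_density", "plot_dendrogram"]


def plot_frequency(calls_by_sample, design: ProbeDesign, path) -> None:
    """Per-probe gain/loss frequency across the cohort, gains up, losses
    down, chromosome boundaries marked."""
    n = max(len(calls_by_sample), 1)
    _, gains = coverage_matrix(calls_by_sample, design, "gain")
    _, losses = coverage_matrix(calls_by_sample, design, "loss")
    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(design.n_probes)
    ax.fill_between(x, gains.sum(axis=0) / n, 0, color="firebrick", label="gain")
    ax.fill_between(x, -losses.sum(axis=0) / n, 0, color="seagreen", label="loss")
    for sl in design.chrom_slices().values():
        ax.axvline(sl.stop - 0.5, color="grey", lw=0.5)
    ax.set_xlabel("probe index (chromosomes in order)")
    ax.set_ylabel("aberration frequency")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_length_density(calls, path) -> None:
    """Log10 length density of gain and loss calls."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for direction, color in (("gain", "firebrick"), ("loss", "seagreen")):
        lengths = np.array([c.length for c in calls if c.direction == direction])
        if len(lengths) >= 2:
            ax.hist(np.log10(lengths), bins=30, density=True, alpha=0.5,
                    color=color, label=direction)
    ax.set_xlabel("log10 aberration length (bp)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(cluster_result: dict, path) -> None:
    """Render the linkage from :func:`cnamcr.clinical.cluster_samples`."""
    fig, ax = plt.subplots(figsize=(6, max(3, 0.2 * len(cluster_result["samples"]))))
    hierarchy.dendrogram(
        cluster_result["linkage"],
        labels=cluster_result["samples"],
        orientation="right",
        ax=ax,
    )
    ax.set_xlabel("distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
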