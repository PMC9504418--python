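"""Minimal matplotlib renderings of the standard MET stability views.

These are working plots for reports, not publication figures: box plots of
genotype means, the AMMI1 biplot (main effect vs IPCA1) and the GGE polygon
with its sector rays.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .ammi import AMMIModel
from .gge import GGEModel, SectorPartition


def boxplot_traits(trait_values: dict[str, np.ndarray], path) -> None:
    fig, ax = plt.subplots(figsize=(1.2 * len(trait_values) + 2, 4))
    ax.boxplot(list(trait_values.values()), tick_labels=list(trait_values.keys()))
    ax.set_ylabel("genotype mean")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ammi1_biplot(model: AMMIModel, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.axvline(model.grand_mean, color="grey", lw=0.6)
    gx = model.grand_mean + model.genotype_effects
    gy = model.genotype_scores[:, 0] if model.n_axes else np.zeros(len(gx))
    ex = model.grand_mean + model.environment_effects
    ey = model.environment_scores[:, 0] if model.n_axes else np.zeros(len(ex))
    ax.scatter(gx, gy, s=12, color="tab:blue")
    for name, x, y in zip(model.genotypes, gx, gy):
        ax.annotate(name, (x, y), fontsize=5)
    ax.scatter(ex, ey, marker="^", s=40, color="tab:red")
    for name, x, y in zip(model.environments, ex, ey):
        ax.annotate(name, (x, y), fontsize=8, color="tab:red")
    ax.set_xlabel("main effect (mean)")
    ax.set_ylabel("IPCA1 score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def gge_polygon(model: GGEModel, partition: SectorPartition, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    G, E = model.genotype_markers, model.environment_markers
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.axvline(0.0, color="grey", lw=0.6)
    ax.scatter(G[:, 0], G[:, 1], s=12, color="tab:blue")
    for name, (x, y) in zip(model.genotypes, G):
        ax.annotate(name, (x, y), fontsize=5)
    ax.scatter(E[:, 0], E[:, 1], marker="^", s=40, color="tab:red")
    for name, (x, y) in zip(model.environments, E):
        ax.annotate(name, (x, y), fontsize=8, color="tab:red")
    hull_idx = [model.genotypes.index(v) for v in partition.hull_vertices]
    poly = G[hull_idx + hull_idx[:1]]
    ax.plot(poly[:, 0], poly[:, 1], color="tab:green", lw=1)
    rmax = 1.1 * float(np.abs(np.concatenate([G, E])).max())
    for angle in partition.ray_angles:
        ax.plot(
            [0, rmax * np.cos(angle)], [0, rmax * np.sin(angle)],
            color="tab:green", lw=0.7, ls="--",
        )
    ax.set_xlabel(f"PC1 ({100 * model.singular_values[0]**2 / (model.singular_values @ model.singular_values):.1f}%)")
    ax.set_ylabel("PC2")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
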