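"""Packaged reference dataset: a 26-hybrid rice trial at three Bangladeshi
locations (Barisal, Gazipur, Ishwardi), one wide table of cell means per
trait plus the marginal statistics as printed in the source report.

The printed overall means, phenotypic indices (Pi), regression statistics
(bi, S2di) and marginal rows (Mean, Ij, CV%, LSD) are kept verbatim —
including several transcription errors present in the published tables —
so they serve as *claims* for :func:`metstab.core.validate_means_table`,
while the cell matrices are the analysis input.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .core import TraitMeans

ENVIRONMENTS = ["Barisal", "Gazipur", "Ishwardi"]

TRAITS = [
    "days_to_maturity",
    "plant_height",
    "effective_tillers",
    "spikelet_fertility",
    "panicle_length",
    "flag_leaf_length",
    "thousand_grain_weight",
    "grain_yield",
]

#: printed sample skewness / excess kurtosis per trait (classification
#: inputs; not recomputable from cell means alone)
PRINTED_MOMENTS = {
    "days_to_maturity": (0.44, -0.49),
    "plant_height": (1.71, 3.24),
    "effective_tillers": (-1.69, 4.47),
    "spikelet_fertility": (0.09, 0.18),
    "panicle_length": (0.25, -0.17),
    "flag_leaf_length": (-0.19, -1.19),
    "thousand_grain_weight": (-0.41, -0.18),
    "grain_yield": (-0.08, -0.21),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("metstab.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_printed_table(trait: str) -> pd.DataFrame:
    """Full printed table: cells plus overall_mean, pi, bi, s2di columns."""
    if trait not in TRAITS:
        raise KeyError(f"unknown trait {trait!r}; choose from {TRAITS}")
    return _read(f"{trait}.csv")


def load_printed_marginals(trait: str) -> pd.DataFrame:
    """Printed Mean / Ij / CV% / LSD rows, indexed by statistic."""
    if trait not in TRAITS:
        raise KeyError(f"unknown trait {trait!r}; choose from {TRAITS}")
    return _read(f"{trait}_marginals.csv").set_index("statistic")


def load_trait_means(trait: str) -> TraitMeans:
    """Cell-mean matrix for one trait (marginals recomputed, not printed)."""
    df = load_printed_table(trait)
    return TraitMeans(
        trait,
        df["genotype"].tolist(),
        ENVIRONMENTS,
        df[ENVIRONMENTS].to_numpy(dtype=float),
    )


def printed_claims(trait: str) -> dict:
    """Printed marginal claims in validate_means_table-ready form."""
    df = load_printed_table(trait)
    marg = load_printed_marginals(trait)
    env_means = marg.loc["mean", ENVIRONMENTS].astype(float).to_numpy()
    grand = float(marg.loc["mean", "overall"])
    ij = marg.loc["ij", ENVIRONMENTS].astype(float).to_numpy()
    return {
        "genotype_means": df["overall_mean"].to_numpy(dtype=float),
        "pi": df["pi"].to_numpy(dtype=float),
        "bi": df["bi"].to_numpy(dtype=float),
        "s2di": df["s2di"].to_numpy(dtype=float),
        "environment_means": env_means,
        "grand_mean": grand,
        "ij": ij,
        "cv_percent": marg.loc["cv_percent", ENVIRONMENTS].astype(float).to_numpy(),
        "lsd_05": marg.loc["lsd_05", ENVIRONMENTS].astype(float).to_numpy(),
    }
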