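"""AMMI: additive main effects and multiplicative interaction.

The cell-mean matrix is decomposed as

    Y_ij = mu + g_i + e_j + sum_k lambda_k alpha_ik gamma_jk + residual,

where the multiplicative part is the SVD of the doubly-centered interaction
residual GE_ij = Y_ij - genotype mean - environment mean + grand mean.
Axis k explains lambda_k^2 / sum(lambda^2) of the interaction sum of
squares; the AMMI1 biplot plots main effects against the first interaction
principal component axis (IPCA1).  Genotypes with IPCA1 near zero interact
little with environments and are stable in the AMMI sense.

Sign convention: each axis is flipped so the environment carrying the
largest absolute loading on it loads positively — outputs are then
deterministic across SVD backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TraitMeans


@dataclass
class AMMIModel:
    genotypes: list[str]
    environments: list[str]
    grand_mean: float
    genotype_effects: np.ndarray     # g
    environment_effects: np.ndarray  # e
    interaction: np.ndarray          # g x e, rows and columns sum to 0
    singular_values: np.ndarray      # descending, K = min(g-1, e-1)
    genotype_scores: np.ndarray      # g x K, scaled by lambda^0.5
    environment_scores: np.ndarray   # e x K, scaled by lambda^0.5
    genotype_loadings: np.ndarray    # g x K unit vectors (U)
    environment_loadings: np.ndarray # e x K unit vectors (V)
    explained: np.ndarray            # K shares of interaction SS

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


@dataclass
class AMMI1Coordinates:
    genotypes: list[str]
    environments: list[str]
    genotype_main_effect: np.ndarray
    genotype_ipca1: np.ndarray
    environment_main_effect: np.ndarray
    environment_ipca1: np.ndarray
    stable_genotypes: list[str]


def _sign_fix(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each axis so the largest-|loading| environment loads positively."""
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return u, vt


def fit_ammi(means: TraitMeans) -> AMMIModel:
    """Fit the full AMMI decomposition of a complete cell-mean matrix."""
    Y = means.matrix
    g, e = Y.shape
    grand = means.grand_mean
    gen_eff = means.genotype_means - grand
    env_eff = means.environment_means - grand
    interaction = Y - means.genotype_means[:, None] - means.environment_means[None, :] + grand
    K = min(g - 1, e - 1)
    u, s, vt = np.linalg.svd(interaction, full_matrices=False)
    u, s, vt = u[:, :K], s[:K], vt[:K]
    u, vt = _sign_fix(u, vt)
    ss_int = float(s @ s)
    explained = (s**2 / ss_int) if ss_int > 0 else np.zeros(K)
    scale = np.sqrt(s)
    return AMMIModel(
        genotypes=list(means.genotypes),
        environments=list(means.environments),
        grand_mean=grand,
        genotype_effects=gen_eff,
        environment_effects=env_eff,
        interaction=interaction,
        singular_values=s,
        genotype_scores=u * scale,
        environment_scores=vt.T * scale,
        genotype_loadings=u,
        environment_loadings=vt.T,
        explained=explained,
    )


def ammi1_coordinates(
    model: AMMIModel, means: TraitMeans, stable_fraction: float = 0.25
) -> AMMI1Coordinates:
    """(main effect, IPCA1) pairs for the AMMI1 biplot.

    Genotypes whose |IPCA1| is below ``stable_fraction`` of the IPCA1 range
    are labeled stable.
    """
    g_ipca1 = model.genotype_scores[:, 0] if model.n_axes else np.zeros(len(model.genotypes))
    e_ipca1 = model.environment_scores[:, 0] if model.n_axes else np.zeros(len(model.environments))
    span = float(np.max(np.abs(g_ipca1))) if len(g_ipca1) else 0.0
    threshold = stable_fraction * span
    stable = [
        name
        for name, v in zip(model.genotypes, g_ipca1)
        if abs(v) <= threshold or span == 0.0
    ]
    return AMMI1Coordinates(
        genotypes=list(model.genotypes),
        environments=list(model.environments),
        genotype_main_effect=model.genotype_effects,
        genotype_ipca1=g_ipca1,
        environment_main_effect=model.environment_effects,
        environment_ipca1=e_ipca1,
        stable_genotypes=stable,
    )


def scores_frame(model: AMMIModel):
    """Long table of main effects and the first two IPCA scores."""
    import pandas as pd

    def block(names, effects, scores, kind):
        k = scores.shape[1]
        return pd.DataFrame(
            {
                "entity": names,
                "type": kind,
                "main_effect": effects,
                "ipca1": scores[:, 0] if k >= 1 else 0.0,
                "ipca2": scores[:, 1] if k >= 2 else 0.0,
            }
        )

    df = pd.concat(
        [
            block(model.genotypes, model.genotype_effects, model.genotype_scores, "genotype"),
            block(
                model.environments,
                model.environment_effects,
                model.environment_scores,
                "environment",
            ),
        ],
        ignore_index=True,
    )
    df["explained1"] = model.explained[0] if model.n_axes >= 1 else 0.0
    df["explained2"] = model.explained[1] if model.n_axes >= 2 else 0.0
    return df
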