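"""Synthetic multi-environment-trial generator.

Plot values follow the model every analysis in this package assumes:

    Y_ijk = mu + g_i + e_j + GE_ij + eps_ijk,    eps ~ N(0, error_sd^2)

with three interaction structures:

* ``none`` — purely additive;
* ``low_rank`` — GE = sum_k lambda_k alpha_k gamma_k' with factor vectors
  orthonormal and orthogonal to the constant vector, so GE rows and columns
  sum to zero exactly (the AMMI model holds with a known spectrum);
* ``regression`` — GE_ij = (b_i - 1) e_j, so that with the environmental
  index I_j = e_j the joint-regression model Y_ij = m_i + b_i I_j holds
  exactly (when mean(b) = 1; otherwise slopes are recovered up to the
  common rescaling that restores mean slope 1).

Default dimensions and scales mirror a typical rice hybrid yield trial:
26 genotypes x 3 locations x 3 replicates, grand mean ~8.7 t/ha, genotype
effect SD 0.5, environment effect SD 0.17, plot error SD 0.28 (a pooled
error mean square of ~0.08).

All randomness flows through one ``numpy.random.Generator`` seeded from
``config.seed``; the same seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import METDataset
from .exceptions import MetstabError


@dataclass
class SyntheticConfig:
    g: int = 26
    e: int = 3
    r: int = 3
    trait: str = "yield"
    grand_mean: float = 8.7
    genotype_effect_sd: float = 0.5
    environment_effect_sd: float = 0.17
    genotype_effects: Sequence[float] | None = None     # overrides the SD draw
    environment_effects: Sequence[float] | None = None  # overrides the SD draw
    interaction_mode: str = "low_rank"                  # none | low_rank | regression
    interaction_rank: int | None = None                 # None = min(2, g-1, e-1)
    interaction_singular_values: Sequence[float] = (2.7, 1.1)
    regression_slopes: Sequence[float] | None = None
    error_sd: float = 0.28
    seed: int = 0

    def __post_init__(self):
        if min(self.g, self.e) < 2 or self.r < 1:
            raise MetstabError("need g >= 2, e >= 2, r >= 1")
        if self.interaction_mode not in ("none", "low_rank", "regression"):
            raise MetstabError(f"unknown interaction mode {self.interaction_mode!r}")
        if self.interaction_mode == "low_rank":
            if self.interaction_rank is None:
                self.interaction_rank = min(2, self.g - 1, self.e - 1)
            if not 0 <= self.interaction_rank <= min(self.g - 1, self.e - 1):
                raise MetstabError(
                    "interaction_rank must lie in [0, min(g-1, e-1)]"
                )
            if len(self.interaction_singular_values) < self.interaction_rank:
                raise MetstabError("need one singular value per interaction axis")


def _centered_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n x k orthonormal columns, each orthogonal to the constant vector."""
    x = rng.standard_normal((n, k))
    x -= x.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(x)
    return q[:, :k]


def generate(config: SyntheticConfig) -> tuple[METDataset, dict]:
    """Draw one balanced trial; returns the dataset and the truth record."""
    rng = np.random.default_rng(config.seed)
    g, e, r = config.g, config.e, config.r

    if config.genotype_effects is not None:
        gen_eff = np.asarray(config.genotype_effects, dtype=float)
    else:
        gen_eff = rng.normal(0.0, config.genotype_effect_sd, g)
        gen_eff -= gen_eff.mean()
    if config.environment_effects is not None:
        env_eff = np.asarray(config.environment_effects, dtype=float)
    else:
        env_eff = rng.normal(0.0, config.environment_effect_sd, e)
        env_eff -= env_eff.mean()

    slopes = None
    if config.interaction_mode == "none":
        ge = np.zeros((g, e))
    elif config.interaction_mode == "low_rank":
        k = config.interaction_rank
        if k == 0:
            ge = np.zeros((g, e))
        else:
            alpha = _centered_orthonormal(rng, g, k)
            gamma = _centered_orthonormal(rng, e, k)
            lam = np.asarray(config.interaction_singular_values[:k], dtype=float)
            ge = (alpha * lam) @ gamma.T
    else:  # regression
        if config.regression_slopes is not None:
            slopes = np.asarray(config.regression_slopes, dtype=float)
        else:
            slopes = np.linspace(0.5, 1.5, g)
        if len(slopes) != g:
            raise MetstabError("regression_slopes must have length g")
        ge = np.outer(slopes - 1.0, env_eff)

    cell = config.grand_mean + gen_eff[:, None] + env_eff[None, :] + ge
    noise = np.zeros((g, e, r))
    if config.error_sd > 0:
        noise = rng.normal(0.0, config.error_sd, (g, e, r))
    values = cell[:, :, None] + noise

    genotypes = [f"G{i + 1:02d}" for i in range(g)]
    environments = [f"E{j + 1}" for j in range(e)]
    data = METDataset.from_arrays(values, genotypes, environments, config.trait)
    truth = {
        "config": config,
        "grand_mean": config.grand_mean,
        "genotype_effects": gen_eff,
        "environment_effects": env_eff,
        "interaction": ge,
        "regression_slopes": slopes,
        "cell_expectations": cell,
    }
    return data, truth
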