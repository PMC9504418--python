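"""Eberhart-Russell joint-regression stability analysis.

For genotype i with cell means Y_ij over environments j, the model is

    Y_ij = m_i + b_i * I_j + delta_ij,

where I_j = environment mean - grand mean is the environmental index
(sums to zero), b_i the regression of the genotype's response on the index
(b_i = 1 means average responsiveness), and the deviation mean square
ms_dev = sum(delta^2)/(e-2) measures departure from linear response.

Two conventions for the published stability statistic S2di coexist in the
literature: the textbook one subtracts the pooled plot-error contribution
(ms_dev - s2_e/r); many published tables simply print ms_dev.  Both are
returned; ``s2di_paper`` (= ms_dev) is the reproduction default.

The phenotypic index Pi = genotype mean - grand mean expresses desirability;
the verbal stability call combines sign(Pi), sign(b_i) and the significance
of b_i vs 1 and of the deviation mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import TraitMeans
from .exceptions import DegenerateDataError, InsufficientDataError


@dataclass
class EnvironmentIndexSet:
    environments: list[str]
    index: np.ndarray  # I_j, sums to zero


@dataclass
class StabilityCall:
    label: str          # stable | stable_specific | responsive_favorable |
                        # responsive_poor | unpredictable
    desirability: str   # above_average | below_average


@dataclass
class ERGenotypeResult:
    genotype: str
    mean: float
    pi: float
    bi: float
    se_bi: float
    ms_dev: float
    s2di_paper: float
    s2di_textbook: float | None
    t_bi_vs_1: float
    p_bi: float
    f_dev: float | None
    p_dev: float | None
    call: StabilityCall | None = None


def environment_index(means: TraitMeans) -> EnvironmentIndexSet:
    """I_j = environment mean - grand mean; negative = poor environment."""
    idx = means.environment_means - means.grand_mean
    return EnvironmentIndexSet(list(means.environments), idx)


def phenotypic_index(means: TraitMeans) -> np.ndarray:
    """Pi = genotype mean - grand mean (sums to zero over genotypes)."""
    return means.genotype_means - means.grand_mean


def joint_regression(
    means: TraitMeans,
    error_ms: float | None = None,
    r: int = 3,
    alpha: float = 0.05,
    df_error: int | None = None,
    test_bi_against: float = 1.0,
    classify: bool = True,
) -> list[ERGenotypeResult]:
    """Fit the joint regression for every genotype of a complete means matrix.

    Parameters
    ----------
    error_ms:
        Pooled plot-error mean square from the combined ANOVA.  Enables the
        textbook S2di and the F test of the deviation mean square; without
        it both are ``None`` and deviation significance is treated as
        non-assessable (non-significant) in the stability call.
    r:
        Replicates per cell (the means are averages of r plots).
    df_error:
        Error df for the deviation F test; defaults to e*(g-1)*(r-1).
    test_bi_against:
        Null value for the t test on b_i (1 = average responsiveness).
    """
    e = means.n_environments
    if e < 3:
        raise InsufficientDataError(
            "joint regression needs e >= 3 environments (deviation df = e - 2)"
        )
    Ij = environment_index(means).index
    ss_index = float(Ij @ Ij)
    if ss_index <= 0:
        raise DegenerateDataError("all environment means identical: index degenerate")
    grand = means.grand_mean
    if df_error is None:
        df_error = e * (means.n_genotypes - 1) * (r - 1)

    results = []
    for i, name in enumerate(means.genotypes):
        y = means.matrix[i]
        m_i = float(y.mean())
        dev = y - m_i
        bi = float(dev @ Ij / ss_index)
        delta = dev - bi * Ij
        ms_dev = float(delta @ delta / (e - 2))
        se_bi = float(np.sqrt(ms_dev / ss_index))
        if se_bi > 0:
            t_bi = (bi - test_bi_against) / se_bi
            p_bi = float(2 * stats.t.sf(abs(t_bi), e - 2))
        else:  # perfect fit: any departure from the null is exact
            t_bi = np.inf if bi != test_bi_against else 0.0
            p_bi = 0.0 if bi != test_bi_against else 1.0
        s2di_textbook = f_dev = p_dev = None
        if error_ms is not None:
            s2di_textbook = ms_dev - error_ms / r
            if error_ms > 0:
                f_dev = ms_dev / (error_ms / r)
                p_dev = float(stats.f.sf(f_dev, e - 2, df_error))
        res = ERGenotypeResult(
            genotype=name,
            mean=m_i,
            pi=m_i - grand,
            bi=bi,
            se_bi=se_bi,
            ms_dev=ms_dev,
            s2di_paper=ms_dev,
            s2di_textbook=s2di_textbook,
            t_bi_vs_1=float(t_bi),
            p_bi=p_bi,
            f_dev=f_dev,
            p_dev=p_dev,
        )
        if classify:
            res.call = classify_stability(res, alpha)
        results.append(res)
    return results


def classify_stability(result: ERGenotypeResult, alpha: float = 0.05) -> StabilityCall:
    """Deterministic verbal call from (sign(Pi), sign(bi), p_bi, p_dev).

    Precedence: a negative slope marks a genotype suited only to poor
    environments; a significant deviation MS invalidates linear prediction
    (unpredictable); a significant slope above 1 marks response to
    favorable environments, a significant slope below 1 specific (below-
    average) response; otherwise the genotype is stable.  Desirability is
    the sign of Pi.  With e = 3 these tests have a single deviation df and
    low power; treat non-significance accordingly.
    """
    desirability = "above_average" if result.pi >= 0 else "below_average"
    dev_significant = result.p_dev is not None and result.p_dev < alpha
    bi_significant = result.p_bi < alpha
    if result.bi < 0:
        label = "responsive_poor"
    elif dev_significant:
        label = "unpredictable"
    elif bi_significant and result.bi > 1:
        label = "responsive_favorable"
    elif bi_significant:
        label = "stable_specific"
    else:
        label = "stable"
    return StabilityCall(label=label, desirability=desirability)


def results_frame(results: list[ERGenotypeResult]):
    """Tabulate joint-regression results as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "genotype": r.genotype,
                "mean": r.mean,
                "pi": r.pi,
                "bi": r.bi,
                "se_bi": r.se_bi,
                "ms_dev": r.ms_dev,
                "s2di_paper": r.s2di_paper,
                "s2di_textbook": r.s2di_textbook,
                "t_bi": r.t_bi_vs_1,
                "p_bi": r.p_bi,
                "f_dev": r.f_dev,
                "p_dev": r.p_dev,
                "call": r.call.label if r.call else None,
                "desirability": r.call.desirability if r.call else None,
            }
            for r in results
        ]
    )
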