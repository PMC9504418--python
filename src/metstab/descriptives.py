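"""Descriptive statistics for breeding-trial traits.

Five-number box-plot summaries with the 1.5*IQR whisker/outlier rule,
moment statistics (sample skewness and excess kurtosis, spreadsheet
conventions) with distribution-shape labels, Shapiro-Wilk normality testing
and histogram binning.

Quantiles default to linear interpolation at ``p*(n-1)`` (the spreadsheet /
"type 7" convention), because that is what the original trial analyses used;
Tukey hinges are available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, InsufficientDataError

#: half-width of the "symmetric"/"mesokurtic" dead band on skewness and
#: excess kurtosis; values within +/- EPS of zero are called shapeless.
DEFAULT_DEAD_BAND = 0.2


@dataclass
class FiveNumberSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    outliers: list[tuple[str, float]]


@dataclass
class MomentsSummary:
    n: int
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    skew_label: str
    kurtosis_label: str


@dataclass
class NormalityResult:
    statistic_w: float
    p_value: float
    alpha: float
    normal_at_alpha: bool


@dataclass
class HistogramSpec:
    bin_edges: np.ndarray
    counts: np.ndarray


def _quartiles(x: np.ndarray, method: str) -> tuple[float, float, float]:
    if method == "type7":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
    elif method == "tukey_hinges":
        xs = np.sort(x)
        n = len(xs)
        med = float(np.median(xs))
        half = (n + 1) // 2
        q1 = float(np.median(xs[:half]))
        q3 = float(np.median(xs[n - half:]))
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    return float(q1), float(med), float(q3)


def five_number_summary(
    values: Sequence[float],
    labels: Sequence[str] | None = None,
    quantile_method: str = "type7",
) -> FiveNumberSummary:
    """Box-plot summary: quartiles, 1.5*IQR whiskers, labeled outliers.

    Whiskers are the most extreme data points *inside* the fences
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``; points beyond the fences are outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("five-number summary needs n >= 4")
    if not np.all(np.isfinite(x)):
        raise DegenerateDataError("values must be finite")
    if labels is None:
        labels = [str(i) for i in range(x.size)]
    q1, med, q3 = _quartiles(x, quantile_method)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = [
        (lab, float(v)) for lab, v in zip(labels, x) if v < lo_fence or v > hi_fence
    ]
    return FiveNumberSummary(
        min=float(x.min()),
        q1=q1,
        median=med,
        q3=q3,
        max=float(x.max()),
        iqr=iqr,
        lower_whisker=float(inside.min()),
        upper_whisker=float(inside.max()),
        outliers=outliers,
    )


def classify_shape(
    skewness: float, excess_kurtosis: float, dead_band: float = DEFAULT_DEAD_BAND
) -> tuple[str, str]:
    """Map (skewness, excess kurtosis) to verbal shape labels.

    Leptokurtic (peaked) iff excess kurtosis > dead_band, platykurtic (flat)
    iff < -dead_band, mesokurtic otherwise; analogous bands for skew.
    """
    if skewness > dead_band:
        skew_label = "right-skewed"
    elif skewness < -dead_band:
        skew_label = "left-skewed"
    else:
        skew_label = "symmetric"
    if excess_kurtosis > dead_band:
        kurt_label = "leptokurtic"
    elif excess_kurtosis < -dead_band:
        kurt_label = "platykurtic"
    else:
        kurt_label = "mesokurtic"
    return skew_label, kurt_label


def moments_summary(
    values: Sequence[float],
    dead_band: float = DEFAULT_DEAD_BAND,
    bias_corrected: bool = True,
) -> MomentsSummary:
    """Mean, SD, sample skewness and excess kurtosis with shape labels.

    With ``bias_corrected=True`` (default) the adjusted Fisher-Pearson
    skewness n/((n-1)(n-2)) * sum(z^3) and the analogously corrected excess
    kurtosis are used — the spreadsheet SKEW/KURT definitions.  The raw
    moment estimators are available with ``bias_corrected=False``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("moment summary needs n >= 4")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("zero variance: skewness/kurtosis undefined")
    skew = float(stats.skew(x, bias=not bias_corrected))
    kurt = float(stats.kurtosis(x, fisher=True, bias=not bias_corrected))
    skew_label, kurt_label = classify_shape(skew, kurt, dead_band)
    return MomentsSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=sd,
        skewness=skew,
        excess_kurtosis=kurt,
        skew_label=skew_label,
        kurtosis_label=kurt_label,
    )


def shapiro_wilk(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality test (Royston approximation via scipy)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InsufficientDataError("Shapiro-Wilk supports 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("all values identical: W undefined")
    w, p = stats.shapiro(x)
    return NormalityResult(float(w), float(p), alpha, bool(p > alpha))


def histogram(values: Sequence[float], bins: int | str = "sturges") -> HistogramSpec:
    """Equal-width histogram over [min, max]; last bin right-inclusive.

    ``bins`` may be a positive integer or one of the rules ``"sturges"`` /
    ``"fd"``.  Constant data falls back to a single unit-width bin.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise InsufficientDataError("histogram needs n >= 1")
    if isinstance(bins, str):
        if bins not in ("sturges", "fd"):
            raise ValueError(f"unknown binning rule {bins!r}")
    elif bins < 1:
        raise ValueError("n_bins must be >= 1")
    if np.ptp(x) == 0.0:
        edges = np.array([x[0] - 0.5, x[0] + 0.5])
        return HistogramSpec(edges, np.array([x.size]))
    counts, edges = np.histogram(x, bins=bins)
    return HistogramSpec(edges, counts)
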