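"""Combined and per-location ANOVA for balanced RCBD multi-environment trials.

The combined model partitions the total sum of squares into Location,
Variety, Location x Rep (replicates nested in locations), Location x Variety
and Error.  All effects are fixed and every F statistic is tested against
the pooled error mean square, which is the convention used in classical MET
reports (a mixed-model analysis would test Location against Location x Rep).

Per-location summaries report the RCBD error mean square, the coefficient of
variation CV% = 100 * sqrt(MSE) / mean, and the least significant difference
LSD = t(1 - alpha/2, df_err) * sqrt(2 * MSE / r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import METDataset
from .exceptions import InsufficientDataError, UnbalancedDesignError


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    f: float | None
    p: float | None

    @property
    def stars(self) -> str:
        if self.p is None:
            return ""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return "ns"


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    total_df: int
    total_ss: float

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self):
        import pandas as pd

        records = [
            (r.source, r.df, r.ss, r.ms, r.f, r.p, r.stars) for r in self.rows
        ]
        records.append(("Total", self.total_df, self.total_ss, None, None, None, ""))
        return pd.DataFrame(
            records, columns=["source", "df", "ss", "ms", "f", "p", "stars"]
        )


@dataclass
class LocationSummary:
    environment: str
    mean: float
    mse: float
    cv_percent: float
    lsd_alpha: float
    lsd: float


def _cube(data: METDataset, trait: str) -> np.ndarray:
    """Pivot a balanced single-trait dataset into a g x e x r value cube."""
    tab = data.table
    tab = tab[tab["trait"] == trait]
    if tab.empty:
        raise InsufficientDataError(f"trait {trait!r} not present")
    genotypes, environments = data.genotypes, data.environments
    reps = sorted(tab["replicate"].unique())
    g, e, r = len(genotypes), len(environments), len(reps)
    if len(tab) != g * e * r:
        raise UnbalancedDesignError(
            f"expected {g * e * r} observations for a balanced "
            f"{g}x{e}x{r} design, found {len(tab)}"
        )
    gi = {name: i for i, name in enumerate(genotypes)}
    ej = {name: j for j, name in enumerate(environments)}
    rk = {rep: k for k, rep in enumerate(reps)}
    cube = np.full((g, e, r), np.nan)
    cube[
        tab["genotype"].map(gi), tab["environment"].map(ej), tab["replicate"].map(rk)
    ] = tab["value"].to_numpy()
    if not np.all(np.isfinite(cube)):
        raise UnbalancedDesignError("missing cells in nominally balanced design")
    return cube


def _f_test(ms: float, ms_err: float, df: int, df_err: int):
    if ms_err <= 0:
        return None, None
    f = ms / ms_err
    return float(f), float(stats.f.sf(f, df, df_err))


def combined_anova(
    data: METDataset, trait: str, log_transform: bool = False
) -> AnovaTable:
    """Combined fixed-effects ANOVA across locations for one trait.

    ``log_transform`` applies natural log before the decomposition, the usual
    remedy for traits failing normality.
    """
    y = _cube(data, trait)
    if log_transform:
        y = np.log(y)
    g, e, r = y.shape
    if r < 2:
        raise InsufficientDataError("combined ANOVA needs r >= 2 for an error term")
    grand = y.mean()
    env_m = y.mean(axis=(0, 2))           # e
    gen_m = y.mean(axis=(1, 2))           # g
    cell_m = y.mean(axis=2)               # g x e
    rep_in_env_m = y.mean(axis=0)         # e x r

    ss_total = float(((y - grand) ** 2).sum())
    ss_loc = float(g * r * ((env_m - grand) ** 2).sum())
    ss_var = float(e * r * ((gen_m - grand) ** 2).sum())
    ss_loc_rep = float(g * ((rep_in_env_m - env_m[:, None]) ** 2).sum())
    ss_int = float(
        r * ((cell_m - gen_m[:, None] - env_m[None, :] + grand) ** 2).sum()
    )
    ss_err = ss_total - ss_loc - ss_var - ss_loc_rep - ss_int

    df_loc, df_var = e - 1, g - 1
    df_loc_rep = e * (r - 1)
    df_int = (e - 1) * (g - 1)
    df_err = e * (g - 1) * (r - 1)
    ms_err = ss_err / df_err

    rows = []
    for source, df, ss in [
        ("Location", df_loc, ss_loc),
        ("Variety", df_var, ss_var),
        ("Location x Rep", df_loc_rep, ss_loc_rep),
        ("Location x Variety", df_int, ss_int),
    ]:
        if df == 0:  # source vanishes (e.g. a single location)
            rows.append(AnovaRow(source, 0, ss, 0.0, None, None))
            continue
        ms = ss / df
        f, p = _f_test(ms, ms_err, df, df_err)
        rows.append(AnovaRow(source, df, ss, ms, f, p))
    rows.append(AnovaRow("Error", df_err, ss_err, ms_err, None, None))
    return AnovaTable(rows, total_df=g * e * r - 1, total_ss=ss_total)


def per_location_anova(
    data: METDataset,
    trait: str,
    environment: str,
    alpha: float = 0.05,
    lsd_df: str = "combined",
) -> tuple[AnovaTable, LocationSummary]:
    """RCBD ANOVA within one location plus its CV% / LSD summary.

    ``lsd_df`` selects the error df for the t quantile in the LSD:
    ``"combined"`` pools across all locations of ``data`` (the convention of
    the combined analysis), ``"local"`` uses the within-location (g-1)(r-1).
    """
    sub = data.subset_environment(environment)
    y = _cube(sub, trait)[:, 0, :]  # g x r
    g, r = y.shape
    if r < 2:
        raise InsufficientDataError("RCBD ANOVA needs r >= 2")
    grand = y.mean()
    gen_m = y.mean(axis=1)
    rep_m = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_rep = float(g * ((rep_m - grand) ** 2).sum())
    ss_gen = float(r * ((gen_m - grand) ** 2).sum())
    ss_err = ss_total - ss_rep - ss_gen
    df_rep, df_gen = r - 1, g - 1
    df_err_local = (g - 1) * (r - 1)
    ms_err = ss_err / df_err_local
    rows = []
    for source, df, ss in [("Replication", df_rep, ss_rep), ("Genotype", df_gen, ss_gen)]:
        ms = ss / df
        f, p = _f_test(ms, ms_err, df, df_err_local)
        rows.append(AnovaRow(source, df, ss, ms, f, p))
    rows.append(AnovaRow("Error", df_err_local, ss_err, ms_err, None, None))
    table = AnovaTable(rows, total_df=g * r - 1, total_ss=ss_total)

    if lsd_df == "combined":
        e_all = len(data.environments)
        df_t = e_all * (g - 1) * (r - 1)
    elif lsd_df == "local":
        df_t = df_err_local
    else:
        raise ValueError("lsd_df must be 'combined' or 'local'")
    t_crit = float(stats.t.ppf(1 - alpha / 2, df_t))
    lsd = t_crit * np.sqrt(2 * ms_err / r) if ms_err > 0 else 0.0
    cv = 100.0 * np.sqrt(ms_err) / grand if grand != 0 else np.inf
    summary = LocationSummary(
        environment=environment,
        mean=float(grand),
        mse=float(ms_err),
        cv_percent=float(cv),
        lsd_alpha=alpha,
        lsd=float(lsd),
    )
    return table, summary
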