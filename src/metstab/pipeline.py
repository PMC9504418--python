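"""End-to-end report assembly: validate -> describe -> ANOVA -> joint
regression -> AMMI -> GGE -> grain classification, one report set per trait.

Outputs are plain CSVs with deterministic column order; a run log records
the configuration, the seed and a SHA-256 digest of every input so a report
bundle can be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .ammi import ammi1_coordinates, fit_ammi, scores_frame
from .anova import combined_anova, per_location_anova
from .core import (
    METDataset,
    TraitMeans,
    cell_means,
    read_long_csv,
    validate_means_table,
)
from .descriptives import five_number_summary, moments_summary, shapiro_wilk
from .eberhart_russell import joint_regression, results_frame
from .exceptions import MetstabError
from .gge import (
    discriminativeness_representativeness,
    fit_gge,
    mean_vs_stability,
    rank_by_ideal,
    which_won_where,
)

log = logging.getLogger("metstab")


@dataclass
class PipelineConfig:
    output_dir: str = "metstab-report"
    long_csv: str | None = None            # replicate-level input
    means_csvs: dict[str, str] = field(default_factory=dict)  # trait -> wide CSV
    use_packaged_tables: bool = False      # analyse the packaged rice trial
    traits: list[str] | None = None        # None = all available
    alpha: float = 0.05
    quantile_method: str = "type7"
    partition_f: float = 0.5
    scale_by_env_sd: bool = False
    s2di_convention: str = "paper"         # paper | textbook
    reps: int = 3
    figures: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise MetstabError("alpha must lie in (0, 1)")
        if self.s2di_convention not in ("paper", "textbook"):
            raise MetstabError("s2di_convention must be 'paper' or 'textbook'")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _gather_means(config: PipelineConfig):
    """Yield (trait, TraitMeans, printed-claims-or-None, dataset-or-None)."""
    out = []
    data = None
    wanted = config.traits  # None = everything available; [] = nothing
    if config.long_csv:
        data = read_long_csv(config.long_csv)
        for trait in data.traits if wanted is None else wanted:
            out.append((trait, cell_means(data, trait), None, data))
    for trait, path in config.means_csvs.items():
        out.append((trait, TraitMeans.from_wide_csv(path, trait), None, None))
    if config.use_packaged_tables:
        for trait in datasets.TRAITS if wanted is None else wanted:
            out.append(
                (trait, datasets.load_trait_means(trait), datasets.printed_claims(trait), None)
            )
    if wanted is not None:
        out = [t for t in out if t[0] in wanted]
    return out, data


def _trait_report(trait, means, claims, data, config, outdir) -> None:
    # validation
    if claims is not None:
        report = validate_means_table(
            means,
            claimed_genotype_means=claims["genotype_means"],
            claimed_environment_means=claims["environment_means"],
            claimed_grand_mean=claims["grand_mean"],
        )
    else:
        report = validate_means_table(means)
    report.to_frame().to_csv(outdir / f"{trait}_validation.csv", index=False)
    for issue in report.issues:
        log.warning("%s: %s — %s", trait, issue.location, issue.message)

    # descriptives on genotype means
    gm = means.genotype_means
    fns = five_number_summary(gm, means.genotypes, config.quantile_method)
    mom = moments_summary(gm)
    norm = shapiro_wilk(gm, config.alpha)
    desc = {
        "n": mom.n, "mean": mom.mean, "sd": mom.sd,
        "min": fns.min, "q1": fns.q1, "median": fns.median, "q3": fns.q3,
        "max": fns.max, "iqr": fns.iqr,
        "lower_whisker": fns.lower_whisker, "upper_whisker": fns.upper_whisker,
        "n_outliers": len(fns.outliers),
        "outliers": ";".join(lab for lab, _ in fns.outliers),
        "skewness": mom.skewness, "excess_kurtosis": mom.excess_kurtosis,
        "skew_label": mom.skew_label, "kurtosis_label": mom.kurtosis_label,
        "shapiro_w": norm.statistic_w, "shapiro_p": norm.p_value,
        "normal": norm.normal_at_alpha,
    }
    pd.DataFrame([desc]).to_csv(outdir / f"{trait}_descriptives.csv", index=False)

    # replicate-level ANOVA when available
    error_ms = None
    if data is not None:
        table = combined_anova(data, trait)
        table.to_frame().to_csv(outdir / f"{trait}_anova.csv", index=False)
        error_ms = table["Error"].ms
        locs = []
        for env in data.environments:
            _, summary = per_location_anova(data, trait, env, alpha=config.alpha)
            locs.append(vars(summary))
        pd.DataFrame(locs).to_csv(outdir / f"{trait}_locations.csv", index=False)

    # joint regression
    er = joint_regression(means, error_ms=error_ms, r=config.reps, alpha=config.alpha)
    results_frame(er).to_csv(
        outdir / f"{trait}_stability.csv", index=False, float_format="%.4f"
    )

    # AMMI
    model = fit_ammi(means)
    scores_frame(model).to_csv(
        outdir / f"{trait}_ammi.csv", index=False, float_format="%.4f"
    )

    # GGE
    gge_model = fit_gge(means, config.partition_f, config.scale_by_env_sd)
    markers = pd.concat(
        [
            pd.DataFrame(
                {"entity": gge_model.genotypes, "type": "genotype",
                 "axis1": gge_model.genotype_markers[:, 0],
                 "axis2": gge_model.genotype_markers[:, 1]}
            ),
            pd.DataFrame(
                {"entity": gge_model.environments, "type": "environment",
                 "axis1": gge_model.environment_markers[:, 0],
                 "axis2": gge_model.environment_markers[:, 1]}
            ),
        ],
        ignore_index=True,
    )
    markers["explained_2d"] = gge_model.explained_2d
    markers.to_csv(outdir / f"{trait}_gge_markers.csv", index=False, float_format="%.4f")

    partition = which_won_where(gge_model)
    sectors = pd.DataFrame(
        {
            "environment": list(partition.environment_sector),
            "sector": list(partition.environment_sector.values()),
            "winner": [
                partition.sector_winner[s]
                for s in partition.environment_sector.values()
            ],
        }
    )
    sectors.to_csv(outdir / f"{trait}_gge_sectors.csv", index=False)

    ranking = rank_by_ideal(gge_model)
    stab = mean_vs_stability(gge_model)
    pd.DataFrame(
        {
            "genotype": ranking.genotypes,
            "aea_projection": stab.aea_projection,
            "stability_deviation": stab.stability_deviation,
            "distance_to_ideal": ranking.distance_to_ideal,
            "rank": ranking.rank,
        }
    ).to_csv(outdir / f"{trait}_gge_ranking.csv", index=False, float_format="%.4f")

    diag = discriminativeness_representativeness(gge_model)
    pd.DataFrame(
        {
            "environment": diag.environments,
            "vector_length": diag.vector_length,
            "angle_to_aea": diag.angle_to_aea,
            "representativeness": diag.representativeness,
        }
    ).to_csv(outdir / f"{trait}_gge_environments.csv", index=False, float_format="%.4f")

    if config.figures:
        from . import plots

        plots.ammi1_biplot(model, outdir / f"{trait}_ammi1.png")
        plots.gge_polygon(gge_model, partition, outdir / f"{trait}_gge_polygon.png")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every requested trait; one report set per trait.

    A degenerate trait aborts only its own report (logged), not the run.
    Returns a summary dict with per-trait status and written paths.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path in filter(None, [config.long_csv, *config.means_csvs.values()]):
        log.info("input %s sha256=%s", path, _sha256(path))
    log.info("config: %s", config)

    jobs, _ = _gather_means(config)
    if not jobs:
        log.warning("no traits to analyse — nothing to do")
        return {"status": "empty", "traits": {}}

    status: dict[str, str] = {}
    for trait, means, claims, data in jobs:
        try:
            _trait_report(trait, means, claims, data, config, outdir)
            status[trait] = "ok"
        except MetstabError as exc:
            log.error("trait %s failed: %s", trait, exc)
            status[trait] = f"failed: {exc}"
    return {"status": "ok", "output_dir": str(outdir), "traits": status}
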