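"""Data model and I/O for multi-environment trials (METs).

A MET evaluates ``g`` genotypes in ``e`` environments (locations, seasons)
under a randomized complete block design with ``r`` replicates.  The raw unit
is one plot observation; every mean-level stability model in this package
consumes a :class:`TraitMeans` — the g x e matrix of cell means with its
marginals.

Marginals are *always* recomputed from the cells.  Published tables often
print marginals computed upstream (sometimes with typos), so printed
marginals are treated as claims to be checked by
:func:`validate_means_table`, never as data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateRecordError,
    MissingCellError,
    SchemaError,
    UnbalancedDesignError,
    ValueParseError,
)

LONG_COLUMNS = ("genotype", "environment", "replicate", "trait", "value")

#: decimal places used by all CSV writers
WRITE_PRECISION = 4


class Observation(NamedTuple):
    """A single plot measurement."""

    genotype: str
    environment: str
    replicate: int
    trait: str
    value: float


@dataclass(frozen=True)
class Design:
    """Dimensions of a (nominally) balanced g x e x r trial."""

    n_genotypes: int
    n_environments: int
    n_replicates: int

    def __iter__(self):
        return iter((self.n_genotypes, self.n_environments, self.n_replicates))


class METDataset:
    """Long-format replicate-level observations of one or more traits.

    Parameters
    ----------
    table:
        DataFrame with columns ``genotype, environment, replicate, trait,
        value``.  Values must be finite, replicates positive integers.
        Label order (first appearance) is preserved throughout.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in LONG_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        table = table.loc[:, list(LONG_COLUMNS)].copy()
        table["genotype"] = table["genotype"].astype(str)
        table["environment"] = table["environment"].astype(str)
        table["trait"] = table["trait"].astype(str)
        try:
            table["replicate"] = table["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValueParseError(f"non-integer replicate label: {exc}") from exc
        if (table["replicate"] < 1).any():
            raise ValueParseError("replicate labels must be >= 1")
        values = pd.to_numeric(table["value"], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))
        if bad.size:
            raise ValueParseError(
                f"non-finite or unparseable value at row(s) {bad[:5].tolist()}"
            )
        table["value"] = values.astype(float)
        dup = table.duplicated(
            subset=["genotype", "environment", "replicate", "trait"]
        )
        if dup.any():
            first = table.loc[dup.idxmax()]
            raise DuplicateRecordError(
                "duplicate record for "
                f"({first.genotype}, {first.environment}, "
                f"{first.replicate}, {first.trait})"
            )
        self._table = table.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self._table["genotype"]))

    @property
    def environments(self) -> list[str]:
        return list(dict.fromkeys(self._table["environment"]))

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self._table["trait"]))

    @property
    def design(self) -> Design:
        return Design(
            len(self.genotypes),
            len(self.environments),
            int(self._table["replicate"].max()),
        )

    @property
    def is_balanced(self) -> bool:
        """True iff every (g, e, rep, trait) combination appears exactly once."""
        g, e, r = self.design
        expected = g * e * r * len(self.traits)
        return len(self._table) == expected

    def __len__(self) -> int:
        return len(self._table)

    def observations(self):
        for row in self._table.itertuples(index=False):
            yield Observation(*row)

    def subset_environment(self, environment: str) -> "METDataset":
        if environment not in self.environments:
            raise MissingCellError(f"unknown environment {environment!r}")
        return METDataset(self._table[self._table["environment"] == environment])

    # -- construction / I/O ------------------------------------------------

    @classmethod
    def from_observations(cls, obs: Sequence[Observation]) -> "METDataset":
        return cls(pd.DataFrame(obs, columns=LONG_COLUMNS))

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        genotypes: Sequence[str],
        environments: Sequence[str],
        trait: str,
    ) -> "METDataset":
        """Build from a g x e x r value array."""
        g, e, r = values.shape
        rows = [
            (genotypes[i], environments[j], k + 1, trait, float(values[i, j, k]))
            for i in range(g)
            for j in range(e)
            for k in range(r)
        ]
        return cls(pd.DataFrame(rows, columns=LONG_COLUMNS))


def read_long_csv(path, schema: Mapping[str, str] | None = None) -> METDataset:
    """Read a long-format trial CSV.

    ``schema`` maps canonical names (``genotype`` ...) to the column names
    actually present in the file.
    """
    raw = pd.read_csv(path, dtype=str)
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing = [v for v in schema.values() if v not in raw.columns]
        if missing:
            raise SchemaError(f"declared columns absent from file: {missing}")
        raw = raw.rename(columns=rename)
    return METDataset(raw)


def write_long_csv(data: METDataset, path) -> None:
    """Write long CSV with deterministic column order and fixed precision."""
    out = data.table
    out["value"] = out["value"].map(lambda v: f"{v:.{WRITE_PRECISION}f}")
    out.to_csv(path, index=False)


@dataclass
class TraitMeans:
    """g x e cell-mean matrix for one trait, genotype rows, environment cols.

    Marginals are derived properties, never stored input.
    """

    trait: str
    genotypes: list[str]
    environments: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        g, e = self.matrix.shape
        if g != len(self.genotypes) or e != len(self.environments):
            raise SchemaError("matrix shape does not match label vectors")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueParseError("cell means must be finite")

    @property
    def genotype_means(self) -> np.ndarray:
        return self.matrix.mean(axis=1)

    @property
    def environment_means(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.matrix.mean())

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @classmethod
    def from_wide_csv(cls, path, trait: str | None = None) -> "TraitMeans":
        """Read a wide means CSV: header ``genotype,<env1>,<env2>,...``."""
        df = pd.read_csv(path)
        if df.columns[0] != "genotype":
            raise SchemaError("wide means CSV must start with a 'genotype' column")
        envs = list(df.columns[1:])
        matrix = df[envs].to_numpy(dtype=float)
        return cls(trait or "trait", df["genotype"].astype(str).tolist(), envs, matrix)

    def to_wide_csv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.environments)
        df.insert(0, "genotype", self.genotypes)
        df.to_csv(path, index=False, float_format=f"%.{WRITE_PRECISION}f")


def cell_means(data: METDataset, trait: str) -> TraitMeans:
    """Aggregate replicate observations into a g x e cell-mean matrix."""
    if trait not in data.traits:
        raise MissingCellError(f"trait {trait!r} not present in dataset")
    sub = data.table
    sub = sub[sub["trait"] == trait]
    genotypes, environments = data.genotypes, data.environments
    pivot = sub.pivot_table(
        index="genotype", columns="environment", values="value", aggfunc="mean"
    )
    matrix = np.full((len(genotypes), len(environments)), np.nan)
    for i, gname in enumerate(genotypes):
        for j, ename in enumerate(environments):
            if gname in pivot.index and ename in pivot.columns:
                matrix[i, j] = pivot.loc[gname, ename]
            if not np.isfinite(matrix[i, j]):
                raise MissingCellError(
                    f"no observations for genotype {gname!r} in "
                    f"environment {ename!r} (trait {trait!r})"
                )
    return TraitMeans(trait, genotypes, environments, matrix)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    location: str
    message: str
    expected_value: float | None = None
    found_value: float | None = None


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, severity, location, message, expected=None, found=None):
        self.issues.append(
            ValidationIssue(severity, location, message, expected, found)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(i) for i in self.issues],
            columns=["severity", "location", "message", "expected_value", "found_value"],
        )


def validate_means_table(
    means: TraitMeans,
    claimed_genotype_means: Sequence[float] | None = None,
    claimed_environment_means: Sequence[float] | None = None,
    claimed_grand_mean: float | None = None,
    tol: float = 0.05,
    iqr_k: float = 3.0,
) -> ValidationReport:
    """Check printed marginals against recomputed ones and screen for
    suspect cells.

    Every claimed marginal differing from the recomputed value by more than
    ``tol`` is flagged; cells more than ``iqr_k`` interquartile ranges from
    their environment-column quartiles are flagged as suspect (the kind of
    transcription typo that survives peer review).
    """
    report = ValidationReport()
    if claimed_genotype_means is not None:
        for name, claimed, actual in zip(
            means.genotypes, claimed_genotype_means, means.genotype_means
        ):
            if np.isfinite(claimed) and abs(claimed - actual) > tol:
                report.add(
                    "error",
                    f"genotype mean[{name}]",
                    "printed genotype mean disagrees with recomputed cell mean",
                    expected=float(actual),
                    found=float(claimed),
                )
    if claimed_environment_means is not None:
        for name, claimed, actual in zip(
            means.environments, claimed_environment_means, means.environment_means
        ):
            if np.isfinite(claimed) and abs(claimed - actual) > tol:
                report.add(
                    "error",
                    f"environment mean[{name}]",
                    "printed environment mean disagrees with recomputed column mean",
                    expected=float(actual),
                    found=float(claimed),
                )
    if claimed_grand_mean is not None and np.isfinite(claimed_grand_mean):
        if abs(claimed_grand_mean - means.grand_mean) > tol:
            report.add(
                "error",
                "grand mean",
                "printed grand mean disagrees with recomputed grand mean",
                expected=means.grand_mean,
                found=float(claimed_grand_mean),
            )
    # suspect-cell screen, column-wise
    for j, ename in enumerate(means.environments):
        col = means.matrix[:, j]
        q1, q3 = np.percentile(col, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_k * iqr, q3 + iqr_k * iqr
        for i, gname in enumerate(means.genotypes):
            if col[i] < lo or col[i] > hi:
                report.add(
                    "warning",
                    f"cell[{gname}, {ename}]",
                    f"cell value beyond {iqr_k} IQR of its environment column",
                    found=float(col[i]),
                )
    return report
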