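"""Tidy phenotype tables, replicate aggregation and analysis configuration.

The pipeline's raw input is a long-format CSV with one row per
``(genotype, index, condition, replicate)`` and the measured value in the
index's native units.  ``condition`` is one of the paired growth regimes
of the trial design: ``CK`` (control, 26/22 °C day/night) or ``HS``
(heat stress, 42/28 °C).  Replicates are averaged per cell before any
ratio is formed; a genotype × index cell missing either condition is a
hard error, because the downstream min–max normalisations are undefined
on partially observed genotypes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConditionError,
    ConfigError,
    DuplicateKeyError,
    FormatError,
    IncompletePairError,
)

CONDITIONS = ("CK", "HS")
PHENO_COLUMNS = ("genotype", "index", "condition", "replicate", "value")


def _validate_pheno_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table is missing columns {missing}")
    df = df.loc[:, list(PHENO_COLUMNS)].copy()

    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        i = int(np.flatnonzero(bad_cond.to_numpy())[0])
        raise ConditionError(
            f"row {i + 1}: condition {df['condition'].iloc[i]!r} is not one of {CONDITIONS}"
        )

    values = pd.to_numeric(df["value"], errors="coerce")
    bad_val = ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    if bad_val.any():
        i = int(np.flatnonzero(bad_val)[0])
        raise FormatError(f"row {i + 1}: value {df['value'].iloc[i]!r} is not a finite number")
    df["value"] = values.astype(float)
    if (df["value"] < 0).any():
        i = int(np.flatnonzero((df["value"] < 0).to_numpy())[0])
        raise FormatError(
            f"row {i + 1}: negative measurement {df['value'].iloc[i]} rejected "
            "(all supported indices are non-negative quantities)"
        )

    reps = pd.to_numeric(df["replicate"], errors="coerce")
    if reps.isna().any() or (reps != reps.round()).any() or (reps < 1).any():
        raise FormatError("replicate ids must be positive integers")
    df["replicate"] = reps.astype(int)

    key = ["genotype", "index", "condition", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise DuplicateKeyError(
            "duplicate (genotype, index, condition, replicate) key: "
            f"{tuple(df.loc[df.index[i], key])}"
        )
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class PhenoTable:
    """Validated long-format table of replicated measurements."""

    data: pd.DataFrame

    def __post_init__(self):
        object.__setattr__(self, "data", _validate_pheno_frame(self.data))

    @property
    def genotypes(self) -> list[str]:
        return list(pd.unique(self.data["genotype"]))

    @property
    def indices(self) -> list[str]:
        return list(pd.unique(self.data["index"]))

    def __eq__(self, other) -> bool:
        return isinstance(other, PhenoTable) and self.data.equals(other.data)


def read_pheno_table(path) -> PhenoTable:
    """Read and validate a long-format phenotype CSV (row order preserved)."""
    df = pd.read_csv(path, dtype={"genotype": str, "index": str, "condition": str})
    return PhenoTable(df)


def write_pheno_table(table: PhenoTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_pheno_wide(path) -> PhenoTable:
    """Read a wide-format convenience CSV.

    Expected header: ``genotype,condition,replicate,<index 1>,<index 2>,...``;
    the frame is melted to the canonical long format internally.
    """
    df = pd.read_csv(path, dtype={"genotype": str, "condition": str})
    id_cols = ["genotype", "condition", "replicate"]
    missing = [c for c in id_cols if c not in df.columns]
    if missing:
        raise FormatError(f"wide phenotype table is missing columns {missing}")
    long = df.melt(id_vars=id_cols, var_name="index", value_name="value")
    return PhenoTable(long[list(PHENO_COLUMNS)])


@dataclass(frozen=True)
class AggregatedPheno:
    """Replicate means per genotype × index × condition.

    ``means`` and ``n_replicates`` share a (genotype, index) MultiIndex and
    have exactly the columns ``CK`` and ``HS``; completeness of every pair
    is guaranteed by :func:`aggregate_replicates`.
    """

    means: pd.DataFrame
    n_replicates: pd.DataFrame


def aggregate_replicates(table: PhenoTable) -> AggregatedPheno:
    """Average replicates into one mean per genotype × index × condition.

    Raises :class:`IncompletePairError` if any (genotype, index) lacks a CK
    or HS cell — the evaluation method has no sensible behaviour for
    partially observed genotypes.
    """
    g = table.data.groupby(["genotype", "index", "condition"], sort=False)["value"]
    means = g.mean().unstack("condition").reindex(columns=list(CONDITIONS))
    ns = g.size().unstack("condition").reindex(columns=list(CONDITIONS))
    incomplete = means.isna().any(axis=1)
    if incomplete.any():
        genotype, index = means.index[np.flatnonzero(incomplete.to_numpy())[0]]
        have = means.columns[means.loc[(genotype, index)].notna()].tolist()
        raise IncompletePairError(
            f"genotype {genotype!r}, index {index!r}: only {have} measured; "
            "both CK and HS are required"
        )
    # preserve first-appearance order of genotypes/indices for reproducibility
    order = pd.MultiIndex.from_frame(
        table.data[["genotype", "index"]].drop_duplicates(), names=["genotype", "index"]
    )
    return AggregatedPheno(means.reindex(order), ns.reindex(order).astype(int))


@dataclass
class AnalysisConfig:
    """Knobs of the evaluation pipeline.

    Parameters
    ----------
    index_list
        Ordered index labels entering the PCA; ``None`` means every index
        present in the data, in first-appearance order.
    anchor_index
        Index used to sign-orient principal components (a benefit trait:
        higher stress/control ratio = more tolerant).  Default ``"Chl a"``,
        chlorophyll-a retention, the lead tolerance indicator.
    variance_threshold
        Retain the smallest number of components whose cumulative variance
        proportion reaches this fraction.  Default 0.80.
    n_components_override
        Exact number of components to retain, overriding the threshold.
    alpha_enter, alpha_remove
        Partial-F significance thresholds for stepwise entry/removal
        (classical defaults 0.05 / 0.10); entry must be stricter.
    n_groups
        Number of tolerance groups for the 1-D clustering cut (default 3).
    seed
        Seed recorded with every run for reproducibility.
    """

    index_list: Optional[Sequence[str]] = None
    anchor_index: str = "Chl a"
    variance_threshold: float = 0.80
    n_components_override: Optional[int] = None
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    n_groups: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.variance_threshold <= 1):
            raise ConfigError("variance_threshold must lie in (0, 1]")
        if not (0 < self.alpha_enter < self.alpha_remove):
            raise ConfigError("need 0 < alpha_enter < alpha_remove")
        if self.alpha_remove >= 1:
            raise ConfigError("alpha_remove must be < 1")
        if self.n_groups < 1:
            raise ConfigError("n_groups must be a positive integer")
        if self.n_components_override is not None and self.n_components_override < 1:
            raise ConfigError("n_components_override must be a positive integer")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["index_list"] is not None:
            d["index_list"] = list(d["index_list"])
        return d

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
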