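"""Replicate-level quality control for peak-area quantification tables.

Shotgun proteomics and GC-MS metabolomics both produce feature x replicate
peak-area matrices.  The shared QC route is: keep only features observed
consistently across replicates, keep proteins supported by unique peptides,
normalize replicate columns to a common total area, impute residual missing
values, and summarize reproducibility as per-feature coefficients of
variation (CV% = 100 * sample SD / mean) plus their unweighted average.

Zeros are treated as missing (a zero peak area means "not observed"); the
loader converts them to NaN by default, and "present" everywhere means a
positive, non-missing area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuantTable",
    "FeatureStats",
    "read_quant_table",
    "consistency_filter",
    "unique_peptide_filter",
    "normalize_areas",
    "impute_missing",
    "replicate_stats",
]


class QuantConfigError(ValueError):
    """Table lacks a column or attribute an operation requires."""


@dataclass
class QuantTable:
    """A feature x replicate matrix of peak areas with per-feature metadata.

    ``data`` holds areas (NaN = missing) indexed by feature id with one column
    per replicate; ``meta`` carries per-feature attributes such as
    ``unique_peptides`` for proteins.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if ((self.data < 0).any()).any():
            raise ValueError("peak areas must be non-negative")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return len(self.data)

    def _with(self, data: pd.DataFrame) -> "QuantTable":
        return QuantTable(data, self.meta.loc[data.index].copy())


@dataclass(frozen=True)
class FeatureStats:
    feature_id: str
    mean: float
    sd: float
    cv_percent: float
    flagged: bool


def read_quant_table(
    path: str | Path,
    replicate_columns: Sequence[str] | None = None,
    id_column: str | None = None,
    zero_as_missing: bool = True,
    sep: str = "\t",
) -> QuantTable:
    """Load a features x replicates TSV into a :class:`QuantTable`.

    The first column is the feature id unless ``id_column`` names another.
    ``replicate_columns`` selects the area columns; by default every numeric
    column is treated as a replicate and the rest become metadata.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    id_col = id_column or df.columns[0]
    df = df.set_index(id_col)
    if replicate_columns is None:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        replicate_columns = [c for c in df.columns if numeric[c].notna().any()]
        # integer-valued support columns are metadata, not areas
        replicate_columns = [
            c for c in replicate_columns if c not in ("unique_peptides",)
        ]
    data = df[list(replicate_columns)].apply(pd.to_numeric, errors="coerce")
    meta = df.drop(columns=list(replicate_columns))
    if zero_as_missing:
        data = data.mask(data == 0)
    return QuantTable(data, meta)


def consistency_filter(
    table: QuantTable, required_present: int | None = None
) -> QuantTable:
    """Keep features present (positive, non-missing) in enough replicates.

    The default requires presence in every replicate — the rule that only
    features observed in all independent extractions are considered.
    """
    n_reps = len(table.data.columns)
    if required_present is None:
        required_present = n_reps
    if not 1 <= required_present <= n_reps:
        raise ValueError(
            f"required_present must be in [1, {n_reps}], got {required_present}"
        )
    present = table.data.notna() & (table.data > 0)
    return table._with(table.data.loc[present.sum(axis=1) >= required_present])


def unique_peptide_filter(table: QuantTable, min_unique: int = 1) -> QuantTable:
    """Keep proteins supported by at least ``min_unique`` unique peptides."""
    if "unique_peptides" not in table.meta.columns:
        raise QuantConfigError(
            "meta lacks a 'unique_peptides' column; cannot apply the filter"
        )
    counts = pd.to_numeric(table.meta["unique_peptides"])
    return table._with(table.data.loc[counts >= min_unique])


def normalize_areas(table: QuantTable, method: str = "total") -> QuantTable:
    """Scale replicate columns onto a common level; missing cells stay missing.

    ``total`` (default): each column is scaled so its sum equals the mean of
    the raw column sums — the grand total of the table is conserved.
    ``median``: columns are scaled so their medians equal the mean of the raw
    column medians.
    """
    if table.data.empty:
        return table._with(table.data.copy())
    if method == "total":
        level = table.data.sum(axis=0, skipna=True)
    elif method == "median":
        level = table.data.median(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    zero = level[(level == 0) | level.isna()]
    if not zero.empty:
        raise ValueError(
            f"replicate column(s) with no positive areas: {list(zero.index)}"
        )
    return table._with(table.data * (level.mean() / level))


def impute_missing(table: QuantTable, rule: str = "half_row_min") -> QuantTable:
    """Replace missing cells deterministically.

    ``half_row_min`` (default): each missing cell takes half the minimum
    observed positive value of its own feature's row.  ``half_global_min``:
    half the minimum observed positive value of the whole table.  A feature
    with no observed value at all cannot be imputed and raises (the
    consistency filter normally guarantees this cannot happen).
    """
    data = table.data.copy()
    if data.empty:
        return table._with(data)
    positive = data.where(data > 0)
    if rule == "half_row_min":
        fill = positive.min(axis=1) / 2.0
        empty = fill[fill.isna()]
        if not empty.empty:
            raise ValueError(
                f"feature(s) with no observed value: {list(empty.index)}"
            )
        data = data.apply(lambda col: col.fillna(fill))
    elif rule == "half_global_min":
        gmin = positive.min().min()
        if pd.isna(gmin):
            raise ValueError("table has no observed positive value")
        data = data.fillna(gmin / 2.0)
    else:
        raise ValueError(f"unknown imputation rule {rule!r}")
    return table._with(data)


def replicate_stats(
    table: QuantTable, ddof: int = 1
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-feature mean / SD / CV% plus a summary.

    SD uses the sample convention (n-1 denominator) by default.  Features
    with zero mean or fewer than two observed replicates are flagged and
    excluded from the summary; the exclusion count is always reported.
    Summary ``mean_cv_percent`` is the unweighted average of per-feature CV%.
    """
    if len(table.data.columns) < 2:
        raise ValueError("replicate_stats requires at least 2 replicates")
    mean = table.data.mean(axis=1, skipna=True)
    sd = table.data.std(axis=1, ddof=ddof, skipna=True)
    n_obs = table.data.notna().sum(axis=1)
    flagged = (n_obs < 2) | (mean == 0) | mean.isna()
    cv = 100.0 * sd / mean.where(mean != 0)
    stats = pd.DataFrame(
        {"mean": mean, "sd": sd, "cv_percent": cv, "n_observed": n_obs,
         "flagged": flagged}
    )
    valid_cv = cv[~flagged]
    summary = {
        "n_features": float(len(stats)),
        "n_flagged": float(int(flagged.sum())),
        "mean_cv_percent": float(valid_cv.mean()) if len(valid_cv) else float("nan"),
    }
    return stats, summary
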