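"""Merged two-ome sample tables: reading, validation, filtering, transforms.

The screen's single input is a *merged table*: one row per sample, a cohort
label per sample, and one column per analyte from either ome.  Microbial
features are relative abundances in [0, 1]; immune features are continuous
positive readouts (cytokine concentrations in pg/ml, cell subsets in percent
of parent).  A separate manifest assigns each feature column to an ome.

File dialect
------------
* Merged table: CSV, UTF-8, header row; first column ``sample_id``, second
  ``cohort``, remaining columns features.
* Manifest: CSV with columns ``feature,ome[,units]``; ome is ``microbe`` or
  ``immune``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, ValidationError

MICROBE = "microbe"
IMMUNE = "immune"
OMES = (MICROBE, IMMUNE)

TRANSFORMS = ("none", "sqrt")
THRESHOLD_TYPES = ("raw_p", "fdr_p")
METRIC_COLUMNS = ("F", "p", "pAdj", "interaction_p", "max_influence")


@dataclass(frozen=True)
class FeatureMeta:
    """One analyte column: its name, ome, units and applied transform."""

    name: str
    ome: str
    units: str = ""
    transform_applied: str = "none"

    def __post_init__(self):
        if self.ome not in OMES:
            raise ValidationError(
                f"feature {self.name!r}: ome must be one of {OMES}, got {self.ome!r}"
            )
        if self.transform_applied not in TRANSFORMS:
            raise ValidationError(
                f"feature {self.name!r}: unknown transform {self.transform_applied!r}"
            )


@dataclass
class MergedTable:
    """Samples x features values with per-sample cohort labels.

    ``values`` is a pandas DataFrame indexed by sample id with one column per
    feature, in manifest order.  Missing values are allowed and handled
    pairwise downstream.
    """

    values: pd.DataFrame
    cohorts: pd.Series
    features: list[FeatureMeta] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def cohort_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cohorts:
            seen.setdefault(str(c))
        return list(seen)

    def feature_names(self, ome: str | None = None) -> list[str]:
        return [f.name for f in self.features if ome is None or f.ome == ome]

    @property
    def microbe_names(self) -> list[str]:
        return self.feature_names(MICROBE)

    @property
    def immune_names(self) -> list[str]:
        return self.feature_names(IMMUNE)

    def meta(self, name: str) -> FeatureMeta:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate feature names: {dup}")
        if list(self.values.columns) != names:
            raise ValidationError("values columns do not match feature manifest order")
        if self.values.index.has_duplicates:
            dup = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise InputError(f"duplicate sample ids: {dup}")
        if not self.values.index.equals(self.cohorts.index):
            raise ValidationError("cohort labels are not aligned with sample ids")
        if len(self.cohort_labels) < 2:
            raise ValidationError(
                f"at least 2 distinct cohorts required, found {self.cohort_labels}"
            )
        for f in self.features:
            if f.ome != MICROBE:
                continue
            col = self.values[f.name]
            bad = col[(col < 0) | (col > 1)].dropna()
            if len(bad):
                sid, val = bad.index[0], bad.iloc[0]
                raise ValidationError(
                    f"microbe feature {f.name!r} outside [0, 1]: "
                    f"value {val!r} at sample {sid!r}"
                )


def read_merged_table(path, manifest) -> MergedTable:
    """Read a merged CSV table and its feature manifest.

    Parameters
    ----------
    path : str or path-like
        CSV with header row; columns ``sample_id, cohort, <features...>``.
    manifest : str, path-like or DataFrame
        Feature->ome assignment with columns ``feature, ome[, units]``.
    """
    mdf = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
    mdf.columns = [c.strip().lower() for c in mdf.columns]
    if not {"feature", "ome"} <= set(mdf.columns):
        raise InputError("manifest must have columns 'feature' and 'ome'")
    if "units" not in mdf.columns:
        mdf = mdf.assign(units="")
    mdf = mdf.fillna({"units": ""})

    df = pd.read_csv(path, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise InputError("merged table needs sample_id, cohort and >=1 feature column")
    cols = [c.strip() for c in df.columns]
    lower = [c.lower() for c in cols]
    if "cohort" not in lower:
        raise InputError("merged table is missing the 'cohort' column")
    sid_col, cohort_col = df.columns[0], df.columns[lower.index("cohort")]

    sample_ids = df[sid_col].astype(str)
    if sample_ids.duplicated().any():
        dup = sorted(sample_ids[sample_ids.duplicated()].unique())
        raise InputError(f"duplicate sample ids: {dup}")

    features = []
    for row in mdf.itertuples(index=False):
        if row.feature not in df.columns:
            raise InputError(f"manifest feature {row.feature!r} not found in table")
        features.append(FeatureMeta(str(row.feature), str(row.ome), str(row.units)))

    values = df[[f.name for f in features]].apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(sample_ids, name="sample_id")
    cohorts = pd.Series(df[cohort_col].astype(str).values, index=values.index,
                        name="cohort")
    return MergedTable(values=values, cohorts=cohorts, features=features)


def prevalence_filter(table: MergedTable, min_nonzero: int) -> MergedTable:
    """Keep microbe features nonzero in at least ``min_nonzero`` samples.

    Immune features are never filtered; sample rows are unchanged.  The
    boundary is inclusive ("at least"), and "nonzero" means strictly > 0.
    """
    if min_nonzero < 0:
        raise ConfigurationError("min_nonzero must be >= 0")
    if min_nonzero > table.n_samples:
        raise ConfigurationError(
            f"min_nonzero={min_nonzero} exceeds sample count {table.n_samples}"
        )
    kept = []
    for f in table.features:
        if f.ome != MICROBE:
            kept.append(f)
            continue
        n_nonzero = int((table.values[f.name] > 0).sum())
        if n_nonzero >= min_nonzero:
            kept.append(f)
    return MergedTable(
        values=table.values[[f.name for f in kept]].copy(),
        cohorts=table.cohorts.copy(),
        features=list(kept),
    )


def apply_transform(table: MergedTable, ome: str, transform: str) -> MergedTable:
    """Apply an elementwise transform to every feature of one ome.

    ``sqrt`` compresses the dynamic range of positive readouts and dampens
    the effect of very high values; it requires all affected values >= 0.
    ``none`` returns a numerically identical table.
    """
    if ome not in OMES:
        raise ConfigurationError(f"unknown ome {ome!r}")
    if transform not in TRANSFORMS:
        raise ConfigurationError(f"unknown transform {transform!r}")

    values = table.values.copy()
    features = []
    for f in table.features:
        if f.ome != ome or transform == "none":
            features.append(f)
            continue
        col = values[f.name]
        bad = col[col < 0].dropna()
        if len(bad):
            sid, val = bad.index[0], bad.iloc[0]
            raise ValidationError(
                f"cannot sqrt-transform feature {f.name!r}: "
                f"negative value {val!r} at sample {sid!r}"
            )
        values[f.name] = np.sqrt(col)
        features.append(replace(f, transform_applied="sqrt"))
    return MergedTable(values=values, cohorts=table.cohorts.copy(), features=features)


@dataclass
class RunConfig:
    """Configuration of one screening run.

    Parameters
    ----------
    reference_cohort
        Cohort absorbed into the intercept under treatment coding; other
        cohorts' effects and interaction p-values are offsets from it.
    threshold_type, threshold_value
        Inclusion rule for the top table: ``raw_p`` keeps pairs with
        unadjusted p strictly below the value, ``fdr_p`` applies the rule to
        the BH-adjusted p-value.
    min_nonzero
        Microbe prevalence filter (0 disables it).
    immune_transform
        ``sqrt`` or ``none``, applied to all immune features before fitting.
    metric_columns
        Which metrics the top table carries beyond the analyte names.
    cohort_colors
        Optional display color per cohort label for the exported document.
    """

    reference_cohort: str
    threshold_type: str = "fdr_p"
    threshold_value: float = 0.05
    min_nonzero: int = 0
    immune_transform: str = "none"
    metric_columns: tuple[str, ...] = ("F", "p", "pAdj")
    seed: int = 0
    cohort_colors: dict[str, str] | None = None

    def __post_init__(self):
        if self.threshold_type not in THRESHOLD_TYPES:
            raise ConfigurationError(
                f"threshold_type must be one of {THRESHOLD_TYPES}"
            )
        if not (0.0 < self.threshold_value <= 1.0) or math.isnan(self.threshold_value):
            raise ConfigurationError("threshold_value must lie in (0, 1]")
        if self.min_nonzero < 0:
            raise ConfigurationError("min_nonzero must be >= 0")
        if self.immune_transform not in TRANSFORMS:
            raise ConfigurationError(f"unknown immune_transform {self.immune_transform!r}")
        self.metric_columns = tuple(self.metric_columns)
        for m in self.metric_columns:
            if m not in METRIC_COLUMNS:
                raise ConfigurationError(f"unknown metric column {m!r}")

    def check_against(self, table: MergedTable) -> None:
        if self.reference_cohort not in table.cohort_labels:
            raise ConfigurationError(
                f"reference cohort {self.reference_cohort!r} not among "
                f"table cohorts {table.cohort_labels}"
            )


def pairwise_complete(
    y: Sequence[float], x: Sequence[float], cohorts: Iterable[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop samples with a missing value in either member of a pair."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cohorts = np.asarray(list(cohorts), dtype=object)
    keep = ~(np.isnan(y) | np.isnan(x))
    return y[keep], x[keep], cohorts[keep]
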