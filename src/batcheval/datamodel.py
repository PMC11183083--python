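"""Core data containers, validation, and delimited-text / JSON I/O.

The analysis operates on three aligned objects: a complete ``FeatureMatrix``
(n samples x m features), a categorical ``BatchLabels`` vector with a
designated reference level, and an optional ``CovariateTable``.  Missing
values are a hard error at read time -- every downstream method assumes a
complete matrix, and silent imputation would change what the batch-effect
statistics measure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A container invariant was violated (shape, missingness, level counts)."""


class AlignmentError(ValidationError):
    """Sample identifiers of two tables do not match one-to-one."""


#: float format giving exact decimal round-trips for IEEE doubles
FLOAT_FORMAT = "%.17g"


def _delimiter_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


@dataclass(frozen=True, eq=False)
class FeatureMatrix:
    """n x m real-valued feature table with sample and feature identifiers."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        if values.ndim != 2:
            raise ValidationError(f"feature values must be 2-D, got shape {values.shape}")
        n, m = values.shape
        if n < 2 or m < 1:
            raise ValidationError(f"need n >= 2 samples and m >= 1 features, got {n} x {m}")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match number of rows")
        if len(self.feature_names) != m:
            raise ValidationError("feature_names length does not match number of columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample IDs")
        if len(set(self.feature_names)) != m:
            raise ValidationError("duplicate feature names")
        if not np.isfinite(values).all():
            bad = [self.feature_names[j] for j in np.unique(np.nonzero(~np.isfinite(values))[1])]
            raise ValidationError(f"missing or non-finite values in features: {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_names)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric feature cells: {exc}") from exc
        return cls(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))


@dataclass(frozen=True)
class BatchLabels:
    """Length-n categorical batch vector aligned to a feature matrix.

    ``levels`` is the ordered unique level list and ``reference_level`` the
    level absorbed into the model intercept (default: first level in sorted
    order).  Every level must carry at least two samples so that within-group
    sums of squares and per-group model fits are defined.
    """

    labels: tuple[str, ...]
    reference_level: str = ""
    _min_level_count: int = field(default=2, repr=False)

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        levels = tuple(sorted(set(labels)))
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ValidationError("batch variable needs at least 2 levels")
        counts = pd.Series(labels).value_counts()
        small = counts[counts < self._min_level_count]
        if len(small):
            raise ValidationError(
                f"batch level(s) with fewer than {self._min_level_count} samples: "
                f"{dict(small)}"
            )
        ref = self.reference_level or levels[0]
        if ref not in levels:
            raise ValidationError(f"reference level {ref!r} not among levels {levels}")
        object.__setattr__(self, "reference_level", ref)

    levels: tuple[str, ...] = field(init=False)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def codes(self) -> np.ndarray:
        """Integer codes with the reference level coded 0."""
        order = [self.reference_level] + [l for l in self.levels if l != self.reference_level]
        lut = {lev: k for k, lev in enumerate(order)}
        return np.fromiter((lut[x] for x in self.labels), dtype=np.intp, count=len(self.labels))

    @property
    def ordered_levels(self) -> tuple[str, ...]:
        """Levels with the reference level first (the coding order)."""
        return (self.reference_level,) + tuple(
            l for l in self.levels if l != self.reference_level
        )

    def counts(self) -> dict[str, int]:
        c = pd.Series(self.labels).value_counts()
        return {lev: int(c[lev]) for lev in self.levels}


@dataclass(frozen=True)
class CovariateTable:
    """n x q covariate frame (numeric or categorical) aligned to samples."""

    frame: pd.DataFrame

    def __post_init__(self):
        frame = self.frame.copy()
        object.__setattr__(self, "frame", frame)
        if frame.isna().any().any():
            bad = list(frame.columns[frame.isna().any()])
            raise ValidationError(f"missing values in covariates: {bad}")

    @property
    def n_covariates(self) -> int:
        return self.frame.shape[1]

    def __len__(self) -> int:
        return len(self.frame)

    def design(self) -> np.ndarray:
        """Numeric design columns: numeric covariates as-is, categoricals dummy-coded
        (first level dropped)."""
        if self.frame.shape[1] == 0:
            return np.empty((len(self.frame), 0))
        return pd.get_dummies(self.frame, drop_first=True, dtype=float).to_numpy(dtype=float)


def read_dataset(
    features_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    batch_column: str,
    covariate_columns: Sequence[str] = (),
    sample_id_column: str | None = None,
    reference_level: str | None = None,
) -> tuple[FeatureMatrix, BatchLabels, CovariateTable]:
    """Read and align a feature table with its sample metadata.

    The sample-ID column is the first column of each file unless
    ``sample_id_column`` names another one.  Metadata rows are reindexed to
    the feature-table row order; the two ID sets must match exactly.
    """
    feats = pd.read_csv(features_path, sep=_delimiter_for(features_path), float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep=_delimiter_for(metadata_path))
    for df, path in ((feats, features_path), (meta, metadata_path)):
        idc = sample_id_column or df.columns[0]
        if idc not in df.columns:
            raise AlignmentError(f"sample-ID column {idc!r} not found in {path}")
        df.set_index(df[idc].astype(str), inplace=True)
        df.drop(columns=[idc], inplace=True)
    if batch_column not in meta.columns:
        raise ValidationError(f"batch column {batch_column!r} not in metadata")
    missing_cov = [c for c in covariate_columns if c not in meta.columns]
    if missing_cov:
        raise ValidationError(f"covariate column(s) not in metadata: {missing_cov}")
    if feats.index.has_duplicates or meta.index.has_duplicates:
        raise AlignmentError("duplicate sample IDs")
    if set(feats.index) != set(meta.index):
        only_f = sorted(set(feats.index) - set(meta.index))[:3]
        only_m = sorted(set(meta.index) - set(feats.index))[:3]
        raise AlignmentError(
            f"sample IDs differ between tables (features-only: {only_f}, metadata-only: {only_m})"
        )
    meta = meta.reindex(feats.index)
    if meta[batch_column].isna().any():
        raise ValidationError(f"missing values in batch column {batch_column!r}")
    x = FeatureMatrix.from_dataframe(feats)
    labels = BatchLabels(
        tuple(meta[batch_column].astype(str)), reference_level=reference_level or ""
    )
    covariates = CovariateTable(meta[list(covariate_columns)])
    return x, labels, covariates


def write_feature_matrix(x: FeatureMatrix, path: str | os.PathLike, id_column: str = "sample_id"):
    df = x.to_dataframe()
    df.index.name = id_column
    df.to_csv(path, sep=_delimiter_for(path), float_format=FLOAT_FORMAT)


def read_feature_matrix(path: str | os.PathLike, sample_id_column: str | None = None) -> FeatureMatrix:
    df = pd.read_csv(path, sep=_delimiter_for(path), float_precision="round_trip")
    idc = sample_id_column or df.columns[0]
    df = df.set_index(df[idc].astype(str)).drop(columns=[idc])
    return FeatureMatrix.from_dataframe(df)


def write_permanova_result(result, path: str | os.PathLike):
    """Serialize a :class:`~batcheval.permanova.PermanovaResult` to JSON."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def read_permanova_result(path: str | os.PathLike):
    from .permanova import PermanovaResult

    with open(path) as fh:
        return PermanovaResult.from_dict(json.load(fh))


def write_resi_table(table: pd.DataFrame, path: str | os.PathLike):
    """Write a per-feature RESI table (one row per feature per non-reference
    batch coefficient)."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty RESI table")
    table.to_csv(path, sep=_delimiter_for(path), index=False, float_format=FLOAT_FORMAT)


def read_resi_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep=_delimiter_for(path))
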