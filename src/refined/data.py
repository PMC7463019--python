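"""Feature-table ingestion, preprocessing, and pairwise feature distances.

The central container is :class:`FeatureTable`: an ``n x p`` matrix of real
values with sample identifiers and unique feature names.  Downstream stages
treat the *features* (columns) as points in sample space: the pairwise
Euclidean distances between feature columns are the dissimilarities that the
2D embedding tries to preserve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FeatureTable",
    "DistanceMatrix",
    "load_feature_table",
    "filter_features",
    "normalize_features",
    "feature_distance_matrix",
]


class ValidationError(ValueError):
    """Raised when a table or matrix violates a structural invariant."""


@dataclass
class FeatureTable:
    """An ``n x p`` table of real-valued features.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per row.
    feature_names : list of str
        One unique name per column.
    values : ndarray, shape (n, p)
        Feature values.  May contain NaN only before :func:`filter_features`.
    """

    sample_ids: list
    feature_names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValidationError(f"{len(self.feature_names)} names for {p} columns")
        if len(set(self.feature_names)) != p:
            dupes = sorted({f for f in self.feature_names if self.feature_names.count(f) > 1})
            raise ValidationError(f"duplicate feature names: {dupes}")
        if len(set(map(str, self.sample_ids))) != n:
            raise ValidationError("duplicate sample ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        return cls(
            sample_ids=list(frame.index),
            feature_names=list(frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def write_csv(self, path, id_column: str = "id") -> None:
        frame = self.to_frame()
        frame.index.name = id_column
        frame.to_csv(path)


@dataclass
class DistanceMatrix:
    """A symmetric ``p x p`` matrix of nonnegative distances with labels."""

    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        p = len(self.labels)
        if self.d.shape != (p, p):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({p}, {p})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise ValidationError("negative distances")
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.d, 0.0)

    @property
    def p(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed (j < k row-major) order."""
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(labels=list(frame.columns), d=frame.to_numpy(dtype=float))


def _sniff_separator(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def load_feature_table(path, id_column: str = "id") -> FeatureTable:
    """Read a CSV/TSV feature table with a header row and an ID column.

    Raises a validation error on duplicate feature names or duplicate IDs,
    and a parse error naming the offending line on malformed input.
    """
    path = Path(path)
    sep = _sniff_separator(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if id_column not in header:
        raise ValidationError(f"id column {id_column!r} not found in header {header}")
    non_id = [h for h in header if h != id_column]
    if len(set(non_id)) != len(non_id):
        dupes = sorted({h for h in non_id if non_id.count(h) > 1})
        raise ValidationError(f"duplicate feature column names: {dupes}")
    try:
        frame = pd.read_csv(path, sep=sep, index_col=id_column, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValidationError(f"malformed file {path}: {exc}") from exc
    return FeatureTable.from_frame(frame)


def filter_features(t: FeatureTable, max_bad_frac: float = 0.10) -> FeatureTable:
    """Drop every column whose fraction of zero-or-missing entries exceeds the cap.

    A value counts as bad when it is exactly zero or NaN.  Columns whose bad
    fraction is *strictly* greater than ``max_bad_frac`` are discarded; the
    order of survivors is preserved.
    """
    if not 0.0 <= max_bad_frac <= 1.0:
        raise ValidationError("max_bad_frac must be in [0, 1]")
    bad = np.isnan(t.values) | (t.values == 0.0)
    frac = bad.mean(axis=0)
    keep = frac <= max_bad_frac
    if not keep.any():
        raise ValidationError("all feature columns dropped by zero/missing filter")
    names = [f for f, k in zip(t.feature_names, keep) if k]
    values = t.values[:, keep]
    if np.isnan(values).any():
        raise ValidationError("missing values remain after filtering; threshold too lax")
    return FeatureTable(sample_ids=list(t.sample_ids), feature_names=names, values=values)


def normalize_features(t: FeatureTable) -> FeatureTable:
    """Min-max scale each column into [0, 1]; constant columns map to all zeros."""
    if not np.isfinite(t.values).all():
        raise ValidationError("non-finite entries; run filter_features first")
    lo = t.values.min(axis=0)
    hi = t.values.max(axis=0)
    span = hi - lo
    out = np.zeros_like(t.values)
    ok = span > 0
    out[:, ok] = (t.values[:, ok] - lo[ok]) / span[ok]
    return FeatureTable(list(t.sample_ids), list(t.feature_names), out)


def feature_distance_matrix(t: FeatureTable) -> DistanceMatrix:
    """Euclidean distances between feature *columns* over the n samples."""
    if t.p < 2:
        raise ValidationError("need at least 2 features for a distance matrix")
    if not np.isfinite(t.values).all():
        raise ValidationError("non-finite entries; preprocess first")
    d = squareform(pdist(t.values.T, metric="euclidean"))
    return DistanceMatrix(labels=list(t.feature_names), d=d)
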