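"""Per-frame feature-matrix assembly and standardization.

The classifier consumes the six OpenFace feature families — gaze vectors (both
eyes, their renormalised average, and yaw/pitch angles), 2D/3D eye-region
landmarks, head pose, 2D/3D face landmarks, rigid and non-rigid shape
parameters, and facial action units — concatenated into one row per frame
(712 columns with every group enabled).

Standardization (z-scoring per column) is an implementation aid for the
optimiser; it is always fitted on training rows only so no information leaks
from held-out frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .openface_io import GROUP_NAMES, SessionTable, column_groups

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "Standardizer",
    "assemble_features",
    "fit_standardizer",
    "apply_standardizer",
]

DEFAULT_GROUPS = tuple(GROUP_NAMES)


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered subset of feature groups to assemble."""

    enabled_groups: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        if not self.enabled_groups:
            raise ConfigError("at least one feature group must be enabled")
        unknown = [g for g in self.enabled_groups if g not in GROUP_NAMES]
        if unknown:
            raise ConfigError(f"unknown feature group(s): {', '.join(unknown)}")
        if len(set(self.enabled_groups)) != len(self.enabled_groups):
            raise ConfigError("feature groups must not repeat")

    def columns(self) -> list[str]:
        cols: list[str] = []
        for g in self.enabled_groups:
            cols.extend(column_groups(g))
        return cols


@dataclass(frozen=True)
class Standardizer:
    """Per-column center/scale fitted on training rows."""

    center: np.ndarray
    scale: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.center) / self.scale


@dataclass
class FeatureMatrix:
    """n_frames x n_features matrix aligned to session frames."""

    values: np.ndarray
    column_names: list[str]
    frame_index: np.ndarray
    standardization: Standardizer | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("feature matrix must be two-dimensional")
        if self.values.shape[1] != len(self.column_names):
            raise ConfigError("column names must match matrix width")
        if len(set(self.column_names)) != len(self.column_names):
            raise ConfigError("feature column names must be unique")
        if self.values.shape[0] != len(self.frame_index):
            raise ConfigError("frame map must match matrix height")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def assemble_features(table: SessionTable, spec: FeatureSpec | None = None) -> FeatureMatrix:
    """Concatenate the enabled group columns, rows aligned to frames.

    Unsuccessful/occluded frames keep whatever values OpenFace produced; any
    exclusion happens downstream via the quality flags, not by imputation.
    """
    spec = spec or FeatureSpec()
    if table.n_frames == 0:
        raise ConfigError("cannot assemble features from an empty table")
    cols = spec.columns()
    missing = [c for c in cols if c not in table.data.columns]
    if missing:
        raise ConfigError(
            f"table lacks {len(missing)} column(s) for the requested groups, "
            f"e.g. {missing[:3]}"
        )
    values = table.data[cols].to_numpy(dtype=float)
    return FeatureMatrix(
        values=values,
        column_names=cols,
        frame_index=table.data["frame"].to_numpy(dtype=int),
    )


def fit_standardizer(matrix: FeatureMatrix, train_rows) -> Standardizer:
    """Fit per-column z-scoring on the given rows only.

    Zero-variance columns get scale 1 so constants map to exactly 0.
    """
    rows = np.asarray(train_rows, dtype=int)
    if rows.size == 0:
        raise ConfigError("train_rows must be nonempty")
    sub = matrix.values[rows]
    center = sub.mean(axis=0)
    scale = sub.std(axis=0, ddof=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return Standardizer(center=center, scale=scale)


def apply_standardizer(matrix: FeatureMatrix, params: Standardizer) -> FeatureMatrix:
    """Return a new matrix with every row transformed by ``params``."""
    return FeatureMatrix(
        values=params.transform(matrix.values),
        column_names=list(matrix.column_names),
        frame_index=matrix.frame_index.copy(),
        standardization=params,
    )
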