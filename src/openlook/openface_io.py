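"""Read, validate and write per-frame feature tables in the OpenFace output-CSV dialect.

OpenFace (Baltrusaitis et al.) emits one CSV row per video frame with face
detection confidence, eye-gaze direction vectors, gaze angles, 2D/3D eye-region
and face landmarks, head pose, rigid/non-rigid shape parameters and facial
action units.  This module owns that schema: the canonical column names, the
grouping of columns into the feature families used downstream, and round-trip
safe I/O.

Conventions
-----------
* Frames are 0-based internally; the on-disk dialect is 1-based (as OpenFace
  writes it) and is rebased on read.
* Timestamps are seconds; intervals elsewhere in the package are half-open
  ``[onset, offset)``.
* The per-frame "average of both eyes" gaze vector is not a native OpenFace
  column; it is derived on read (mean of the two unit vectors, renormalised)
  under the names ``gaze_avg_x/y/z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "META_COLUMNS",
    "SessionTable",
    "FrameRecord",
    "column_groups",
    "feature_columns",
    "read_openface_csv",
    "write_openface_csv",
]

# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

META_COLUMNS = ["frame", "face_id", "timestamp", "confidence", "success"]

# AU intensity channels (…_r) and presence channels (…_c) as emitted by OpenFace.
_AU_INTENSITY = [
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10", "AU12",
    "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU45",
]
_AU_PRESENCE = [
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10", "AU12",
    "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU28", "AU45",
]

GAZE_DERIVED = [f"gaze_avg_{a}" for a in "xyz"]


def _build_schema() -> dict[str, list[str]]:
    gaze = (
        [f"gaze_0_{a}" for a in "xyz"]
        + [f"gaze_1_{a}" for a in "xyz"]
        + list(GAZE_DERIVED)
        + ["gaze_angle_x", "gaze_angle_y"]
    )
    eye2d = [f"eye_lmk_x_{i}" for i in range(56)] + [f"eye_lmk_y_{i}" for i in range(56)]
    eye3d = (
        [f"eye_lmk_X_{i}" for i in range(56)]
        + [f"eye_lmk_Y_{i}" for i in range(56)]
        + [f"eye_lmk_Z_{i}" for i in range(56)]
    )
    pose = ["pose_Tx", "pose_Ty", "pose_Tz", "pose_Rx", "pose_Ry", "pose_Rz"]
    face2d = [f"x_{i}" for i in range(68)] + [f"y_{i}" for i in range(68)]
    face3d = (
        [f"X_{i}" for i in range(68)]
        + [f"Y_{i}" for i in range(68)]
        + [f"Z_{i}" for i in range(68)]
    )
    shape = ["p_scale", "p_rx", "p_ry", "p_rz", "p_tx", "p_ty"] + [
        f"p_{i}" for i in range(34)
    ]
    aus = [f"{au}_r" for au in _AU_INTENSITY] + [f"{au}_c" for au in _AU_PRESENCE]
    return {
        "gaze": gaze,
        "eye_landmarks_2d": eye2d,
        "eye_landmarks_3d": eye3d,
        "pose": pose,
        "face_landmarks_2d": face2d,
        "face_landmarks_3d": face3d,
        "shape_params": shape,
        "action_units": aus,
    }


_SCHEMA = _build_schema()
GROUP_NAMES = tuple(_SCHEMA)


def column_groups(group: str | None = None) -> dict[str, list[str]] | list[str]:
    """Feature columns per group, ordered as the model consumes them.

    With no argument, returns the full mapping ``group name -> column list``
    (copies; safe to mutate).  With a group name, returns that group's list.
    Groups are pairwise disjoint and together cover every feature column.
    """
    if group is None:
        return {k: list(v) for k, v in _SCHEMA.items()}
    try:
        return list(_SCHEMA[group])
    except KeyError:
        raise KeyError(
            f"unknown feature group {group!r}; known groups: {', '.join(_SCHEMA)}"
        ) from None


def feature_columns() -> list[str]:
    """All feature columns in group order (712 names)."""
    out: list[str] = []
    for cols in _SCHEMA.values():
        out.extend(cols)
    return out


def _native_columns() -> list[str]:
    return [c for c in feature_columns() if c not in GAZE_DERIVED]


# Columns a file must carry to be readable at all.  Other groups may be absent
# (OpenFace can be run with per-family output flags) but must be complete when
# present.
_CORE_COLUMNS = ["frame", "timestamp", "confidence", "success"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FrameRecord:
    """A single frame's features, unpacked into named arrays."""

    frame_index: int
    timestamp: float
    success: int
    confidence: float
    gaze_left: np.ndarray
    gaze_right: np.ndarray
    gaze_avg: np.ndarray
    gaze_angle: np.ndarray
    eye_landmarks_2d: np.ndarray  # (56, 2)
    eye_landmarks_3d: np.ndarray  # (56, 3)
    head_translation: np.ndarray
    head_rotation: np.ndarray
    face_landmarks_2d: np.ndarray  # (68, 2)
    face_landmarks_3d: np.ndarray  # (68, 3)
    shape_params: np.ndarray  # 6 rigid + 34 non-rigid
    action_units: np.ndarray  # 17 intensities + 18 presence flags


@dataclass
class SessionTable:
    """Ordered per-frame OpenFace feature records for one processed video.

    ``data`` holds one row per frame with the meta columns plus whichever
    feature groups the source provided.  Invariants (checked on construction):
    frame indices contiguous from 0, timestamps nondecreasing, confidence in
    [0, 1].
    """

    data: pd.DataFrame
    participant_id: str = "unknown"
    fps: float | None = None
    setting: str = "remote"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        for col in _CORE_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"session table missing column {col!r}")
        if "face_id" not in df.columns:
            df = df.copy()
            df.insert(1, "face_id", 0)
            self.data = df
        n = len(df)
        if n:
            frames = df["frame"].to_numpy()
            if not np.array_equal(frames, np.arange(n)):
                raise SchemaError("frame indices must be contiguous from 0")
            ts = df["timestamp"].to_numpy(dtype=float)
            if np.any(np.diff(ts) < 0):
                raise SchemaError("timestamps must be nondecreasing")
            conf = df["confidence"].to_numpy(dtype=float)
            if conf.min() < -1e-9 or conf.max() > 1 + 1e-9:
                raise SchemaError("confidence must lie in [0, 1]")
        if self.setting not in ("in_lab", "remote"):
            raise SchemaError(f"setting must be 'in_lab' or 'remote', got {self.setting!r}")
        if self.fps is None:
            self.fps = self._estimate_fps()
        elif self.fps <= 0:
            raise SchemaError("fps must be positive")

    def _estimate_fps(self) -> float:
        ts = self.timestamps
        if len(ts) < 2:
            return 30.0
        dt = float(np.median(np.diff(ts)))
        return 1.0 / dt if dt > 0 else 30.0

    # -- accessors ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> np.ndarray:
        return self.data["timestamp"].to_numpy(dtype=float)

    @property
    def confidence(self) -> np.ndarray:
        return self.data["confidence"].to_numpy(dtype=float)

    @property
    def success(self) -> np.ndarray:
        return self.data["success"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)

    def record(self, i: int) -> FrameRecord:
        row = self.data.iloc[i]

        def grab(cols: list[str], shape: tuple[int, ...] | None = None) -> np.ndarray:
            v = row[cols].to_numpy(dtype=float)
            # landmark columns are laid out coordinate-major (all x, all y, ...)
            return v.reshape(shape, order="F") if shape else v

        g = _SCHEMA
        return FrameRecord(
            frame_index=int(row["frame"]),
            timestamp=float(row["timestamp"]),
            success=int(row["success"]),
            confidence=float(row["confidence"]),
            gaze_left=grab(g["gaze"][0:3]),
            gaze_right=grab(g["gaze"][3:6]),
            gaze_avg=grab(g["gaze"][6:9]),
            gaze_angle=grab(g["gaze"][9:11]),
            eye_landmarks_2d=grab(g["eye_landmarks_2d"], (56, 2)),
            eye_landmarks_3d=grab(g["eye_landmarks_3d"], (56, 3)),
            head_translation=grab(g["pose"][:3]),
            head_rotation=grab(g["pose"][3:]),
            face_landmarks_2d=grab(g["face_landmarks_2d"], (68, 2)),
            face_landmarks_3d=grab(g["face_landmarks_3d"], (68, 3)),
            shape_params=grab(g["shape_params"]),
            action_units=grab(g["action_units"]),
        )

    def validate_records(self, atol: float = 1e-3) -> None:
        """Check the per-frame invariants that depend on feature values.

        Gaze direction vectors must be unit length (within ``atol``) on frames
        where the face was successfully tracked.
        """
        ok = self.success == 1
        if not ok.any():
            return
        for eye in ("gaze_0", "gaze_1"):
            cols = [f"{eye}_{a}" for a in "xyz"]
            if not all(c in self.data.columns for c in cols):
                continue
            v = self.data.loc[ok, cols].to_numpy(dtype=float)
            norms = np.linalg.norm(v, axis=1)
            bad = np.flatnonzero(np.abs(norms - 1.0) > atol)
            if bad.size:
                i = int(np.flatnonzero(ok)[bad[0]])
                raise SchemaError(
                    f"{eye} vector on frame {i} has norm {norms[bad[0]]:.6f}, expected 1"
                )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _present_schema_columns(df: pd.DataFrame) -> list[str]:
    """Schema columns present in ``df``; incomplete groups raise."""
    cols = set(df.columns)
    out = [c for c in META_COLUMNS if c in cols]
    for name, group in _SCHEMA.items():
        native = [c for c in group if c not in GAZE_DERIVED]
        have = [c for c in native if c in cols]
        if have and len(have) != len(native):
            missing = sorted(set(native) - cols)
            raise SchemaError(
                f"feature group {name!r} is incomplete: missing {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        if have:
            out.extend(c for c in group if c in cols or c in GAZE_DERIVED and name == "gaze")
    return out


def _coerce_numeric(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for col in cols:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw.iloc[i]!r} in column {col!r}, data row {i + 1}"
            )
        df[col] = num.astype(float)
    return df


def _derive_gaze_avg(df: pd.DataFrame) -> pd.DataFrame:
    left = df[[f"gaze_0_{a}" for a in "xyz"]].to_numpy(dtype=float)
    right = df[[f"gaze_1_{a}" for a in "xyz"]].to_numpy(dtype=float)
    avg = 0.5 * (left + right)
    norms = np.linalg.norm(avg, axis=1, keepdims=True)
    avg = avg / np.maximum(norms, 1e-12)
    for j, name in enumerate(GAZE_DERIVED):
        df[name] = avg[:, j]
    return df


def read_openface_csv(
    path,
    participant_id: str = "unknown",
    setting: str = "remote",
    fps: float | None = None,
    metadata: dict[str, str] | None = None,
) -> SessionTable:
    """Parse an OpenFace output CSV into a :class:`SessionTable`.

    Header names are whitespace-stripped (some OpenFace releases pad them),
    the 1-based frame column is rebased to 0, and the derived average-gaze
    columns are appended when absent.  Row order is preserved.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]

    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    gaze_native = [c for c in _SCHEMA["gaze"] if c not in GAZE_DERIVED]
    missing += [c for c in gaze_native if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    keep = _present_schema_columns(df)
    numeric = [c for c in keep if c in df.columns]
    df = df[numeric].copy()
    df = _coerce_numeric(df, numeric)

    if len(df):
        df["frame"] = (df["frame"] - df["frame"].iloc[0]).astype(int)
        df["success"] = df["success"].astype(int)
        if "face_id" in df.columns:
            df["face_id"] = df["face_id"].astype(int)
    else:
        df["frame"] = df["frame"].astype(int)
        df["success"] = df["success"].astype(int)
    if not all(c in df.columns for c in GAZE_DERIVED):
        if len(df):
            df = _derive_gaze_avg(df)
        else:
            for name in GAZE_DERIVED:
                df[name] = pd.Series(dtype=float)
    # canonical column order
    order = [c for c in META_COLUMNS if c in df.columns]
    for group in _SCHEMA.values():
        order.extend(c for c in group if c in df.columns)
    df = df[order]
    return SessionTable(
        data=df.reset_index(drop=True),
        participant_id=participant_id,
        setting=setting,
        fps=fps,
        metadata=dict(metadata or {}),
    )


def write_openface_csv(table: SessionTable, path) -> str:
    """Write ``table`` in the OpenFace dialect (1-based frame column).

    The output is re-readable by :func:`read_openface_csv`; a write/read round
    trip reproduces every numeric field exactly (pandas emits shortest
    round-trip float representations).
    """
    df = table.data.copy()
    df["frame"] = df["frame"].astype(int) + 1
    df.to_csv(path, index=False)
    return str(path)


def session_from_arrays(
    timestamps: np.ndarray,
    confidence: np.ndarray,
    success: np.ndarray,
    features: dict[str, np.ndarray],
    **kwargs,
) -> SessionTable:
    """Assemble a SessionTable from column arrays (simulator back door).

    ``features`` maps schema column name -> per-frame values; any schema
    column not provided is omitted.  Validation is as for the constructor.
    """
    n = len(timestamps)
    data = {
        "frame": np.arange(n, dtype=int),
        "face_id": np.zeros(n, dtype=int),
        "timestamp": np.asarray(timestamps, dtype=float),
        "confidence": np.asarray(confidence, dtype=float),
        "success": np.asarray(success, dtype=int),
    }
    for col in feature_columns():
        if col in features:
            data[col] = np.asarray(features[col], dtype=float)
    df = pd.DataFrame(data)
    gaze_native = [c for c in _SCHEMA["gaze"][:6]]
    if all(c in df.columns for c in gaze_native) and not all(
        c in df.columns for c in GAZE_DERIVED
    ):
        if len(df):
            df = _derive_gaze_avg(df)
        else:
            for name in GAZE_DERIVED:
                df[name] = pd.Series(dtype=float)
        order = [c for c in META_COLUMNS if c in df.columns]
        for group in _SCHEMA.values():
            order.extend(c for c in group if c in df.columns)
        df = df[order]
    return SessionTable(data=df, **kwargs)


def mean_confidence_pct(table: SessionTable) -> float:
    """Mean per-frame confidence on the percent scale (convenience)."""
    if table.n_frames == 0:
        raise SchemaError("empty session table")
    return float(table.confidence.mean() * 100.0)
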