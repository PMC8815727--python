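"""MAAP session timeline and per-frame AOI labeling.

The MAAP (Multisensory Attention Assessment Protocol) is a three-screen
audiovisual looking-time task: each trial presents a 3-s silent central event
followed by two 12-s side-by-side lateral events, one of which is synchronised
with the soundtrack.  Sessions open with a sequence of attention getters —
salient stimuli at known screen locations (center, left, right) that give the
gaze classifier ground-truth labels without a live coder.

This module builds session timelines and converts either live-coder look logs
or the attention-getter schedule into per-frame AOI label series.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .openface_io import SessionTable

__all__ = [
    "AOI",
    "ON_SCREEN_AOIS",
    "AOILabelSeries",
    "Look",
    "AttentionGetterEvent",
    "TrialSpec",
    "SessionProtocol",
    "default_maap_protocol",
    "labels_from_calibration",
    "labels_from_coder_looks",
]


class AOI(enum.IntEnum):
    """Screen area of interest, plus off-screen and unlabeled sentinels."""

    LEFT = 0
    CENTER = 1
    RIGHT = 2
    OFF = 3
    UNLABELED = 4

    def __str__(self) -> str:  # CSV-friendly
        return self.name


ON_SCREEN_AOIS = (AOI.LEFT, AOI.CENTER, AOI.RIGHT)


@dataclass
class AOILabelSeries:
    """Per-frame AOI labels with provenance.

    ``codes`` is an int8 array of :class:`AOI` values, one entry per session
    frame; ``source`` records where the labels came from (``coder`` |
    ``calibration`` | ``model`` | ``truth``).
    """

    codes: np.ndarray
    source: str = "truth"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise ConfigError("label codes must be one-dimensional")
        if self.source not in ("coder", "calibration", "model", "truth"):
            raise ConfigError(f"unknown label source {self.source!r}")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 4):
            raise ConfigError("label codes out of range")

    def __len__(self) -> int:
        return len(self.codes)

    def labels(self) -> list[str]:
        return [AOI(c).name for c in self.codes]

    def counts(self) -> dict[str, int]:
        return {a.name: int((self.codes == a).sum()) for a in AOI}

    def on_screen_mask(self) -> np.ndarray:
        return self.codes <= AOI.RIGHT

    @classmethod
    def from_names(cls, names, source: str = "truth") -> "AOILabelSeries":
        codes = np.array([AOI[str(n)].value for n in names], dtype=np.int8)
        return cls(codes, source=source)

    def to_frame(self, table: SessionTable | None = None) -> pd.DataFrame:
        ts = table.timestamps if table is not None else np.arange(len(self)) * np.nan
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "timestamp": ts,
                "label": self.labels(),
                "source": self.source,
            }
        )

    def write_csv(self, path, table: SessionTable | None = None) -> str:
        self.to_frame(table).to_csv(path, index=False)
        return str(path)

    @classmethod
    def read_csv(cls, path) -> "AOILabelSeries":
        df = pd.read_csv(path)
        source = str(df["source"].iloc[0]) if len(df) else "truth"
        return cls.from_names(df["label"], source=source)


@dataclass(frozen=True)
class Look:
    """A maximal contiguous interval of gaze in one on-screen AOI."""

    aoi: AOI
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.aoi not in ON_SCREEN_AOIS:
            raise ConfigError("looks carry only on-screen AOIs")
        if not self.offset > self.onset:
            raise ConfigError("look duration must be positive")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def looks_to_frame(looks: list[Look], participant_id: str = "unknown") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "aoi": [lk.aoi.name for lk in looks],
            "onset_s": [lk.onset for lk in looks],
            "offset_s": [lk.offset for lk in looks],
            "duration_s": [lk.duration for lk in looks],
        }
    )


def write_looks_csv(looks: list[Look], path, participant_id: str = "unknown") -> str:
    looks_to_frame(looks, participant_id).to_csv(path, index=False)
    return str(path)


def read_looks_csv(path) -> list[Look]:
    df = pd.read_csv(path)
    return [
        Look(AOI[str(r.aoi)], float(r.onset_s), float(r.offset_s))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# timeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttentionGetterEvent:
    """A calibration stimulus at a known screen location."""

    location: AOI
    onset: float
    duration_ms: float = 1500.0

    def __post_init__(self) -> None:
        if self.location not in ON_SCREEN_AOIS:
            raise ConfigError("attention getters appear at on-screen locations")
        if self.duration_ms <= 0:
            raise ConfigError("getter duration must be positive")

    @property
    def offset(self) -> float:
        return self.onset + self.duration_ms / 1000.0


@dataclass(frozen=True)
class TrialSpec:
    """One MAAP trial: silent central event, then two lateral events."""

    index: int
    condition: str  # "social" | "nonsocial"
    central_onset: float
    central_duration: float = 3.0
    lateral_duration: float = 12.0
    sync_side: AOI = AOI.LEFT

    def __post_init__(self) -> None:
        if self.condition not in ("social", "nonsocial"):
            raise ConfigError(f"unknown trial condition {self.condition!r}")
        if self.central_duration <= 0 or self.lateral_duration <= 0:
            raise ConfigError("trial phase durations must be positive")
        if self.sync_side not in (AOI.LEFT, AOI.RIGHT):
            raise ConfigError("sync side must be LEFT or RIGHT")

    @property
    def lateral_onset(self) -> float:
        return self.central_onset + self.central_duration

    @property
    def onset(self) -> float:
        return self.central_onset

    @property
    def offset(self) -> float:
        return self.lateral_onset + self.lateral_duration

    @property
    def duration(self) -> float:
        return self.central_duration + self.lateral_duration


@dataclass
class SessionProtocol:
    """Timed calibration getters plus ordered MAAP trials."""

    calibration: list[AttentionGetterEvent] = field(default_factory=list)
    trials: list[TrialSpec] = field(default_factory=list)
    inter_trial_gap: float = 1.0

    def __post_init__(self) -> None:
        events = [(g.onset, g.offset) for g in self.calibration] + [
            (t.onset, t.offset) for t in self.trials
        ]
        for (a0, a1), (b0, b1) in zip(events, events[1:]):
            if b0 < a1 - 1e-9 or a0 > b0:
                raise ConfigError("protocol events must be time-ordered and non-overlapping")

    @property
    def total_duration(self) -> float:
        ends = [g.offset for g in self.calibration] + [t.offset for t in self.trials]
        return max(ends) if ends else 0.0


def default_maap_protocol(
    n_trials: int = 24,
    block_size: int = 6,
    getter_duration_ms: float = 1500.0,
    getter_repeats: int = 2,
    central_duration: float = 3.0,
    lateral_duration: float = 12.0,
    inter_trial_gap: float = 1.0,
    lead_in_gap: float = 1.0,
    first_condition: str = "social",
) -> SessionProtocol:
    """Construct the default MAAP timeline.

    Calibration: attention getters in the order center, left, center, right,
    with the whole sequence repeated (8 events of 1,500 ms by default, played
    back to back).  Trials: 24 trials of 3 s central + 12 s lateral, in
    alternating blocks of six social / six nonsocial trials, with the
    sound-synchronised side counterbalanced left/right within each block.
    """
    if getter_duration_ms <= 0 or central_duration <= 0 or lateral_duration <= 0:
        raise ConfigError("durations must be positive")
    if n_trials <= 0 or block_size <= 0 or getter_repeats <= 0:
        raise ConfigError("counts must be positive")

    base = [AOI.CENTER, AOI.LEFT, AOI.CENTER, AOI.RIGHT]
    getter_s = getter_duration_ms / 1000.0
    calibration = []
    t = 0.0
    for _ in range(getter_repeats):
        for loc in base:
            calibration.append(AttentionGetterEvent(loc, t, getter_duration_ms))
            t += getter_s

    trials = []
    t += lead_in_gap
    other = {"social": "nonsocial", "nonsocial": "social"}
    for i in range(n_trials):
        block = i // block_size
        condition = first_condition if block % 2 == 0 else other[first_condition]
        within = i % block_size
        # counterbalance: alternate sides within block, flip the starting side
        # on odd blocks
        start_left = block % 2 == 0
        sync = AOI.LEFT if (within % 2 == 0) == start_left else AOI.RIGHT
        trials.append(
            TrialSpec(
                index=i,
                condition=condition,
                central_onset=t,
                central_duration=central_duration,
                lateral_duration=lateral_duration,
                sync_side=sync,
            )
        )
        t += central_duration + lateral_duration
        if i < n_trials - 1:
            t += inter_trial_gap
    return SessionProtocol(calibration=calibration, trials=trials, inter_trial_gap=inter_trial_gap)


def protocol_to_dict(protocol: SessionProtocol) -> dict:
    return {
        "calibration": [
            {"location": g.location.name, "onset": g.onset, "duration_ms": g.duration_ms}
            for g in protocol.calibration
        ],
        "trials": [
            {
                "index": t.index,
                "condition": t.condition,
                "central_onset": t.central_onset,
                "central_duration": t.central_duration,
                "lateral_duration": t.lateral_duration,
                "sync_side": t.sync_side.name,
            }
            for t in protocol.trials
        ],
        "inter_trial_gap": protocol.inter_trial_gap,
    }


def protocol_from_dict(doc: dict) -> SessionProtocol:
    return SessionProtocol(
        calibration=[
            AttentionGetterEvent(AOI[g["location"]], g["onset"], g["duration_ms"])
            for g in doc.get("calibration", [])
        ],
        trials=[
            TrialSpec(
                index=t["index"],
                condition=t["condition"],
                central_onset=t["central_onset"],
                central_duration=t["central_duration"],
                lateral_duration=t["lateral_duration"],
                sync_side=AOI[t["sync_side"]],
            )
            for t in doc.get("trials", [])
        ],
        inter_trial_gap=doc.get("inter_trial_gap", 1.0),
    )


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------


def labels_from_calibration(
    protocol: SessionProtocol,
    table: SessionTable,
    trim_ms: float = 300.0,
    cfg=None,
) -> AOILabelSeries:
    """Label frames inside attention-getter windows with the getter location.

    The first ``trim_ms`` of each window is left UNLABELED to skip the
    saccade-latency period (children are not instructed to fixate, so frames
    right after getter onset may still show the previous gaze target).  When a
    :class:`~openlook.quality.QualityConfig` is supplied, frames failing the
    usability rule (success and confidence threshold) are also left UNLABELED;
    pass ``cfg=None`` for pure window-membership labels (used e.g. to measure
    face visibility during calibration).
    """
    if not protocol.calibration:
        raise ConfigError("protocol has no calibration events")
    ts = table.timestamps
    if table.n_frames == 0:
        raise AlignmentError("session table is empty")
    last = max(g.offset for g in protocol.calibration)
    if ts[-1] < min(g.onset for g in protocol.calibration):
        raise AlignmentError("session table ends before the calibration span")

    codes = np.full(table.n_frames, AOI.UNLABELED, dtype=np.int8)
    for getter in protocol.calibration:
        lo = getter.onset + trim_ms / 1000.0
        hi = getter.offset
        mask = (ts >= lo) & (ts < hi)
        codes[mask] = getter.location
    if cfg is not None:
        from .quality import frame_quality_flags

        usable = frame_quality_flags(table, cfg)
        codes[~usable] = AOI.UNLABELED
    return AOILabelSeries(codes, source="calibration")


def labels_from_coder_looks(looks: list[Look], table: SessionTable) -> AOILabelSeries:
    """Expand a live-coder look log into per-frame labels.

    Each frame whose timestamp falls in a look's half-open span ``[onset,
    offset)`` receives that look's AOI; all other frames are UNLABELED.
    """
    ordered = sorted(looks, key=lambda lk: lk.onset)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset < a.offset - 1e-12:
            raise ConfigError(
                f"overlapping looks: {a.aoi.name} [{a.onset}, {a.offset}) and "
                f"{b.aoi.name} [{b.onset}, {b.offset})"
            )
    ts = table.timestamps
    codes = np.full(table.n_frames, AOI.UNLABELED, dtype=np.int8)
    for lk in ordered:
        codes[(ts >= lk.onset) & (ts < lk.offset)] = lk.aoi
    return AOILabelSeries(codes, source="coder")
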