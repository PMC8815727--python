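"""Frame-quality and participant-inclusion rules.

OpenFace attaches a confidence rating (0-100%) to every frame, summarising how
well face, head pose and gaze were identified; occluded or partly out-of-frame
faces score low.  This module summarises those ratings, flags usable frames,
applies the participant inclusion rules (enough valid trials, face visible
during calibration), and implements the pre-session internet connection check
used before remote testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .openface_io import SessionTable
from .protocol import AOI, AOILabelSeries, SessionProtocol

__all__ = [
    "ConfidenceSummary",
    "QualityConfig",
    "InclusionDecision",
    "confidence_summary",
    "frame_quality_flags",
    "participant_inclusion",
    "check_connection",
]

# quartile bins on the percent scale: [0,25), [25,50), [50,75), [75,100]
_BIN_EDGES = (0.25, 0.50, 0.75)


@dataclass
class ConfidenceSummary:
    """Mean/SD of per-frame confidence plus quartile-bin proportions."""

    mean_pct: float
    sd_pct: float
    n_frames: int
    bin_proportions: tuple[float, float, float, float]

    def to_dict(self) -> dict:
        return {
            "mean_pct": self.mean_pct,
            "sd_pct": self.sd_pct,
            "n_frames": self.n_frames,
            "bin_proportions": list(self.bin_proportions),
        }


@dataclass
class QualityConfig:
    """Thresholds for frame usability, inclusion, and the connection check.

    ``min_confidence`` defaults to 0.75 — the top quartile bin of the
    confidence distribution ("75% or higher"); no a-priori criterion exists in
    the source protocol, so this is a configurable post-hoc choice.
    ``download_mbps_min``/``ping_ms_max`` are strict bounds (>50 mbps, <25 ms).
    """

    min_confidence: float = 0.75
    min_calibration_visible_fraction: float = 0.5
    min_valid_trials: int = 5
    trials_per_block: int = 6
    download_mbps_min: float = 50.0
    ping_ms_max: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigError("min_confidence must lie in [0, 1]")
        if not 0.0 <= self.min_calibration_visible_fraction <= 1.0:
            raise ConfigError("min_calibration_visible_fraction must lie in [0, 1]")
        if self.min_valid_trials < 0 or self.trials_per_block <= 0:
            raise ConfigError("trial thresholds must be nonnegative")


@dataclass
class InclusionDecision:
    include: bool
    reasons: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"include": self.include, "reasons": self.reasons, "details": self.details}
        )


def confidence_summary(table: SessionTable) -> ConfidenceSummary:
    """Summarise per-frame confidence, averaged across all frames.

    Mean and population SD are reported on the percent scale; bin proportions
    cover the quartiles [0,25), [25,50), [50,75) and [75,100] (a confidence of
    exactly 0.75 counts in the top bin).
    """
    if table.n_frames == 0:
        raise ConfigError("cannot summarise an empty session table")
    conf = table.confidence
    bins = np.array(
        [
            (conf < _BIN_EDGES[0]).mean(),
            ((conf >= _BIN_EDGES[0]) & (conf < _BIN_EDGES[1])).mean(),
            ((conf >= _BIN_EDGES[1]) & (conf < _BIN_EDGES[2])).mean(),
            (conf >= _BIN_EDGES[2]).mean(),
        ]
    )
    return ConfidenceSummary(
        mean_pct=float(conf.mean() * 100.0),
        sd_pct=float(conf.std(ddof=0) * 100.0),
        n_frames=table.n_frames,
        bin_proportions=tuple(float(b) for b in bins),
    )


def frame_quality_flags(table: SessionTable, cfg: QualityConfig | None = None) -> np.ndarray:
    """Boolean usability per frame: tracked successfully and confident enough."""
    cfg = cfg or QualityConfig()
    return (table.success == 1) & (table.confidence >= cfg.min_confidence)


def participant_inclusion(
    table: SessionTable,
    calibration_labels: AOILabelSeries,
    trial_validity,
    cfg: QualityConfig | None = None,
    protocol: SessionProtocol | None = None,
) -> InclusionDecision:
    """Apply the participant inclusion rules.

    Excludes when (a) fewer than ``min_valid_trials`` of each
    ``trials_per_block`` block are valid, or (b) the usable-frame fraction
    during the calibration windows falls below
    ``min_calibration_visible_fraction`` — the operational form of "the face
    must be fully visible during calibration".

    Calibration windows are taken from ``protocol`` when given; otherwise from
    the frames ``calibration_labels`` marks as labeled (pass quality-ungated
    labels, i.e. ``labels_from_calibration(..., cfg=None)``, so the window
    membership is not already filtered by the rule being measured).
    """
    cfg = cfg or QualityConfig()
    validity = np.asarray(list(trial_validity), dtype=bool)
    if validity.size == 0:
        raise ConfigError("trial_validity must be nonempty")
    reasons: list[str] = []
    details: dict = {}

    usable = frame_quality_flags(table, cfg)
    if protocol is not None:
        ts = table.timestamps
        in_window = np.zeros(table.n_frames, dtype=bool)
        for g in protocol.calibration:
            in_window |= (ts >= g.onset) & (ts < g.offset)
    else:
        if len(calibration_labels) != table.n_frames:
            raise ConfigError("calibration labels must match the table length")
        in_window = calibration_labels.codes != AOI.UNLABELED
    if in_window.any():
        visible = float(usable[in_window].mean())
    else:
        visible = 0.0
    details["calibration_visible_fraction"] = visible
    if visible < cfg.min_calibration_visible_fraction:
        reasons.append("face_visibility")

    n_blocks = int(np.ceil(validity.size / cfg.trials_per_block))
    valid_per_block = [
        int(validity[b * cfg.trials_per_block : (b + 1) * cfg.trials_per_block].sum())
        for b in range(n_blocks)
    ]
    details["valid_trials_per_block"] = valid_per_block
    if any(v < cfg.min_valid_trials for v in valid_per_block):
        reasons.append("insufficient_trials")

    return InclusionDecision(include=not reasons, reasons=reasons, details=details)


def check_connection(
    download_mbps: float, ping_ms: float, cfg: QualityConfig | None = None
) -> tuple[bool, list[str]]:
    """Pre-session connection check: download > 50 mbps and ping < 25 ms.

    Both bounds are strict; values on the boundary fail.
    """
    cfg = cfg or QualityConfig()
    if download_mbps < 0 or ping_ms < 0:
        raise ConfigError("connection measurements must be nonnegative")
    reasons = []
    if not download_mbps > cfg.download_mbps_min:
        reasons.append("download_speed")
    if not ping_ms < cfg.ping_ms_max:
        reasons.append("ping")
    return (not reasons, reasons)
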