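"""Look segmentation and MAAP attention metrics.

Converts per-frame AOI labels into looks (maximal contiguous fixation bouts
to one screen region) and computes trial-level multisensory attention skill
(MASk) measures: duration of looking, speed of shifting to the lateral
events, and accuracy of audiovisual matching.

The MASk formulas here are explicit operational stand-ins (the protocol's
published definitions live in its own literature and are not reproduced):

* duration of looking: time on any on-screen AOI / trial length,
* shift latency: lateral-event onset to the first lateral-AOI look,
* matching: sync-side looking / total lateral looking during the lateral
  phase, defined only when total lateral looking is at least ``min_lateral_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .protocol import AOI, AOILabelSeries, Look, SessionProtocol, TrialSpec

__all__ = [
    "SegmentationConfig",
    "MaapMetrics",
    "frames_to_looks",
    "trial_looking_durations",
    "maap_summary",
]

METRICS_NOTE = (
    "MASk formulas are operational stand-ins defined by this package, "
    "not the protocol's published definitions"
)


@dataclass(frozen=True)
class SegmentationConfig:
    """Run-length smoothing parameters for frame-label segmentation."""

    min_look_ms: float = 100.0
    bridge_gap_frames: int = 1

    def __post_init__(self) -> None:
        if self.min_look_ms < 0 or self.bridge_gap_frames < 0:
            raise ConfigError("segmentation parameters must be nonnegative")


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, code) for maximal equal-value runs; stop exclusive."""
    if codes.size == 0:
        return []
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [codes.size]))
    return [(int(a), int(b), int(codes[a])) for a, b in zip(starts, stops)]


def frames_to_looks(
    series: AOILabelSeries, fps: float, cfg: SegmentationConfig | None = None
) -> list[Look]:
    """Segment per-frame labels into looks.

    OFF/UNLABELED gaps of at most ``bridge_gap_frames`` frames flanked by the
    same AOI are bridged, then maximal same-AOI runs lasting at least
    ``min_look_ms`` become looks with half-open time spans (frame ``i`` covers
    ``[i/fps, (i+1)/fps)``).  OFF/UNLABELED never produce looks.
    """
    if fps <= 0:
        raise ConfigError("fps must be positive")
    cfg = cfg or SegmentationConfig()
    codes = series.codes.copy()

    if cfg.bridge_gap_frames > 0:
        runs = _runs(codes)
        for j in range(1, len(runs) - 1):
            a, b, code = runs[j]
            prev_code = runs[j - 1][2]
            next_code = runs[j + 1][2]
            if (
                code >= AOI.OFF
                and b - a <= cfg.bridge_gap_frames
                and prev_code == next_code
                and prev_code <= AOI.RIGHT
            ):
                codes[a:b] = prev_code

    looks: list[Look] = []
    for a, b, code in _runs(codes):
        if code > AOI.RIGHT:
            continue
        duration_ms = (b - a) / fps * 1000.0
        if duration_ms + 1e-9 < cfg.min_look_ms:
            continue
        looks.append(Look(AOI(code), a / fps, b / fps))
    return looks


def _overlap(onset: float, offset: float, lo: float, hi: float) -> float:
    return max(0.0, min(offset, hi) - max(onset, lo))


def trial_looking_durations(looks: list[Look], trial: TrialSpec) -> dict[AOI, float]:
    """Seconds of looking per AOI within the trial window (spans clipped)."""
    out = {AOI.LEFT: 0.0, AOI.CENTER: 0.0, AOI.RIGHT: 0.0}
    for lk in looks:
        out[lk.aoi] += _overlap(lk.onset, lk.offset, trial.onset, trial.offset)
    return out


@dataclass
class MaapMetrics:
    """Per-trial and mean MASk measures for one session."""

    per_trial: pd.DataFrame
    means: dict[str, float]
    n_missing: dict[str, int]
    notes: str = METRICS_NOTE
    thresholds: dict = field(default_factory=dict)

    def write_csv(self, path, participant_id: str = "unknown") -> str:
        long = self.per_trial.melt(
            id_vars=["trial", "condition"], var_name="metric", value_name="value"
        )
        long.insert(0, "participant_id", participant_id)
        long.to_csv(path, index=False)
        return str(path)


def maap_summary(
    looks: list[Look],
    protocol: SessionProtocol,
    min_lateral_s: float = 0.5,
) -> MaapMetrics:
    """Compute the three MASk measures per trial plus session means.

    A trial with no lateral-AOI looking has missing shift latency and
    matching; matching additionally requires at least ``min_lateral_s`` of
    total lateral looking.  Means skip missing values; missing counts are
    reported alongside.
    """
    if not protocol.trials:
        raise ConfigError("protocol has no trials")
    rows = []
    for trial in protocol.trials:
        durs = trial_looking_durations(looks, trial)
        duration_prop = sum(durs.values()) / trial.duration

        lateral_lo, lateral_hi = trial.lateral_onset, trial.offset
        latency = np.nan
        for lk in sorted(looks, key=lambda l: l.onset):
            if lk.aoi in (AOI.LEFT, AOI.RIGHT) and lk.offset > lateral_lo and lk.onset < lateral_hi:
                latency = max(lk.onset, lateral_lo) - lateral_lo
                break

        sync = sum(
            _overlap(lk.onset, lk.offset, lateral_lo, lateral_hi)
            for lk in looks
            if lk.aoi == trial.sync_side
        )
        lateral_total = sum(
            _overlap(lk.onset, lk.offset, lateral_lo, lateral_hi)
            for lk in looks
            if lk.aoi in (AOI.LEFT, AOI.RIGHT)
        )
        matching = sync / lateral_total if lateral_total >= min_lateral_s else np.nan

        rows.append(
            {
                "trial": trial.index,
                "condition": trial.condition,
                "looking_duration_prop": duration_prop,
                "shift_latency_s": latency,
                "matching_prop": matching,
            }
        )
    df = pd.DataFrame(rows)
    metric_cols = ["looking_duration_prop", "shift_latency_s", "matching_prop"]
    means = {c: float(df[c].mean(skipna=True)) for c in metric_cols}
    n_missing = {c: int(df[c].isna().sum()) for c in metric_cols}
    return MaapMetrics(
        per_trial=df,
        means=means,
        n_missing=n_missing,
        thresholds={"min_lateral_s": min_lateral_s},
    )
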