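"""Frame-wise agreement and inter-observer reliability.

Percent agreement is the number of frames on which two label sources give the
same AOI, divided by the compared frames.  Frames the reference leaves
UNLABELED (and OFF, unless off-screen frames are compared as a fourth class)
are excluded from the denominator.  The overall percentage is therefore a
frame-count-weighted average across AOIs; the unweighted (macro) mean across
per-AOI agreements is reported alongside, since the two differ whenever
looking is unevenly distributed across locations.

Inter-observer reliability follows the absolute-difference approach: for each
summary measure, the per-participant |a - b| between two coders, its median,
and the median scaled by the range of possible scores (values near 0 indicate
measures free of random error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .protocol import AOI, AOILabelSeries

__all__ = [
    "AgreementReport",
    "ReliabilityReport",
    "percent_agreement",
    "reliability_absdiff",
    "agreement_group_means",
]


@dataclass
class AgreementReport:
    overall_pct: float
    per_aoi_pct: dict[str, float]
    macro_avg_pct: float
    confusion: pd.DataFrame  # rows: reference AOI, columns: predicted label
    n_compared: int
    n_excluded: int
    group_means: dict[str, float] | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "overall_pct": self.overall_pct,
            "per_aoi_pct": self.per_aoi_pct,
            "macro_avg_pct": self.macro_avg_pct,
            "n_compared": self.n_compared,
            "n_excluded": self.n_excluded,
            "group_means": self.group_means,
        }


def percent_agreement(
    pred: AOILabelSeries, ref: AOILabelSeries, compare_off: bool = False
) -> AgreementReport:
    """Frame-wise percent agreement of ``pred`` against a reference series.

    Per-AOI agreement is conditional on the reference label (of the frames
    the reference called LEFT, what fraction did the prediction also call
    LEFT).  With ``compare_off=True``, OFF becomes a fourth compared class.
    """
    if len(pred) != len(ref):
        raise ConfigError(
            f"series lengths differ: {len(pred)} vs {len(ref)} frames"
        )
    ref_classes = [AOI.LEFT, AOI.CENTER, AOI.RIGHT] + ([AOI.OFF] if compare_off else [])
    mask = np.isin(ref.codes, [int(a) for a in ref_classes])
    n_compared = int(mask.sum())
    n_excluded = len(ref) - n_compared
    if n_compared == 0:
        raise ConfigError("no comparable frames (reference all OFF/UNLABELED)")

    p = pred.codes[mask]
    r = ref.codes[mask]
    overall = 100.0 * float((p == r).mean())

    per_aoi: dict[str, float] = {}
    for aoi in ref_classes:
        sel = r == aoi
        if sel.any():
            per_aoi[aoi.name] = 100.0 * float((p[sel] == aoi).mean())
    macro = float(np.mean(list(per_aoi.values())))

    pred_classes = list(AOI)
    counts = np.zeros((len(ref_classes), len(pred_classes)), dtype=int)
    for i, ra in enumerate(ref_classes):
        sel = r == ra
        for j, pa in enumerate(pred_classes):
            counts[i, j] = int((p[sel] == pa).sum())
    confusion = pd.DataFrame(
        counts,
        index=[a.name for a in ref_classes],
        columns=[a.name for a in pred_classes],
    )
    return AgreementReport(
        overall_pct=overall,
        per_aoi_pct=per_aoi,
        macro_avg_pct=macro,
        confusion=confusion,
        n_compared=n_compared,
        n_excluded=n_excluded,
    )


def agreement_group_means(
    overall_by_participant: dict[str, float], group_by_participant: dict[str, str]
) -> dict[str, float]:
    """Mean overall agreement per metadata group (no hypothesis tests)."""
    groups: dict[str, list[float]] = {}
    for pid, pct in overall_by_participant.items():
        group = group_by_participant.get(pid)
        if group is not None:
            groups.setdefault(group, []).append(pct)
    return {g: float(np.mean(v)) for g, v in groups.items()}


@dataclass
class ReliabilityReport:
    abs_differences: np.ndarray
    median_absdiff: float
    scaled_median: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "median_absdiff": self.median_absdiff,
            "scaled_median": self.scaled_median,
            "n_pairs": self.n_pairs,
        }


def reliability_absdiff(a, b, score_range: float) -> ReliabilityReport:
    """Absolute differences between two coders' paired measure estimates.

    ``score_range`` is the range of possible scores for the measure (e.g. the
    trial duration for a looking-time measure); the scaled median is the
    median absolute difference divided by that range.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ConfigError("paired measures must be equal-length nonempty vectors")
    if not score_range > 0:
        raise ConfigError("score_range must be positive")
    diffs = np.abs(a - b)
    median = float(np.median(diffs))
    return ReliabilityReport(
        abs_differences=diffs,
        median_absdiff=median,
        scaled_median=median / score_range,
        n_pairs=int(a.size),
    )
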