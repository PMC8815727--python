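"""End-to-end composition: simulate/ingest -> QC -> label -> train -> predict
-> segment -> metrics -> agreement.

These functions are the library-level backbone of the command-line interface
and of the reproducibility script.  All randomness is derived from a single
caller-supplied seed via fixed offsets, so identical (config, seed) pairs
produce identical reports.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .agreement import percent_agreement
from .classifier import (
    ClassifierSpec,
    TrainConfig,
    TrainedClassifier,
    build_network,
    predict_frames,
    split_frames,
    train_classifier,
)
from .errors import ConfigError
from .features import FeatureSpec, assemble_features, fit_standardizer
from .looktime import SegmentationConfig, frames_to_looks, maap_summary
from .protocol import AOI, AOILabelSeries, labels_from_calibration
from .quality import QualityConfig, confidence_summary, frame_quality_flags
from .simulate import SimConfig, simulate_session

__all__ = ["run_pipeline", "chance_agreement", "noise_ladder", "build_configs"]

# fixed offsets deriving substream seeds from the global seed
_SPLIT_OFFSET = 101
_TRAIN_OFFSET = 211
_NET_OFFSET = 307
_LABELS_OFFSET = 401


def _sub_seed(seed: int, offset: int) -> int:
    return int((seed * 1009 + offset) % (2**31 - 1))


def balanced_label_series(n: int, seed: int) -> AOILabelSeries:
    """Exactly balanced L/C/R labels in seeded random order (source truth)."""
    base = np.tile(np.array([AOI.LEFT, AOI.CENTER, AOI.RIGHT], dtype=np.int8), n // 3 + 1)[:n]
    rng = np.random.default_rng(seed)
    return AOILabelSeries(rng.permutation(base), source="truth")


def chance_agreement(seed: int, sim_cfg: SimConfig | None = None) -> float:
    """Frame agreement of an untrained network against balanced truth labels.

    The network gets seeded random initialization and no training; truth is an
    exactly balanced, independently shuffled label series over the session's
    frames.  Expected agreement is the chance level for three classes (~33%).
    Occlusion is disabled so every frame receives an on-screen prediction.
    """
    cfg = replace(sim_cfg or SimConfig(), occlusion_rate_per_s=0.0)
    table, _truth, _looks, _proto = simulate_session(cfg, seed=seed)
    feats = assemble_features(table, FeatureSpec())
    spec = ClassifierSpec(input_dim=feats.n_features)
    net = build_network(spec, seed=_sub_seed(seed, _NET_OFFSET))
    # standardize with whole-session statistics purely for numeric sanity;
    # no labels are involved, so this is not training
    scaler = fit_standardizer(feats, np.arange(feats.n_frames))
    model = TrainedClassifier(spec=spec, networks=[net], standardizer=scaler)
    pred = predict_frames(model, table, feats, QualityConfig(min_confidence=0.0))
    ref = balanced_label_series(table.n_frames, seed=_sub_seed(seed, _LABELS_OFFSET))
    return percent_agreement(pred, ref).overall_pct


def run_pipeline(
    sim_cfg: SimConfig | None = None,
    seed: int = 0,
    quality_cfg: QualityConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    feature_spec: FeatureSpec | None = None,
    train_fraction: float = 0.5,
    trim_ms: float = 300.0,
) -> dict:
    """Simulate a session and run the full coding pipeline on it.

    Training labels come from the attention-getter calibration windows; a
    random ``train_fraction`` of the labeled frames trains the network and
    the model is then evaluated against the simulator's ground truth on every
    usable held-out frame (frames used for training are excluded).
    Returns a JSON-serialisable report.
    """
    sim_cfg = sim_cfg or SimConfig()
    quality_cfg = quality_cfg or QualityConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    feature_spec = feature_spec or FeatureSpec()

    table, truth, truth_looks, protocol = simulate_session(sim_cfg, seed=seed)
    summary = confidence_summary(table)
    usable = frame_quality_flags(table, quality_cfg)

    cal = labels_from_calibration(protocol, table, trim_ms=trim_ms, cfg=quality_cfg)
    labeled_rows = np.flatnonzero(cal.codes <= AOI.RIGHT)
    if labeled_rows.size < 2:
        raise ConfigError("too few usable calibration frames to train")
    split = split_frames(labeled_rows, fraction=train_fraction, seed=_sub_seed(seed, _SPLIT_OFFSET))

    feats = assemble_features(table, feature_spec)
    spec = ClassifierSpec(input_dim=feats.n_features)
    cfg = train_cfg or TrainConfig(seed=_sub_seed(seed, _TRAIN_OFFSET))
    model = train_classifier(spec, feats, cal, split, cfg)
    pred = predict_frames(model, table, feats, quality_cfg)

    in_train = np.zeros(table.n_frames, dtype=bool)
    in_train[split.train_rows] = True
    eval_mask = usable & ~in_train
    report_agreement = percent_agreement(
        AOILabelSeries(pred.codes[eval_mask], source="model"),
        AOILabelSeries(truth.codes[eval_mask], source="truth"),
    )

    looks = frames_to_looks(pred, fps=table.fps, cfg=seg_cfg)
    metrics = maap_summary(looks, protocol)

    return {
        "seed": seed,
        "n_frames": table.n_frames,
        "fps": table.fps,
        "confidence": summary.to_dict(),
        "n_labeled_calibration_frames": int(labeled_rows.size),
        "n_train_frames": int(split.train_rows.size),
        "heldout_agreement": report_agreement.to_dict(),
        "n_looks": len(looks),
        "maap_means": metrics.means,
        "maap_n_missing": metrics.n_missing,
        "metrics_note": metrics.notes,
        "train_epochs_run": len(model.train_log),
    }


def noise_ladder(
    noise_sds=(0.05, 0.15, 0.30), seed: int = 0, sim_cfg: SimConfig | None = None
) -> list[dict]:
    """Held-out pipeline agreement across increasing gaze-noise levels."""
    base = sim_cfg or SimConfig()
    out = []
    for sd in noise_sds:
        rep = run_pipeline(replace(base, gaze_noise_sd=float(sd)), seed=seed)
        out.append(
            {"gaze_noise_sd": float(sd), "heldout_pct": rep["heldout_agreement"]["overall_pct"]}
        )
    return out


# ---------------------------------------------------------------------------
# config documents
# ---------------------------------------------------------------------------

_SIM_KEYS = {
    "fps",
    "aoi_centers",
    "aoi_half_width",
    "gaze_noise_sd",
    "dwell_median_s",
    "dwell_sigma",
    "off_screen_prob",
    "transition_stay",
    "occlusion_rate_per_s",
    "occlusion_mean_s",
    "n_trials",
    "block_size",
    "getter_repeats",
    "inter_trial_gap",
}
_QUALITY_KEYS = {
    "min_confidence",
    "min_calibration_visible_fraction",
    "min_valid_trials",
    "trials_per_block",
    "download_mbps_min",
    "ping_ms_max",
}
_TRAIN_KEYS = {
    "learning_rate",
    "epochs",
    "batch_size",
    "patience",
    "val_fraction",
    "weight_decay",
    "n_ensemble",
}
_SEG_KEYS = {"min_look_ms", "bridge_gap_frames"}
_TOP_KEYS = {"simulation", "quality", "training", "segmentation", "train_fraction", "trim_ms"}


def build_configs(doc: dict, seed: int = 0) -> dict:
    """Validate a run-config document and build the typed config objects.

    Unknown keys are rejected so typos fail loudly.  Returns a dict with
    ``sim_cfg``, ``quality_cfg``, ``train_cfg``, ``seg_cfg``,
    ``train_fraction`` and ``trim_ms``.
    """
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")

    sim_doc = dict(doc.get("simulation", {}))
    bad = set(sim_doc) - _SIM_KEYS
    if bad:
        raise ConfigError(f"unknown simulation key(s): {', '.join(sorted(bad))}")
    from .protocol import default_maap_protocol

    proto_kwargs = {
        k: sim_doc.pop(k)
        for k in ("n_trials", "block_size", "getter_repeats", "inter_trial_gap")
        if k in sim_doc
    }
    if "aoi_centers" in sim_doc:
        sim_doc["aoi_centers"] = tuple(tuple(c) for c in sim_doc["aoi_centers"])
    sim_cfg = SimConfig(protocol=default_maap_protocol(**proto_kwargs), **sim_doc)

    q_doc = dict(doc.get("quality", {}))
    bad = set(q_doc) - _QUALITY_KEYS
    if bad:
        raise ConfigError(f"unknown quality key(s): {', '.join(sorted(bad))}")
    quality_cfg = QualityConfig(**q_doc)

    t_doc = dict(doc.get("training", {}))
    bad = set(t_doc) - _TRAIN_KEYS
    if bad:
        raise ConfigError(f"unknown training key(s): {', '.join(sorted(bad))}")
    train_cfg = TrainConfig(seed=_sub_seed(seed, _TRAIN_OFFSET), **t_doc)

    s_doc = dict(doc.get("segmentation", {}))
    bad = set(s_doc) - _SEG_KEYS
    if bad:
        raise ConfigError(f"unknown segmentation key(s): {', '.join(sorted(bad))}")
    seg_cfg = SegmentationConfig(**s_doc)

    return {
        "sim_cfg": sim_cfg,
        "quality_cfg": quality_cfg,
        "train_cfg": train_cfg,
        "seg_cfg": seg_cfg,
        "train_fraction": float(doc.get("train_fraction", 0.5)),
        "trim_ms": float(doc.get("trim_ms", 300.0)),
    }
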