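"""Synthetic MAAP sessions in the OpenFace output schema.

The generator emulates what the pipeline assumes about real webcam sessions:
a child whose gaze dwells on one of three screen regions at a time, snapping
to attention getters at known locations during calibration (after a saccade
latency), with occasional off-screen glances and occlusion episodes during
which OpenFace loses the face (success = 0, low confidence).

AOIs are defined generatively in gaze-angle space (yaw/pitch radians), not in
screen pixels: the whole point of the classifier is that OpenFace output has
no external frame of reference, so the simulator never hit-tests a screen —
it places gaze-angle clusters at distinct locations and lets the network
learn the mapping.  Eye-region landmarks move with the estimated gaze angle
(in real OpenFace output the gaze vector is computed from them); face
landmarks, head pose, shape parameters and action units are low-signal
correlates of head pose (not of the AOI), so a classifier must rely on the
gaze-bearing features.

Defaults place adjacent AOI centers 0.35 rad apart with 0.05 rad frame noise
(7 noise SDs): learnable but not trivial.  ``SimConfig.hard()`` halves the
separation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .openface_io import SessionTable, column_groups, session_from_arrays, write_openface_csv
from .protocol import (
    AOI,
    AOILabelSeries,
    Look,
    SessionProtocol,
    default_maap_protocol,
    write_looks_csv,
)

__all__ = ["SimConfig", "simulate_session", "simulate_coder", "emit_session"]

_ON = (AOI.LEFT, AOI.CENTER, AOI.RIGHT)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic session."""

    protocol: SessionProtocol = field(default_factory=default_maap_protocol)
    fps: float = 30.0
    # AOI geometry in gaze-angle space (yaw, pitch), radians
    aoi_centers: tuple[tuple[float, float], ...] = ((-0.35, 0.0), (0.0, 0.0), (0.35, 0.0))
    aoi_half_width: float = 0.10
    gaze_noise_sd: float = 0.05
    # dwell process
    dwell_median_s: float = 1.5
    dwell_sigma: float = 0.6
    dwell_bounds_s: tuple[float, float] = (0.2, 8.0)
    off_screen_prob: float = 0.05
    transition_stay: float = 0.1  # probability of re-fixating the same AOI
    # calibration saccade latency, ms
    getter_latency_ms: tuple[float, float] = (150.0, 400.0)
    # fixation scatter on a getter, as an SD in units of the AOI half-width
    # (the getter is a single salient point at the AOI center, so fixations
    # land much closer to it than free looking spreads over an AOI)
    getter_fixation_scatter: float = 0.25
    # nuisance dynamics: mean-reverting walk around a home position (a seated
    # child fidgets but stays in front of the camera)
    head_translation_walk_mm: float = 0.5
    head_rotation_walk_rad: float = 0.002
    head_pose_reversion: float = 0.2  # per-frame pull toward the home position
    # occlusion process
    occlusion_rate_per_s: float = 0.02
    occlusion_mean_s: float = 1.0
    occlusion_bounds_s: tuple[float, float] = (0.2, 3.0)
    occluded_confidence: tuple[float, float] = (0.0, 0.3)
    confidence_beta: tuple[float, float] = (18.0, 2.0)  # mean ~0.9

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if not 0.0 <= self.off_screen_prob < 1.0:
            raise ConfigError("off_screen_prob must lie in [0, 1)")
        if not 0.0 <= self.transition_stay < 1.0:
            raise ConfigError("transition_stay must lie in [0, 1)")
        if self.aoi_half_width <= 0 or self.gaze_noise_sd < 0:
            raise ConfigError("angle parameters must be positive")
        centers = np.asarray(self.aoi_centers, dtype=float)
        if centers.shape != (3, 2):
            raise ConfigError("aoi_centers must give (yaw, pitch) for LEFT, CENTER, RIGHT")
        for i in range(3):
            for j in range(i + 1, 3):
                d = float(np.linalg.norm(centers[i] - centers[j]))
                if d <= 2 * self.aoi_half_width:
                    raise ConfigError(
                        f"AOI centers {i} and {j} overlap: separation {d:.3f} "
                        f"<= 2 x half-width {2 * self.aoi_half_width:.3f}"
                    )

    @classmethod
    def hard(cls, **overrides) -> "SimConfig":
        """Half the default angular separation between AOI centers."""
        base = cls(aoi_centers=((-0.175, 0.0), (0.0, 0.0), (0.175, 0.0)), aoi_half_width=0.05)
        return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# gaze state process
# ---------------------------------------------------------------------------


def _sample_dwell(cfg: SimConfig, rng: np.random.Generator) -> float:
    lo, hi = cfg.dwell_bounds_s
    for _ in range(64):
        d = float(rng.lognormal(math.log(cfg.dwell_median_s), cfg.dwell_sigma))
        if lo <= d <= hi:
            return d
    return float(np.clip(d, lo, hi))


def _phase_at(protocol: SessionProtocol, t: float) -> str:
    for trial in protocol.trials:
        if trial.onset <= t < trial.lateral_onset:
            return "central"
        if trial.lateral_onset <= t < trial.offset:
            return "lateral"
    return "gap"


def _next_target(cfg: SimConfig, current: int, t: float, rng: np.random.Generator) -> int:
    """Sample the next dwell target; AOI.OFF for off-screen glances."""
    if rng.random() < cfg.off_screen_prob:
        return int(AOI.OFF)
    weights = np.full(3, (1.0 - cfg.transition_stay) / 2.0)
    if 0 <= current <= 2:
        weights[:] = (1.0 - cfg.transition_stay) / 2.0
        weights[current] = cfg.transition_stay
    else:  # coming back from off-screen: uniform
        weights[:] = 1.0 / 3.0
    phase = _phase_at(cfg.protocol, t)
    if phase == "central":
        weights[int(AOI.CENTER)] *= 4.0
    elif phase == "lateral":
        weights[int(AOI.LEFT)] *= 2.0
        weights[int(AOI.RIGHT)] *= 2.0
    weights /= weights.sum()
    return int(rng.choice(3, p=weights))


def _gaze_segments(cfg: SimConfig, rng: np.random.Generator, total: float):
    """Continuous-time gaze state: list of (start, end, aoi, angle_offset).

    During calibration the state snaps to each getter's location after a
    sampled saccade latency and holds it until the next snap; elsewhere the
    dwell/transition process runs freely.
    """
    hw = cfg.aoi_half_width
    segments: list[tuple[float, float, int, np.ndarray]] = []

    def offset_for(aoi: int) -> np.ndarray:
        if aoi == int(AOI.OFF):
            # off-screen: well outside every AOI (looking down past the screen)
            return np.array([rng.uniform(-0.2, 0.2), -0.6 + rng.uniform(-0.1, 0.1)])
        return rng.uniform(-0.8 * hw, 0.8 * hw, size=2)

    snaps = []
    for g in cfg.protocol.calibration:
        lat = rng.uniform(*cfg.getter_latency_ms) / 1000.0
        snaps.append((g.onset + lat, int(g.location), g.offset))

    t = 0.0
    current = int(AOI.CENTER)
    i = 0  # next snap
    while t < total:
        if i < len(snaps) and t >= snaps[i][0] - 1e-12:
            snap_t, loc, g_off = snaps[i]
            end = snaps[i + 1][0] if i + 1 < len(snaps) else g_off
            end = min(end, total)
            off = rng.normal(0.0, cfg.getter_fixation_scatter * hw, size=2)
            segments.append((t, end, loc, off))
            current = loc
            t = end
            i += 1
            continue
        dwell = _sample_dwell(cfg, rng)
        end = t + dwell
        if i < len(snaps):
            end = min(end, snaps[i][0])
        end = min(end, total)
        target = _next_target(cfg, current, t, rng)
        segments.append((t, end, target, offset_for(target)))
        current = target
        t = end
    return segments


def _segments_to_looks(segments, total: float) -> list[Look]:
    looks: list[Look] = []
    for start, end, aoi, _ in segments:
        if aoi > int(AOI.RIGHT) or end <= start:
            continue
        if looks and looks[-1].aoi == AOI(aoi) and abs(looks[-1].offset - start) < 1e-9:
            looks[-1] = Look(AOI(aoi), looks[-1].onset, min(end, total))
        else:
            looks.append(Look(AOI(aoi), start, min(end, total)))
    return looks


# ---------------------------------------------------------------------------
# frame feature synthesis
# ---------------------------------------------------------------------------


def _angles_to_vec(yaw: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Unit gaze direction; camera convention with -z toward the camera."""
    return np.stack(
        [np.sin(yaw) * np.cos(pitch), np.sin(pitch), -np.cos(yaw) * np.cos(pitch)],
        axis=1,
    )


def _face_template(rng: np.random.Generator, n: int, spread: float, center: np.ndarray):
    return center + rng.uniform(-spread, spread, size=(n, center.size))


def simulate_session(
    cfg: SimConfig | None = None, seed: int = 0
) -> tuple[SessionTable, AOILabelSeries, list[Look], SessionProtocol]:
    """Generate one synthetic session.

    Returns the OpenFace-schema frame table, the ground-truth per-frame label
    series (source ``truth``), the ground-truth look sequence, and the
    protocol used.  Identical (cfg, seed) reproduce the session exactly.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    protocol = cfg.protocol
    total = protocol.total_duration
    n = int(round(cfg.fps * total))
    ts = np.arange(n) / cfg.fps

    segments = _gaze_segments(cfg, rng, total)
    truth_looks = _segments_to_looks(segments, total)

    starts = np.array([s[0] for s in segments])
    seg_idx = np.clip(np.searchsorted(starts, ts, side="right") - 1, 0, len(segments) - 1)
    seg_aoi = np.array([s[2] for s in segments], dtype=np.int8)
    seg_off = np.array([s[3] for s in segments])
    centers = np.asarray(cfg.aoi_centers, dtype=float)

    truth = seg_aoi[seg_idx]
    base = np.where(
        (truth <= int(AOI.RIGHT))[:, None],
        centers[np.clip(truth, 0, 2)],
        centers[int(AOI.CENTER)],
    )
    base = base + seg_off[seg_idx]

    # occlusion episodes (Poisson starts, clipped-exponential durations)
    occluded = np.zeros(n, dtype=bool)
    n_episodes = rng.poisson(cfg.occlusion_rate_per_s * total)
    ep_starts = np.sort(rng.uniform(0.0, total, size=n_episodes))
    for t0 in ep_starts:
        dur = float(
            np.clip(rng.exponential(cfg.occlusion_mean_s), *cfg.occlusion_bounds_s)
        )
        occluded |= (ts >= t0) & (ts < t0 + dur)

    # per-frame gaze angles; occluded frames carry garbage estimates
    angle = base + rng.normal(0.0, cfg.gaze_noise_sd, size=(n, 2))
    angle[occluded] += rng.normal(0.0, 0.5, size=(int(occluded.sum()), 2))

    vergence = 0.02
    eye_noise = 0.01
    yaw_l = angle[:, 0] + vergence + rng.normal(0, eye_noise, n)
    yaw_r = angle[:, 0] - vergence + rng.normal(0, eye_noise, n)
    pit_l = angle[:, 1] + rng.normal(0, eye_noise, n)
    pit_r = angle[:, 1] + rng.normal(0, eye_noise, n)
    v_l = _angles_to_vec(yaw_l, pit_l)
    v_r = _angles_to_vec(yaw_r, pit_r)
    v_avg = 0.5 * (v_l + v_r)
    v_avg /= np.maximum(np.linalg.norm(v_avg, axis=1, keepdims=True), 1e-12)
    gaze_angle_x = np.arctan2(v_avg[:, 0], -v_avg[:, 2])
    gaze_angle_y = np.arcsin(np.clip(v_avg[:, 1], -1.0, 1.0))

    feats: dict[str, np.ndarray] = {}
    for j, a in enumerate("xyz"):
        feats[f"gaze_0_{a}"] = v_l[:, j]
        feats[f"gaze_1_{a}"] = v_r[:, j]
        feats[f"gaze_avg_{a}"] = v_avg[:, j]
    feats["gaze_angle_x"] = gaze_angle_x
    feats["gaze_angle_y"] = gaze_angle_y

    # head pose: mean-reverting walks around a home position (nuisance,
    # independent of the AOI)
    def ou_walk(n_dims: int, step_sd: float) -> np.ndarray:
        theta = cfg.head_pose_reversion
        eps = rng.normal(0, step_sd, size=(n, n_dims))
        out = np.empty_like(eps)
        out[0] = eps[0]
        for i in range(1, n):
            out[i] = (1.0 - theta) * out[i - 1] + eps[i]
        return out

    home = np.array([0.0, 0.0, 600.0]) + rng.normal(0, 5.0, size=3)
    trans = home + ou_walk(3, cfg.head_translation_walk_mm)
    rot = ou_walk(3, cfg.head_rotation_walk_rad)
    for j, name in enumerate(["pose_Tx", "pose_Ty", "pose_Tz"]):
        feats[name] = trans[:, j]
    for j, name in enumerate(["pose_Rx", "pose_Ry", "pose_Rz"]):
        feats[name] = rot[:, j]

    occ_noise = np.where(occluded, 10.0, 1.0)[:, None]

    def landmark_block(
        prefixes: list[str],
        n_pts: int,
        template: np.ndarray,
        gains: list[float],
        jitter: float,
        gaze_gain: list[float] | None = None,
    ):
        # template: (n_pts, ndim); columns laid out coordinate-major.
        # gaze_gain couples a coordinate to the *estimated* gaze angle: in real
        # OpenFace output the gaze vector is computed from the eye-region
        # landmarks, so the two share per-frame estimation noise (the face
        # outline does not move with the eyeball and gets no coupling).
        for d, prefix in enumerate(prefixes):
            drive = trans[:, d % 3] * gains[d]
            vals = (
                template[None, :, d]
                + drive[:, None]
                + rng.normal(0, jitter, size=(n, n_pts)) * occ_noise
            )
            if gaze_gain is not None and gaze_gain[d] != 0.0:
                point_gain = rng.uniform(0.3, 1.0, size=n_pts) * gaze_gain[d]
                vals = vals + angle[:, d % 2, None] * point_gain[None, :]
            for k in range(n_pts):
                feats[f"{prefix}{k}"] = vals[:, k]

    # iris/eyelid points shift ~12 mm (~30 px at webcam scale) per radian of
    # eye rotation; x tracks yaw, y tracks pitch
    eye2d_t = _face_template(rng, 56, 30.0, np.array([320.0, 220.0]))
    landmark_block(["eye_lmk_x_", "eye_lmk_y_"], 56, eye2d_t, [0.4, 0.4], 0.6, gaze_gain=[30.0, -30.0])
    eye3d_t = _face_template(rng, 56, 20.0, np.array([0.0, -20.0, 600.0]))
    landmark_block(
        ["eye_lmk_X_", "eye_lmk_Y_", "eye_lmk_Z_"], 56, eye3d_t, [1.0, 1.0, 1.0], 0.6,
        gaze_gain=[12.0, -12.0, 0.0],
    )
    face2d_t = _face_template(rng, 68, 90.0, np.array([320.0, 260.0]))
    landmark_block(["x_", "y_"], 68, face2d_t, [0.4, 0.4], 0.8)
    face3d_t = _face_template(rng, 68, 60.0, np.array([0.0, 0.0, 600.0]))
    landmark_block(["X_", "Y_", "Z_"], 68, face3d_t, [1.0, 1.0, 1.0], 0.8)

    # shape parameters: rigid from pose, non-rigid AR(1) noise
    feats["p_scale"] = 1.0 + trans[:, 2] * 1e-4 + rng.normal(0, 0.002, n)
    for name, j in (("p_rx", 0), ("p_ry", 1), ("p_rz", 2)):
        feats[name] = rot[:, j] + rng.normal(0, 0.003, n)
    feats["p_tx"] = trans[:, 0] * 0.1 + rng.normal(0, 0.05, n)
    feats["p_ty"] = trans[:, 1] * 0.1 + rng.normal(0, 0.05, n)

    def ar1(n_series: int, phi: float, sd: float) -> np.ndarray:
        eps = rng.normal(0, sd, size=(n, n_series))
        out = np.empty_like(eps)
        out[0] = eps[0]
        for i in range(1, n):
            out[i] = phi * out[i - 1] + eps[i]
        return out

    nonrigid = ar1(34, 0.85, 0.05)
    for k in range(34):
        feats[f"p_{k}"] = nonrigid[:, k]

    au_cols = column_groups("action_units")
    intens_cols = [c for c in au_cols if c.endswith("_r")]
    pres_cols = [c for c in au_cols if c.endswith("_c")]
    au = np.clip(np.abs(ar1(len(intens_cols), 0.8, 0.4)), 0.0, 5.0)
    for k, c in enumerate(intens_cols):
        feats[c] = au[:, k]
    pres = ar1(len(pres_cols), 0.8, 0.5)
    for k, c in enumerate(pres_cols):
        feats[c] = (pres[:, k] > 0.5).astype(float)

    confidence = rng.beta(*cfg.confidence_beta, size=n)
    confidence[occluded] = rng.uniform(*cfg.occluded_confidence, size=int(occluded.sum()))
    success = (~occluded).astype(int)

    table = session_from_arrays(
        timestamps=ts,
        confidence=confidence,
        success=success,
        features=feats,
        participant_id=f"sim-{seed}",
        fps=cfg.fps,
        setting="remote",
        metadata={"generator": "openlook.simulate", "seed": str(seed)},
    )
    truth_labels = AOILabelSeries(truth, source="truth")
    return table, truth_labels, truth_looks, protocol


def simulate_coder(
    truth: AOILabelSeries,
    error_rate: float = 0.05,
    boundary_jitter_frames: int = 1,
    seed: int = 0,
) -> AOILabelSeries:
    """Imperfect live coder: jittered look boundaries plus random mislabels.

    Each boundary between label runs shifts by a uniform integer in
    [-jitter, +jitter] frames, then every on-screen frame is independently
    relabeled to one of the two other AOIs with probability ``error_rate``.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ConfigError("error_rate must lie in [0, 1)")
    if boundary_jitter_frames < 0:
        raise ConfigError("boundary_jitter_frames must be nonnegative")
    rng = np.random.default_rng(seed)
    codes = truth.codes.copy()
    n = codes.size

    if boundary_jitter_frames > 0 and n:
        change = np.flatnonzero(np.diff(codes)) + 1
        run_codes = codes[np.concatenate(([0], change))]
        new_bounds = []
        prev = 0
        for b in change:
            nb = int(np.clip(b + rng.integers(-boundary_jitter_frames, boundary_jitter_frames + 1), prev, n))
            new_bounds.append(nb)
            prev = nb
        edges = [0, *new_bounds, n]
        out = np.empty(n, dtype=np.int8)
        for code, a, b in zip(run_codes, edges, edges[1:]):
            out[a:b] = code
        codes = out

    if error_rate > 0 and n:
        on = codes <= AOI.RIGHT
        flip = on & (rng.random(n) < error_rate)
        idx = np.flatnonzero(flip)
        # pick one of the other two AOIs uniformly
        shift = rng.integers(1, 3, size=idx.size)
        codes[idx] = ((codes[idx] + shift) % 3).astype(np.int8)
    return AOILabelSeries(codes, source="coder")


def emit_session(
    cfg: SimConfig, seed: int, out_dir, prefix: str = "session"
) -> dict[str, str]:
    """Write a session bundle: OpenFace CSV, truth labels/looks, protocol, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth, looks, protocol = simulate_session(cfg, seed)
    paths = {
        "openface_csv": write_openface_csv(table, out / f"{prefix}_openface.csv"),
        "truth_labels": truth.write_csv(out / f"{prefix}_truth_labels.csv", table),
        "truth_looks": write_looks_csv(looks, out / f"{prefix}_truth_looks.csv", table.participant_id),
    }
    from .protocol import protocol_to_dict

    proto_doc = protocol_to_dict(protocol)
    ppath = out / f"{prefix}_protocol.json"
    ppath.write_text(json.dumps(proto_doc, indent=1))
    paths["protocol"] = str(ppath)
    manifest = {
        "seed": seed,
        "fps": cfg.fps,
        "aoi_centers": [list(c) for c in cfg.aoi_centers],
        "aoi_half_width": cfg.aoi_half_width,
        "gaze_noise_sd": cfg.gaze_noise_sd,
        "n_frames": table.n_frames,
    }
    mpath = out / f"{prefix}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    paths["manifest"] = str(mpath)
    return paths
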