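# openlook

Automated looking-time coding for gaze video collected outside the lab.

Developmental researchers measure infant and child attention by coding where
a participant looks on a screen — traditionally by trained observers pressing
buttons in real time, or frame-by-frame from video. Neither scales to remote
testing, where a child watches stimuli on a home computer and the only record
is a webcam video. Tools like OpenFace recover rich per-frame descriptions of
the face from such video — eye-gaze direction vectors, gaze angles, 2D/3D
eye-region and face landmarks, head pose, shape parameters, facial action
units, and a confidence rating — but in camera coordinates, with **no external
frame of reference**: the output alone cannot say which screen region the
child is looking at.

`openlook` closes that gap. A small artificial neural network is trained *per
participant* to map each frame's OpenFace features to one of three screen
areas of interest (AOIs): **left**, **center**, **right**. Training labels
come either from a live coder's look log (in-lab sessions) or from
attention-getter calibration stimuli presented at known screen locations
(remote sessions). Predicted frame labels are then segmented into looks and
summarised as trial-level attention measures for a three-screen audiovisual
protocol (the MAAP: 24 trials, each a 3-s central event followed by two 12-s
lateral events, one synchronised with the soundtrack).

## The model

Each frame contributes a feature vector **x** ∈ ℝ⁷¹² (six OpenFace feature
families: gaze, eye landmarks 2D/3D, head pose, face landmarks 2D/3D, shape
parameters, action units). The classifier is a four-layer fully connected
network (three hidden layers of 64 units):

    h_k = Dropout₀.₂( ReLU( BatchNorm( W_k h_{k−1} + b_k ) ) ),  k = 1..3
    p   = softmax( W₄ h₃ + b₄ ) ∈ Δ²  over {LEFT, CENTER, RIGHT}

trained with cross-entropy and Adam on a random 50% of the labeled frames;
the held-out 50% measures frame-wise percent agreement

    agreement = 100 × (# frames where prediction = reference) / (# compared frames).

With no training, agreement against balanced reference labels sits at the
three-class chance level (33%). Frames where OpenFace loses the face
(success = 0 or confidence below threshold) are classed OFF, never forced
into an AOI.

## Worked example

No data are bundled; the `simulate` module generates complete sessions in the
OpenFace output schema (gaze-angle AOI clusters, dwell/transition looking,
attention-getter calibration with saccade latency, occlusion episodes with
low confidence, nuisance landmark/pose/action-unit channels) together with
ground-truth labels. The end-to-end pipeline — simulate → quality control →
calibration labeling → 50/50 split → train → predict → segment → score:

```python
from openlook.pipeline import run_pipeline
report = run_pipeline(seed=1)
```

produces (abridged):

```json
{
 "n_frames": 11880,
 "n_labeled_calibration_frames": 266,
 "n_train_frames": 133,
 "confidence_mean_pct": 89.2,
 "heldout_overall_pct": 95.52,
 "heldout_per_aoi": {"LEFT": 91.5, "CENTER": 96.9, "RIGHT": 97.9},
 "n_looks": 489,
 "maap_means": {"looking_duration_prop": 0.935,
                "shift_latency_s": 1.001,
                "matching_prop": 0.487}
}
```

Reading: an 11,880-frame session (8 calibration getters + 24 trials at
30 fps) yielded 266 usable calibration-labeled frames; a network trained on
half of them agreed with the simulator's ground truth on **95.5%** of usable
held-out frames, with per-AOI agreement 91–98%. Segmentation found 489 looks;
the child-process looked at the screen 93.5% of trial time, first shifted to
a lateral event about 1.0 s after lateral onset, and split lateral looking
roughly evenly between the sound-synchronised and silent sides (the simulated
gaze process has no audiovisual-matching preference, so ≈ 0.5 is expected).

The same pipeline is available from a shell:

```bash
openlook pipeline --seed 1 --out-dir out/
openlook simulate --seed 5 --out-dir sim/          # emit an OpenFace-schema bundle
openlook agree --pred pred.csv --ref truth.csv --out-dir agr/
```

Every command writes a `manifest.json` (effective config + seed + version)
from which its outputs can be regenerated bit-identically.

## Package layout

| module | role |
|---|---|
| `openface_io` | OpenFace output-CSV dialect: schema, column groups, read/write |
| `quality` | confidence summaries, frame usability, inclusion rules, connection check |
| `protocol` | MAAP timeline, attention getters, coder-log / calibration labeling |
| `features` | feature-matrix assembly and leak-free standardization |
| `classifier` | the per-participant network: split, build, train, predict, persist |
| `looktime` | look segmentation and MAAP attention metrics |
| `agreement` | frame-wise percent agreement, confusion, absolute-difference reliability |
| `simulate` | synthetic sessions with ground truth; imperfect-coder simulation |
| `cli` / `pipeline` | command-line interface and end-to-end composition |

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
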