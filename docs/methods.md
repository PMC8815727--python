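# Methods

This note documents the models, conventions, parameter defaults and known
limitations behind `openlook`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

OpenFace-style video post-processing yields, per frame: a tracking success
flag, a confidence rating in [0, 1], unit eye-gaze direction vectors for each
eye, gaze yaw/pitch angles, 56 eye-region landmarks (2D px, 3D mm), head
translation (mm) and rotation (rad), 68 face landmarks (2D, 3D), 6 rigid +
34 non-rigid shape parameters, and 17 action-unit intensities + 18 presence
flags — 712 feature columns in the grouping this package uses (the derived
average-of-both-eyes vector adds 3 columns to the native gaze family). All of
it is expressed relative to the camera; nothing maps to screen coordinates.
The package's job is to learn that mapping per participant and turn frame
labels into standard looking-time measures.

Conventions: frames are 0-based internally (the on-disk CSV dialect is
1-based, as OpenFace writes it); timestamps are seconds; all intervals are
half-open `[onset, offset)`; when a file does not determine the frame rate it
is estimated from the median timestamp increment, falling back to 30 fps.

## The classifier

Architecture: input → 3 × [linear(64) → 1-D batch normalization → ReLU →
dropout p = 0.2] → linear(n_classes) → softmax. Four fully connected layers,
three hidden. The relative order linear→BN→activation→dropout is a
documented choice (only "each layer is followed by" normalization and
dropout is fixed by the architecture description; the order w.r.t. the
activation is the common modern one). `n_classes` defaults to 3 and is
configurable to support future protocols with more AOIs.

Training (`TrainConfig`): cross-entropy loss, Adam (lr 1e-3), batch size 64,
up to 200 epochs, early stopping with patience 20 on a 10% validation slice
carved out of the *training* rows, L2 weight decay 1e-4 on the weight
matrices. The labeled frames are split 50/50 into train/test uniformly at
random (no stratification); `round(fraction·n)` rows train. Feature
standardization (per-column z-score, zero-variance guard) is fitted on
training rows only. None of these optimisation hyperparameters is constrained
by the architecture; they were chosen for robustness at desk scale and are
all configurable and recorded in the model artifact.

**Ensembling.** By default `n_ensemble = 3` networks are trained with
independent seeded initializations and batch orders, and predicted
probabilities are averaged. With calibration-sized training sets (~130
frames) a single network's held-out agreement varies by a few points with
initialization; averaging is the standard variance reduction. Set
`n_ensemble = 1` for a single net; every member is the same four-layer
architecture.

Prediction: usable frames (success = 1 and confidence ≥ threshold) receive
the argmax class, with exact probability ties broken CENTER > LEFT > RIGHT;
unusable frames are labeled OFF. All randomness (split, init, validation
slice, batching, dropout) flows from explicit seeds; identical seeds give
identical weights and predictions, and training provably never touches the
held-out rows (removing them reproduces the weights exactly — this is
asserted in the tests).

The network is implemented directly in NumPy (forward, backward, Adam) so
that determinism is complete and the artifact has no deep-learning
dependency; scikit-learn's MLP serves as an independent cross-check on
separable data in the test suite, never as the implementation.

## Quality control

The confidence summary reports mean and *population*-SD confidence on the
percent scale plus the proportion of frames per quartile bin [0,25), [25,50),
[50,75), [75,100] — a confidence of exactly 75% counts in the top bin. Frame
usability is `success ∧ confidence ≥ min_confidence` with a default threshold
of 0.75, aligned with the top bin; there is no a-priori standard for this
cut, so it is a configurable post-hoc choice. "Face fully visible" is
operationalised through the same rule: a participant is excluded when the
usable-frame fraction inside the calibration windows falls below 0.5
(configurable), or when any block has fewer than 5 of its 6 trials valid.
The pre-session connection check passes only for download > 50 mbps *and*
ping < 25 ms, both strict.

## Protocol and labeling

The default MAAP timeline: 8 attention getters (center, left, center, right,
sequence repeated once; 1,500 ms each, back to back), then 24 trials of 3 s
central + 12 s lateral event phases, in alternating blocks of six
social/nonsocial trials with the sound-synchronised side counterbalanced
within block (3 left / 3 right, starting side alternating across blocks).
The 1-s inter-trial gap and the counterbalancing scheme are package defaults
(not fixed by the protocol description) and configurable.

Calibration labeling assigns each frame inside a getter window the getter's
location, skipping the first 300 ms of every window: participants are not
instructed to fixate, so early frames may precede the saccade to the new
stimulus. The trim and window schedule are configurable. When a quality
config is supplied, unusable frames stay UNLABELED; pass `cfg=None` to get
pure window-membership labels (used by the inclusion rule's denominator).

Coder-log labeling maps each frame whose timestamp falls in a look's
`[onset, offset)` to that look's AOI. Looks carry only on-screen AOIs;
off-screen behaviour exists only as OFF in label series.

## Look segmentation and MAAP metrics

Frame labels become looks by run-length segmentation: OFF/UNLABELED gaps of
≤ 1 frame flanked by the same AOI are bridged, then maximal same-AOI runs
lasting ≥ 100 ms become looks (both parameters configurable; with min-look
one frame and no bridging, labels→looks→labels is the identity on OFF-free
series). Frame *i* covers `[i/fps, (i+1)/fps)`.

The three multisensory-attention-skill measures are **operational stand-ins
defined by this package** (the protocol's published definitions live in its
own literature and are not reproduced here); outputs carry a metadata note
saying so:

* *duration of looking*: time on any on-screen AOI within the trial ÷ trial
  length (looks clipped to the trial window);
* *shift latency*: lateral-phase onset to the onset of the first look at a
  lateral AOI (clipped to 0 when a lateral look already spans the onset;
  missing when no lateral look occurs);
* *matching*: sync-side looking ÷ total lateral looking within the lateral
  phase, defined only when total lateral looking ≥ 0.5 s.

Session means skip missing trials and missing counts are reported.

## Agreement and reliability

Percent agreement excludes frames the *reference* leaves UNLABELED (and OFF,
unless OFF is compared as a fourth class) and is the plain frame-weighted
proportion; per-AOI agreement conditions on the reference label, and the
unweighted mean across AOIs is reported alongside because the two differ
whenever looking is unevenly distributed (the weighted overall is what a
"frames agreed ÷ total frames" computation yields). The implementation is
checked exhaustively against a brute-force counting oracle over all pairs of
4-frame series.

Inter-observer reliability uses absolute differences between two coders'
paired measure estimates — per-pair |a−b|, the median, and the median scaled
by the caller-supplied range of possible scores (e.g. 15 s for a per-trial
looking-time measure). Chance-corrected coefficients (κ) are out of scope.

## The simulator

The generator defines AOIs **in gaze-angle space**, not pixels: LEFT/CENTER/
RIGHT centers at yaw −0.35/0/+0.35 rad (pitch 0), half-width 0.10 rad. The
child's gaze is a dwell process: truncated-lognormal dwell durations (median
1.5 s, σ = 0.6, bounds [0.2, 8] s), a transition matrix with re-fixation
probability 0.1 and phase-dependent bias (central phase favours CENTER ×4,
lateral phase favours the sides ×2), and a 5% per-dwell off-screen
probability. Each on-screen dwell fixates a point drawn uniformly within
±0.8 half-widths of the AOI center; the observed gaze angle adds N(0, 0.05²)
rad per-frame estimation noise (adjacent centers are therefore 7 noise-SDs
apart: learnable, not trivial; `SimConfig.hard()` halves the separation).
During calibration the state snaps to each getter's location after a uniform
150–400 ms saccade latency, with a tighter fixation scatter (SD 0.25
half-widths — a getter is a single salient point, not a region).

Feature synthesis mirrors how OpenFace derives its outputs: per-eye gaze
vectors are the noisy angle ± a 0.02 rad vergence offset; the eye-region
landmarks shift with the *estimated* gaze angle (seeded per-point gains,
~30 px or ~12 mm per radian) because in real output the gaze vector is
computed from those landmarks — they share estimation noise and add no
independent signal. Head pose is a mean-reverting (OU) walk around a home
position (step SD 0.5 mm / 0.002 rad per frame, reversion 0.2 per frame —
sub-second fidgeting of a seated child); face landmarks, shape parameters
and action units are low-signal correlates of head pose (AR(1) processes,
φ = 0.8–0.85) and carry **no** AOI information, so a classifier must earn
its agreement from the gaze family. Nuisance correlation times are kept
below the 1.5-s getter window on purpose: the calibration phase is
time-blocked, and any nuisance process that is near-constant within a window
separates the classes in-sample while carrying zero signal later — a
confound no within-participant learner can overcome, which a generator
intending learnable sessions must therefore not build in.

Occlusions are a Poisson process (0.02 episodes/s, exponential duration mean
1 s clipped to [0.2, 3] s); occluded frames get success = 0, confidence
~ U[0, 0.3], and garbage gaze/landmark estimates. Clean-frame confidence is
Beta(18, 2) (mean ≈ 0.9). Truth labels record the underlying state (the
child keeps looking somewhere while occluded).

The simulated coder jitters every look boundary by ±1 frame and mislabels
each on-screen frame with probability `error_rate` to one of the other two
AOIs.

**What the simulator does not emulate:** real OpenFace estimation biases
(systematic, participant-specific distortions rather than i.i.d. noise),
head-pose-dependent gaze error, smooth pursuit within events, audiovisual
matching preferences (lateral looking is side-symmetric by construction, so
simulated matching proportions center on 0.5), and any correlation between
head orientation and gaze target. Passing tests therefore show the pipeline
recovers *this* generative family, not that any particular real dataset
would reach the same agreement.

## Problem sizes and determinism

The default simulated session is 396 s at 30 fps = 11,880 frames; calibration
yields ~260 usable labeled frames, ~130 of which train the network. The
chance-level baseline averages 20 seeded sessions (~238k frames). The
end-to-end benchmark evaluates agreement against simulator truth on usable
held-out frames (training frames excluded) and repeats across a
gaze-noise ladder (SD 0.05/0.15/0.30 rad) to confirm monotone degradation.
Every pipeline product can be regenerated bit-identically from its manifest
(config + seed + version); all substream seeds derive from the single global
seed by fixed offsets.

## Known limitations

* One model per participant; no cross-participant transfer (a pooled mode is
  deliberately out of scope, as is K-fold cross-validation).
* The MASk formulas are stand-ins (flagged in outputs) pending the
  protocol's canonical definitions.
* Calibration-based training rests on the assumption that the child fixates
  the getter after a saccade latency; the 300 ms trim is a heuristic, not a
  per-child latency estimate.
* With ~130 training frames the network is far over-parameterised; weight
  decay, early stopping and ensembling manage but do not eliminate the
  variance, which is why held-out agreement on simulated sessions varies by
  a few points across seeds.
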