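# Methods

## Coordinate and angle conventions

Sessions are sequences of timestamped frames, each holding the 33 body
landmarks of the MediaPipe Holistic numbering as metric world coordinates
plus a visibility confidence in [0, 1]. Internally, frames are **y-up**: x
is lateral (+ toward the subject's right in the camera frame), y is
vertical (+ up, gravity along [0, −1, 0]), z is depth (+ away from the
camera). Pose estimators that emit image-style y-down world coordinates are
flipped at ingest (`y_axis="down"`); externalizing this as a flag avoids
guessing any particular estimator's axis orientation. Timestamps are
required per frame and must be strictly increasing; the nominal frame rate
is advisory metadata only, since achieved rates drift below nominal.

All angles are degrees and normalized so a neutral upright posture reads
≈ 0° (before the trunk correction):

- **Trunk flexion** = angle(mid-shoulders→mid-hips, gravity) + a
  configurable correction (default **+10°**), clamped to [0, 180]. The
  correction compensates for typical frontal camera tilt at a workstation.
  It is applied literally as an addition; a subtraction reading (camera
  pitched the other way) is selectable via `kinematics.trunk_correction`.
  Note the downstream trunk thresholds consume the *corrected* angle, so an
  exactly upright trunk (corrected 10.0°) still scores 1 because thresholds
  are strict lower bounds.
- **Neck flexion** = 180° − angle(neck, trunk): the mid-shoulder→mid-ear
  and trunk vectors are antiparallel when upright, so this reads 0° neutral
  and the >10°/>30° penalty thresholds apply directly.
- **Arm flexion** = angle(shoulder→elbow, shoulder→ipsilateral-hip); a
  hanging arm reads ≈ 0 regardless of trunk posture.
- **Forearm angle** = the included elbow angle, 180° − angle(upper arm,
  forearm), so a right-angle elbow reads 90° and the 50–110° neutral zone
  applies literally. (Of the two supplementary angles this is the
  anatomically standard one.)
- **Arm abduction** = the frontal-plane (x–y) projected angle between upper
  arm and its reference. See "Known limitations" for its conditioning.
- **Lateral tilt** = |frontal-plane inclination of the shoulder line −
  inclination of the hip line|, an asymmetry indicator.

Angle computation clamps the cosine to [−1, 1] before arccos; vectors with
norm ≤ 1e−9 m are degenerate and flagged invalid (as are all angles that
depend on a landmark whose visibility fell below the 0.5 gate).

The **active side** is the shoulder nearer the camera (smaller z), ties to
the right, holding the previous side when a shoulder is occluded: in a
sagittal working view the task arm is nearest the camera and carries the
highest risk profile.

## Smoothing

First-order exponential smoothing, L̂ₜ = α·Lₜ + (1−α)·L̂ₜ₋₁, is applied to
the derived **angle channels** (trunk, neck, tilt at α = 0.8; per-side arm
flexion, abduction and forearm at α = 0.7). The first sample seeds the
filter unchanged (no zero-initialization bias). Step-response latency to a
settle fraction *f* is the smallest n with 1 − (1−α)ⁿ ≥ *f*; the exposed
default *f* = 0.99 gives 3 frames (100 ms at 30 FPS) for α = 0.8 and 4 for
α = 0.7. On white noise the stationary output variance is σ²·α/(2−α).

A coordinate-level mode (`stabilizer.mode = coordinates`) smooths raw
landmark positions with a single α before any angle is computed; it exists
because smoothing can equivalently be framed at either stage, but the
angle-channel mode is the default since the per-segment update is the most
explicit statement of the pipeline. Channels invalidated by the visibility
gate do **not** update the filter: the last smoothed value is held, flagged
stale, and excluded from scoring — so a frame is unscorable exactly when
the gating rule invalidates a required landmark. The extra
`abduction_left/right` channels (not strictly part of the seven classic
segment channels) default to the arm α so every scored stream is smoothed
uniformly.

## RULA scoring

Per-segment threshold bands, with every breakpoint a strict lower bound
(">30°" leaves 30.0° in the lower band):

| segment | bands (default) | adjustment |
|---|---|---|
| upper arm | ≤30→1, (30,45]→2, (45,90]→3, >90→4 | +1 if abduction > 45°, cap 6 |
| forearm | 1 inside [50°, 110°], else 2 | — |
| trunk | ≤10→1, (10,20]→2, (20,60]→3, >60→4 | +1 if lateral tilt > 10°, cap 6 |
| neck | ≤10→1, (10,30]→2, >30→3 | — |

The interior 45° upper-arm breakpoint follows the original RULA convention
(only the >30° and >90° anchors are fixed by the tolerant-threshold design);
the forearm zone uses 50–110° (the dedicated scoring definition) rather than
the alternative 60–110° phrasing — both are config-exposed. Wrist,
wrist-twist and leg scores default to 1 because markerless vision cannot
resolve them reliably; muscle-use and force/load additions exist in config
but default to 0. The abduction (+1 above 45°) and tilt (+1 above 10°)
adjustments are on by default with config off-switches, since the underlying
asymmetry indicators are measured but no canonical thresholds exist for
them in a markerless setting.

Sub-scores index the published Table A (upper limb), Table B
(neck/trunk/legs) and Table C (grand score) matrices, transcribed once into
`src/rulakit/data/rula_tables.json` and frozen by a sha256 checksum; a test
and the `tables-check` CLI verify the checksum, entry ranges and
monotonicity in every index. Adjusted scores beyond Table C's last
row/column clamp to it (the "8+" convention). Final scores map to action
levels 1–2 acceptable, 3–4 investigate, 5–6 changes soon, 7 urgent.

## Alerts

An alert fires when the final score reaches the threshold (default 5) and
strictly more than the refractory period (default 2.0 s) has elapsed since
the previous alert; scores of 7 escalate the tone parameter from 1000 Hz to
2500 Hz (200 ms duration). Alerts are data (events CSV); audio playback is
deliberately out of scope. Unscorable frames neither trigger nor reset the
refractory clock. Under sustained critical input at 30 FPS the rule yields
an alert at onset and then one per first frame beyond each refractory
window (e.g. five alerts in a 10 s run). A `sustain_s` config stub is
reserved for sustained-duration triggering variants and is inert at its 0
default.

## Session and cohort analytics

Frame durations are the gap to the next timestamp; the last frame uses the
median gap. Time-in-critical sums durations of scorable frames with score
≥ 5. The **risk↔alert correlation** is the Pearson r between the binary
per-frame risk indicator (score ≥ threshold) and an alert-coverage
indicator (timestamp within [event, event + refractory) of any event); no
canonical construction exists for this quantity, so this
indicator-with-coverage-window definition is the package's own and is
undefined (reported as null) when either indicator is constant.
False-alarm rate = fraction of events triggered below threshold; missed
rate = fraction of critical runs longer than the refractory period that
contain no event. A segment "contributed to risk" when its sub-score
reached the penalized range (≥ 2, per-segment configurable) during at least
one critical frame. The static baseline score is the maximum over the
leading `baseline_s` window (default first 3 s, half-open).

**McNemar's exact test** on the paired static/dynamic risk table uses the
two-sided binomial closed form p = min(1, 2·P(X ≤ min(n₁₀, n₀₁))) with
X ~ Binomial(n₁₀+n₀₁, ½); the asymptotic continuity-corrected χ² variant is
available behind a flag (via statsmodels, which also serves as an
independent cross-check in the tests). **Cohen's h** =
|2·arcsin√p₁ − 2·arcsin√p₂|. For the reference proportions 25/40 vs 3/40
this evaluates to ≈ 1.269 (a very large effect); the implementation always
reports the formula value.

## Synthetic lifting sessions

The generator emulates a 60 s frontal-view load-lifting trial at 30 FPS
with four phases — initiation (5 s), loaded peak (30 s), sustained
elevation (15 s), recovery (10 s) — using raised-cosine ramps between
plateaus (any C¹ ramp would do; raised cosine has bounded derivatives). An
articulated chain (hips fixed; trunk pitched forward by the instantaneous
trunk angle; shoulders, ears, arms and filler landmarks attached with
anthropometric segment lengths: trunk 0.5 m, upper arm 0.3 m, forearm
0.27 m, neck 0.18 m, shoulder width 0.4 m, hip width 0.3 m, consistent with
an average adult stature) produces the 33-landmark frames. Gaussian
isotropic jitter (default 5 mm, roughly the few-pixel pre-filter jitter of
markerless estimators at a ~2 m working distance; no exact pixel↔metre
mapping is claimed) and per-landmark visibility dropouts emulate estimator
noise and occlusion. Default peak angles (trunk 48°, arm 87°, neck 44°,
abduction 30°, tilt 5°) reflect observed task means; presets `neutral`,
`moderate_lift` and `severe_lift` span the risk range, and the default
cohort sampler draws per-participant peaks around the task means.

Ground truth: trunk, neck, tilt and elbow angles are exact by construction;
arm flexion and abduction under combined flexion+abduction rotations are
evaluated from the generator's own direction vectors with self-contained
vector algebra, independent of the landmark-parsing/kinematics path under
test. Expected sub-scores and final scores are derived from the true angles
under the configured thresholds. With zero noise the full
landmark→vector→angle path recovers ground truth to < 1e−6°; with default
noise and smoothing, plateau RMS error stays below 2° on every scored
channel.

What the generator does **not** emulate: inverse dynamics or load forces,
estimator-correlated (non-isotropic, non-white) noise, soft-tissue and
clothing artefacts, multi-person scenes, camera motion. Passing tests
therefore demonstrate the correctness of the computation given
schema-conformant landmarks, not pose-estimation accuracy on real video.

## Numerical choices and degenerate inputs

Cosines clamped to [−1, 1]; degeneracy floor 1e−9 m on vector norms;
degenerate geometry yields invalid flags (never exceptions) inside the
per-frame path. Threshold comparisons are strict; active-side ties go
right. Sessions with zero scorable frames produce summaries with explicit
missing markers. Reports are serialized with sorted keys so identical
inputs yield byte-identical files.

Problem sizes used by the shipped tests: full-length (60 s, 1800-frame)
sessions where plateau statistics matter, shortened phase structures
(1/2/1/1 s) where only the phase shape matters, 10⁴ trials for the
angle-rotation oracle, 200 random streams for the alert invariants, and the
complete sub-score index domain (6·3·4·2·6·6·2 cells) for table
monotonicity.

## Known limitations

- **Projected abduction conditioning.** The frontal-plane projection of a
  strongly forward-flexed arm shortens, amplifying landmark noise in the
  projected angle; its noise floor is geometry-dependent and larger than
  that of the directly-measured 3D angles. The abduction threshold is
  deliberately coarse (45°) for this reason.
- Wrist posture, wrist twist, head rotation and neck extension are not
  estimated (defaulted scores), so true RULA risk is under-reported for
  wrist-intensive tasks.
- The +10° trunk correction is a fixed offset, not a per-setup calibration.
- Cohort statistics operate on per-participant binary risk classifications;
  no confidence interval is constructed for the risk↔alert correlation, as
  there is no canonical construction for the coverage-window definition.
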