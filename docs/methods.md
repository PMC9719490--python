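# Methods

This note documents the models, parameters and numerical choices behind
`batnav`, in the spirit of a package methods appendix. It states no result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Coordinate and angle conventions

Planar local coordinates in metres, x = east, y = north. Absolute azimuths
are degrees clockwise in [0, 360) with 0 = map north; all relative angles
(labels, errors, estimates) are signed degrees in [−180, 180). A view's
label is `wrap(gaze − bearing_to_goal(position))`: 0 iff the gaze points at
the goal, positive when the gaze is clockwise of it. One module
(`batnav.angles`) owns every wrap so the convention cannot drift.

## The synthetic nightscape

A `World` is a flat plane of Gaussian light blobs (position, peak radiance
in arbitrary units, spatial extent in metres, two correlated channel
weights), a ground-texture seed, a two-parameter sky gradient, an origin
("cave") and a goal ("target tree") at 17,200 m by default (bearing 315°).
The default layout emulates a rural commute corridor: 24 ordinary sources
(log-normal radiances, median 1.0; extents 150–900 m) scattered 1.5–10 km
to the sides of the route and in a band beyond the goal, plus one dominant
"city" with radiance 25× the median, 6.5 km off the origin–goal axis.
The off-axis city makes brightest-direction steering (the phototaxis null)
point away from the goal by construction, and serves as the stable distant
landmark for the generalisation analyses. Year-to-year drift
(`perturb_world`) independently moves, re-lights or replaces each ordinary
source with a configurable probability; the dominant city is always kept.

The renderer is a pure function of (world, position, gaze, config) and
composes three horizontal bands:

* **sky** (top third): a vertical luminance gradient with no azimuthal
  structure;
* **horizon** (middle third): each source projected by perspective — its
  pixel column is linear in the signed angle between its azimuth and the
  gaze — with angular width `max(1.2°, atan(extent/distance))`, intensity
  `radiance / (1 + (d/8000 m)²)`, clipped to [0, 1];
* **ground** (bottom third): a position-locked value-noise texture (60 m
  cells, hash-based, amplitude 0.03 over a 0.07 base) sampled along the
  projected ground intersection of each pixel ray, plus a broad glow from
  sources within 2.5 km.

Confining the source geometry to the middle band is deliberate: it makes
"which band carries the navigation signal" a designed, testable property.
The ground amplitude is kept low for the same reason — a high-contrast
ground texture acts as a positional fingerprint that competes with the
horizon geometry (and night terrain away from lights is in fact dim).
Acquisition renders at 2× resolution and downsamples bicubically
(degradation only; constant images are preserved; the operation is a no-op
at the target size). No celestial cues, weather or occluding terrain are
modelled.

## Acquisition protocol

Along a gently meandering origin→goal trajectory (waypoints every 40 m,
sinusoidal lateral offset of 300 m amplitude pinned at both ends, segment
turns ≪ 15°), views are acquired at stops every 250 m (full 360° rotation
at 5° spacing, random rotation phase) and between stops (two views every
250 m at the midpoint, gaze drawn from the mixture
`0.5 · wrapped-normal(0, 40°) about the goal bearing + 0.5 · uniform` —
the goal-facing acquisition bias). Acquisition positions zig-zag laterally
(100 m amplitude sinusoid plus 15 m jitter). The desk-scale default yields
5,178 views at 64×64×2. Every label is recomputable exactly from the
stored position and gaze; the excluded-segment split removes all samples
whose acquisition arc length falls in a contiguous window (default: 23% of
the arc starting at 40% of the route) from training and tests only samples
at least 1,050 m inside the window, asserting the realised euclidean
train–test gap ≥ 1 km.

## Network and training

Desk-scale architecture: conv blocks (8, 16, 32 filters, 3×3, each with
2×2 max pooling) on the 64×64×2 input, then fully-connected probe layers
of 256/64/32 units (ReLU), then a single scalar squashed to [−180, 180] by
`180·tanh(z/180)` — near-identity in degrees over the useful range. A
full-scale preset (160×160, fc 4096/1024/256) exists but is not exercised
by the tests. The loss per batch is
`Σ angdiff² / (2·32) + 10⁻⁴·Σw²` with the divisor fixed at the nominal
batch normaliser 64 regardless of the actual batch size (a
`fixed_loss_divisor` flag switches to `2B`); the regularisation term is
added once per batch. Gradients flow through the wrapped difference, which
equals the min-form angdiff and is differentiable except exactly at the
antipode.

Training is seeded minibatch SGD: lr 0.01, batch 32, momentum 0.9,
global-norm gradient clipping at 5, lr halved at epochs 6/10/13 of 16,
Gaussian input noise (sd 0.01 in pixel units) on training images, and a
Polyak average of the weights over the last 3 epochs. The clipping,
schedule, input noise and tail averaging are stability choices: the raw
loss scale (squared degrees) makes plain SGD runs erratic — occasionally
sticking in poor basins or, for the excluded-segment model, saturating the
tanh head on out-of-distribution gap views (predictions pinned at ±180°).
The input noise in particular removed every saturation event we observed
while leaving the full-route fit intact; 0.02 was over-regularising.
RMSProp-style per-parameter scaling was tried and rejected: at the fixed
lr 0.01 it barely trains, and retuning the learning rate would abandon a
reference value. A gaze-shift augmentation (horizontal pixel shift with
exactly shifted labels — pixel-exact against the renderer) degraded gap
generalisation badly, most plausibly through its edge-replication
artifacts, and was removed.

All randomness is explicit: builds, shuffles, noise and simulations take
seeds; stage seeds derive from one global seed by `crc32(seed:stage)`.
Identical seeds give bit-identical runs single-threaded.

## Evaluations

* **Sector error**: mean ± SD of `angdiff(prediction, label)` over test
  views with |label| ≤ 45° (the goal sector). Full-route test views are
  freshly rendered at jittered positions (lateral sd 50 m) and gazes
  (uniform ±60° about the bearing), so no test pixel equals a training
  pixel; the excluded-segment condition instead tests the held-out gap
  samples.
* **Polar profile**: per-30°-label-bin mean |error| and counts.
* **Stripe experiment**: three retrainings with the top/middle/bottom
  image third zeroed in both training and test images (heights not
  divisible by 3 are truncated at the bottom first). Run at a reduced
  scale (2.5 km world, 48×48, ~2,500 views, 14 epochs) to keep three
  trainings cheap.
* **Green sectors**: at off-route probe points (default 9 points, 2–5 km
  from the route, full 360° gaze coverage), the maximal contiguous gaze
  intervals where |error| < 15°, and their mean total width across probes.
  The analysis runs this on a drifted world (20% of sources modified) to
  probe generalisation in space and time together.

## Closed-loop simulator

Start: position uniform over the first 2.5 km of the route arc, heading =
goal bearing + U[−30°, 30°]. Loop: estimate the relative goal azimuth from
the current state, turn by the full estimate, advance 350 m. "Flying
around the target" is operationalised as capture-then-orbit: success when
the agent comes within 350 m of the goal and the next 5 positions stay
within 1,050 m; a broken orbit lets the agent re-capture within the
100-step budget. `SimResult.reached` separately records whether the 350 m
radius was ever crossed.

Estimators: (1) noisy oracles — truth plus wrapped-normal noise, with the
half-normal calibration sd = m·√(π/2) mapping a target mean |error| m to
its noise sd (22.2° → 27.8°, 25.4° → 31.8°); (2) the trained network,
either rendering the exact current view through the acquisition pipeline
or looking up the nearest stored view (metric: position distance + 10 m/°
× gaze difference; ties to the lowest index) and correcting the prediction
by the gaze mismatch; (3) the phototaxis null steering at the brightest
horizon-band column. A known limitation, visible in analysis 06: the
trained network reliably brings the agent inside the 350 m radius, but the
orbiting phase needs views with return headings near the goal, which the
route dataset does not contain — past the goal the nearest stored views
still say "straight on". The headline success-rate condition therefore
uses the calibrated noisy oracles, whose errors are state-independent.

## Unit tuning analysis

For each unit of the three fc probe layers, the mean activation per 1°
bin of gaze-relative-to-goal (averaged across probe locations at equal
relative gaze) is binned to 30°, smoothed with a circular 3-bin moving
average, and min-max normalised. Directionality is tested with an
activation-weighted Rayleigh statistic: bin centres weighted by the
min-shifted activation, the standard Zar p-approximation, and the
effective sample size set to the number of raw per-gaze observations
behind the profile (360), not the bin count — 12 pseudo-observations make
the test so weak that even ideal two-peaked profiles fail it. Because a
balanced antipodal profile has a near-zero first-harmonic resultant, the
gate uses the better of the first- and second-harmonic (axial) tests, the
standard treatment for axial circular data; profiles with three or more
balanced, widely-spaced peaks remain invisible to both harmonics and are
reported non-directional — an inherent property of Rayleigh gating that
the stub-recovery test battery respects by using dominated multi-peak
shapes. Peaks are detected on the circularly padded normalised profile
(minimum height 0.05, prominence 0.065, inter-peak distance 20° enforced
at sub-bin precision via parabolic peak interpolation); modality is the
surviving peak count; tuning width is the two-sided half-height width with
circular wrap and linear interpolation between bins, capped at 360° (with
a flag) when a side never crosses half height. Layer summaries report
class fractions, the 20°-bin histogram of unimodal peak azimuths, the mean
profile of units peaking in the modal bin, and the joint peak × width
table. All-constant units are non-directional by definition (no
normalisation is attempted).

## What the synthetic twin does and does not show

The generator reproduces the *structure* of the study — degraded two-band
panoramas, a biased stop-and-rotate acquisition, a contiguous spatial
hold-out, noise-calibrated closed-loop control, drift and off-route probes
— but its scenes are far simpler than real drone footage: light sources
are smooth Gaussian blobs, there is no terrain occlusion, weather, or
celestial background, and scene complexity does not change along the route.
Passing tests therefore validate the algorithms and the pipeline, and show
that the visual-homing strategy is learnable and navigable under these
idealised statistics; they do not certify performance numbers on real
nightscapes. Desk-scale problem sizes (5,178 views at 64×64, 16 epochs,
50 simulation runs per condition) were chosen so a full study runs on one
CPU in minutes; the `paper_faithful` preset records the full-scale
configuration without being exercised.

Observed divergences worth noting: on this synthetic world the trained
errors (≈2° full-route, ≈14° in-gap at the default seed) are far below
the reference figures used as bounds — smooth, distinctive light blobs are
easier than real footage — and the unimodal units' preferred directions
cluster opposite the goal rather than near it. In-gap error varies
substantially from world seed to world seed (≈14–27° across three seeds),
driven by how many informative distant sources happen to serve the
excluded window.
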