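# Methods

## Problem and scope

`dogmotion` quantifies how a single dog moves during a behavioral
consultation, starting from overhead-camera tracking output: one planar
position per video frame, with a per-frame detection confidence. The
scientific question it serves is whether dogs with ADHD-like behavior show
movement patterns during consultation that distinguish them from controls
along three dimensions — speed, coverage of room space, and frequency of
re-orientation. The package deliberately begins *after* detection: video
decoding and the convolutional tracker that produces the (x, y) stream are
out of scope, as are clinical diagnosis criteria.

## Track preparation

Raw tracks are delimited text (`frame,time,x,y,confidence`). A frame is
treated as a missed detection when its confidence falls below 0.5 (the
tracker's own per-frame criterion is not part of the data contract, so the
threshold is exposed in the config) or its position fields are blank.
Preparation is a fixed sequence:

1. **Calibration.** Positions are converted from pixels to centimetres with
   a per-site scale (each clinic's camera height differs). All downstream
   metrics assume centimetres.
2. **Windowing.** The first 180 s of the consultation are analysed, as a
   half-open interval [0, 180). Consultations shorter than the window are
   rejected rather than padded.
3. **Quality control.** A track missing *more than* 30% of frames in the
   window is excluded (the boundary is exclusive: exactly 30% missing still
   passes). Exclusions are reported with their missing fractions rather
   than silently dropped.
4. **Gap filling.** Runs of up to 2 s of consecutive missed frames are
   linearly interpolated between the flanking detections; longer runs stay
   missing; leading/trailing runs are dropped (no flank to interpolate
   from). Originally valid positions are never altered.
5. **Resampling.** Positions are linearly interpolated onto a uniform 5 Hz
   grid. The choice is deliberate: turning-angle and simplification metrics
   should describe locomotion, not inter-frame tracker jitter, and at
   typical walking speeds 0.2 s steps are comfortably above the ~1 cm
   jitter floor. Resampling can only shorten a path (triangle inequality),
   so absolute distances are conservative.

The image coordinate convention (origin top-left, y downward) is accepted
as-is: every metric below is invariant under translation, rotation, and
reflection, so no axis flip is needed.

## Movement parameters

Twelve parameters are computed per subject, on the prepared track.

- **Distance** — summed Euclidean segment lengths (cm); **normalized
  distance** divides by body weight (kg), the approximate correction for
  larger dogs covering more ground by size alone. **Average speed** is
  distance over the tracked duration; it is weight-normalized the same way.
- **Turn counts** — absolute angles between successive displacement
  vectors, after merging steps shorter than 2 cm into the following
  displacement (sub-resolution noise must not register as turning), binned
  half-open with inclusive lower edges: [30, 60), [60, 90), [90, 120), and
  [120, 180]; angles under 30° are not counted as turns. A `turn_total`
  aggregate of the four bins is also reported.
- **Number of approximation points** — vertices surviving
  Ramer–Douglas–Peucker simplification at ε = 5 cm. The recursion keeps a
  point when its distance to the chord of its current segment (measured to
  the segment, projection clamped) exceeds ε; this variant makes the
  guarantee "every discarded point lies within ε of the simplified
  polyline" exact. ε is recorded in the output config digest.
- **Intensity of use (IU)** — path length divided by the square root of the
  area of movement. The area is the convex hull of visited positions (a
  grid-occupancy alternative was considered and rejected as default: it
  adds a resolution parameter with no principled value). The ratio is
  dimensionless and scale-invariant, and is reported unscaled — its
  conventional description as a percentage is dimensionally spurious.
- **Straightness (ST)** — net displacement over path length, in [0, 1].
- **Mean squared displacement rate (MSD)** — mean of ‖r_i − r_0‖² over all
  samples after the first, divided by the tracked duration, giving cm²/s.
  The reference position is the first valid position; division by duration
  is forced by the unit the quantity is conventionally reported in.
- **Sinuosity (SI)** — two modes. `ratio` is the literal path length over
  net displacement (≥ 1, undefined for closed paths, the reciprocal of
  straightness). The default `benhamou` mode is the corrected sinuosity
  2·[p·(1+c)/(1−c)]^(−1/2), with p the mean retained step length and c the
  mean cosine of turning angles; it is defined for closed paths and lives
  on the sub-1 scale observed in practice. The cohort summaries this
  package is checked against report SI values well below 1, which the
  ratio definition cannot produce — evidence that a corrected form was
  used; both are kept and the mode is recorded in output.
- **Fractal dimension (FD)** — box counting: square grids at 8
  geometrically spaced box sizes from 2 cm up to a quarter of the hull
  diameter are overlaid on the (densified) path; FD is the negative slope
  of log N(s) on log s, clamped to [1, 2] with the raw value retained.
  Box counting was preferred over the divider method for robustness to
  irregular sampling. Segments are densified to half the smallest box size
  first, so a sparsely sampled straight transit still fills its boxes and
  estimates FD ≈ 1.

Undefined metrics (degenerate hull, zero path length, extent below the FD
ladder) propagate as NaN with an explicit flag and are excluded pairwise in
the statistics stage — never imputed, never zero.

## Group comparison

Cohorts are small (12 per group in the design this reproduces) and metric
distributions are skewed, so location differences use the Mann–Whitney U
test with midranks, two-sided throughout: exact enumeration of the rank
distribution when the pooled sample is ≤ 12 and untied, otherwise the
normal approximation with tie-corrected variance and continuity correction.
The reported U is min(U₁, U₂). A fully tied pooled sample returns
U = n₁n₂/2, p = 1 by symmetry.

Effect size is Cohen's d with the root-mean-square pooled SD,
(m₁ − m₂)/√((s₁² + s₂²)/2), computed from sample means and (n−1) SDs; the
sign convention is case minus control. Post-hoc power is the power of a
two-sided two-sample t-test at |d|, via the noncentral-t distribution with
noncentrality d·√(n₁n₂/(n₁+n₂)) on n₁+n₂−2 degrees of freedom; at d = 0 it
equals α. An asymptotic-relative-efficiency correction for the rank test
(n_eff ≈ 0.955·n) would shift power by under a point at these sizes and is
not applied. Comparisons with power below 0.80 are flagged `disregarded`
but stay in the table. No multiple-testing correction is applied, matching
the reporting convention this pipeline mirrors.

Demographic matching uses the same U test for age and weight (per-group
median, SD, min, max reported) and Fisher's exact test plus the φ
coefficient for sex and neutered status.

## Synthetic cohorts

No tracking data were published with the study this package reproduces, so
validation runs on a seeded simulator. The kinematic model is a bounded
correlated random walk chosen as the *minimal* generator expressing the
three target dimensions; it claims metric-level contrast, not behavioral
realism:

- heading evolves by von Mises turning noise (concentration κ; higher =
  straighter), overridden by uniformly random heading resets at Poisson
  rate `reorient_rate`;
- step length per frame is a truncated-at-zero normal
  (`mean_speed`, `speed_sd`)/frame rate, zero during pause bouts, which
  start with per-second probability `pause_prob` and last an exponential
  `pause_mean_duration`;
- an optional angular drift (`anchor_strength`, per second) pulls the
  heading toward a fixed anchor point representing the owner's chair;
- walls reflect specularly (the simplest closed-room boundary), keeping
  every true position inside the room;
- an observation layer then adds isotropic Gaussian jitter (`jitter_sd`)
  and Bernoulli per-frame dropout, so invalid frames are missed
  detections, not teleports.

Presets (room 300 × 160 cm, 25 Hz, 180 s for both): the hyperactive-like
profile moves at 30 cm/s (SD 10), κ = 4, reorients 0.5/s, rarely pauses,
and ignores the anchor; the control profile moves at 8 cm/s (SD 3), κ = 8,
reorients 0.05/s, pauses often (0.4/s, mean 4 s), and is anchored
(strength 0.5). Both share 1 cm jitter and 5% dropout — values typical of
an overhead tracker at this scale — so both presets pass QC. Weights are
drawn per group from normals (21 ± 7 and 23 ± 7 kg, clipped to 8–45 kg).
Per-subject seeds derive from the master seed through `SeedSequence`, so a
cohort is byte-reproducible while subjects stay independent.

What the simulator does **not** emulate: owner interaction beyond the
static anchor, behavioral state switching richer than pause/move, camera
perspective distortion, identity swaps, or the heavy-tailed dropout bursts
real trackers produce. Passing tests on synthetic cohorts therefore
demonstrate that the pipeline *recovers designed contrasts through the full
I/O → QC → metric → statistics path*, not that it would classify real
clinic dogs.

One deliberate consequence of the noise model: a paused control dog under
positional jitter accumulates many sharp (> 120°) pseudo-turns once the
jittered displacement crosses the 2 cm merge threshold, so synthetic
control tracks are sharp-turn-rich relative to real slow dogs. The
directional contrast in total turns, speed, distance, coverage, and
straightness is unaffected.

## Numerical choices and degenerate inputs

- QC boundary exclusive at exactly 30% missing; fraction compared with a
  1e-12 tolerance to absorb float division.
- RDP uses an explicit stack (tracks can be long) and keeps endpoints
  always; ε = 0 keeps every non-collinear point.
- Turning angles clip cosines to [−1, 1] before `arccos`; zero-length
  steps are always merged regardless of `min_step`.
- 180° reversals bin into the sharpest class; the bins' lower edges are
  inclusive.
- FD needs ≥ 10 samples and a hull diameter > 4× the minimum box size;
  otherwise it is flagged undefined rather than extrapolated.
- Benhamou sinuosity returns 0 in the straight-path limit (mean cosine
  → 1), matching the ratio-mode value's reciprocal diverging.
- The comparison stage computes d = 0 (rather than failing) when both
  group SDs are zero, since identical groups are a meaningful null.

## Problem sizes

The bundled validation workloads are sized for a laptop: synthetic
acceptance cohorts use 12 subjects per group at 25 Hz × 180 s (4500 frames
per track, 24 tracks ≈ 2 s to simulate, ≈ 4 s end-to-end), RDP oracles run
120 random 50-point walks, Mann–Whitney exact agreement is enumerated for
all untied splits up to n = 4 per group, and the Monte-Carlo power oracle
uses 10⁵ simulated t-tests.

## Known limitations

- The exact RDP ε, turn-event definition, FD estimator, and sinuosity
  formula behind the published per-cohort magnitudes are unstated there, so
  published `number_of_points`, FD, and SI magnitudes are not reproduction
  targets; only quantities that recompute from printed inputs (effect sizes
  from group summaries, demographic medians) are asserted exactly.
- The convex hull overestimates the used area for L-shaped visits; IU is
  correspondingly conservative.
- MSD from a single reference position conflates diffusion with directed
  departure; it is kept because it is the convention in the parameter set
  being reproduced.
- Power is computed on the t-test model at the rank test's effect size — a
  standard but approximate pairing.
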