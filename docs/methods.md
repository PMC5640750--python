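# Methods

## Arena standardisation

Each testing arena is described by raw-frame landmarks: the two feeder
plates, two points on the infrared beam, and the entrance-door midpoint.
The analysis frame puts the Go plate at (1, 1), the Change plate at
(−1, 1) and the beam on y = 0, so one unit equals half the 50 cm plate
spacing (25 cm).  The constraints "plates to (±1, 1)" and "both beam
points onto y = 0" give six linear equations for the six parameters of a
2-D affine map, so the transform is determined exactly; the remaining
freedom in the x-row (the plates fix only two of its three parameters) is
closed by sending the midpoint of the two beam points to x = 0, i.e. the
beam emitter/receiver pair is taken to straddle the arena centreline, as
it does physically.  The solve is affine-equivariant: rescaling, rotating,
shearing or reflecting the raw coordinates (together with the landmarks)
leaves the standardised output bit-for-bit unchanged, which is what the
mirror-invariance and scale-invariance tests check.  Mirrored arenas need
no special casing — the calibration labels each plate, so the fitted map
absorbs the reflection — and the `mirrored` flag is carried as metadata
and used by the simulator to lay out the reflected arenas.

Calibrations whose landmark geometry is inconsistent (plates at unequal
offsets from the beam line, collinear/coincident landmarks, entrance on
the plate side of the beam) are rejected rather than silently fitted.

## Event detection

* **Beam crossing**: the first consecutive sample pair with y going from
  below zero to at/above zero; time and point are linearly interpolated
  to y = 0 exactly.  Sub-frame interpolation avoids quantisation bias in
  the reaction-time measure at low frame rates.  The *first* upward
  crossing is used because the physical change signal fires on first beam
  interruption.
* **Completion**: the first time the path comes within the capture radius
  (default 0.2 units = 5 cm, the feeder-plate half-width) of the active
  plate centre, again interpolated between samples.  On Change trials
  only the Change plate, and only after the crossing, can complete the
  trial (the Go plate is covered at the beam).
* **Correction point**: among the interpolated crossing point and all
  later samples up to completion, the sample of maximal x; ties resolve
  to the earliest sample (the first instant the bird stops gaining ground
  toward Go).  If no sample exceeds the crossing x, the crossing itself
  is returned with zero distance and zero reaction time.

The correction distance is Euclidean from the crossing point by default;
an along-path option (`distance_metric: PATHLENGTH`) is provided, since
the published range of the measure is compatible with either reading.

## Vincentization

A completed path is resampled at the n latency quantiles k/n (default
n = 20), i.e. the interpolated positions at times
t_entry + (k/n)(t_end − t_entry); the start position is kept separately
for plotting.  Quantile paths with equal n can be averaged pointwise
across birds to give mean trajectories per trial.

## Exclusion rules

* Any of the six trials not completed in under 2 min (or never completed)
  excludes the bird; "less than 2 min" is read strictly, so a latency of
  exactly 120.0 s is a timeout.
* On trial 6, the pre-crossing samples must stay within 33% of the
  entrance→Go line length of that line; the deviation functional is the
  maximum perpendicular distance to the segment (a mean-offset variant is
  configurable), normalised by the segment length.  "More than 33%" is
  strict: a ratio of exactly 0.33 is retained (an epsilon of 1e−9
  relative guards the boundary against floating-point rounding).
* Birds with fewer than six usable trials are flagged MISSING_DATA.

Both rules are monotone in their thresholds: loosening a threshold never
excludes a previously retained bird.

## Composite scores

The three measures (latency difference, correction distance, CSRT) have
incommensurate units, so the composite is the first principal component
of their **correlation** matrix (z-scored inputs).  The eigenvector is
oriented so the loadings on the three poor-control measures are
non-negative (flipped by the loading sum if necessary) and the projection
is multiplied by −1, making high scores mean strong inhibitory control —
a deterministic convention stable across linear-algebra backends.  The
body-size component treats mass and tarsus the same way; its eigenvalue
is analytically 1 + |r|, the variance explained (1 + |r|)/2, and the
exactly-uncorrelated tie resolves to the (1, 1)/√2 direction.

## Inference

* The repeated-measures ANOVA (Block: trials 1–3 vs 4–6 × Trial Type:
  first Go, second Go, Change) partitions sums of squares explicitly and
  tests each effect against its own Effect × Subject stratum.  No
  sphericity correction is applied by default (a Greenhouse–Geisser
  option exists); the implementation is cross-checked against
  statsmodels' AnovaRM in the test suite.
* Quadratic trends use the per-bird contrast (1, −2, 1) tested against
  zero (F = t², df (1, n−1)); post hocs are the three within-block paired
  t-tests with Bonferroni correction (adjusted p = min(1, 3p), family =
  the three within-block pairs).
* The IC-score model is a linear mixed model (normal response, REML, via
  statsmodels MixedLM) with a random intercept for enclosure and fixed
  effects sex (female = 0 reference), body size, BWA, TO and trial-4
  latency.  The sex × size interaction is fitted first and dropped — with
  a main-effects refit — when its p ≥ 0.05.  Reported p-values are Wald
  tests from the large-sample normal approximation (the "t" column is
  coefficient/SE); with a single enclosure the model falls back to OLS
  with a logged warning.

## The synthetic cohort

The simulator is a kinematic heading-relaxation walker, not a force
model: each frame (dt = 0.04 s, 25 fps-like) the heading turns toward the
active target by at most ω·dt (ω = 20 rad/s) plus Gaussian heading noise
(default 0.05 rad/√s), and the position advances v·dt.  Every trial
starts at the entrance (0, −0.2) aimed at the Go plate — the empirically
observed initial bias — and on Change trials the target switches to
(−1, 1) at (first beam crossing) + τ, making the per-bird detection delay
τ the exact generative analogue of the CSRT.  Speeds are drawn from
N(0.45, 0.08) units/s (Go-trial latencies of a few seconds) and
τ ~ U(0.2, 3.0) s, spanning immediate to very sluggish correction.

Non-participation is injected per trial with probability 0.135: such
trials are tortuous wanderers that pace the lower arena for the full
130 s cap and never complete, so the bird falls to the 2-minute rule.
The per-trial rate makes the expected share of birds with at least one
timeout trial 1 − (1 − 0.135)⁶ ≈ 58%, matching the drop-out level the
task produces in practice.  Covariates emulate the study population:
~30% male/female mass dimorphism with a within-sex mass–tarsus
correlation of 0.6 (pooling to ≈ 0.83, so the size component explains
≈ 91% of the variance), gamma-distributed worm-acquisition latencies
(mean ≈ 24 s), shuffled entry-order ranks, and optional sex/size shifts
on τ for model-recovery studies (zero by default).  Tracks are emitted in
raw centimetre coordinates through per-arena similarity maps (small
camera rotations, genuine reflections for the mirrored arenas) together
with the matching calibrations, so the full standardisation path is
exercised.

What the simulator does **not** emulate: learning or familiarisation
across trials (an optional trial-1 slowdown factor exists but defaults to
off and makes no mechanistic claim), gait/acceleration structure,
tracker jitter or dropped frames, and any dependence of the crossing
point on individual strategy (simulated birds cross near x ≈ 0.17, the
straight-line value, with little spread).  Passing recovery tests
therefore show that the estimators invert this generative model, not that
real trajectories are this clean.

## Numerical choices and problem sizes

Recovery checks use 200-bird clean cohorts (timeout propensity 0);
turn-rate ω = 20 rad/s keeps the post-switch turn fast enough that the
discretisation bound mean |CSRT − τ| ≤ 2·dt holds at zero noise, while
still giving smoothly curved corrections at the default noise.  The
sign-convention sweep uses 100 seeds of 16-bird cohorts; ANOVA
calibration uses 400 null replicates at n = 50 and mixed-model coverage
100 replicates at n = 200 with four enclosures, generated at the score
level (not via trajectories) since only the inference layer is under
test.  CSV round-trips write floats with 17 significant digits and parse
with round-trip precision, so reader/writer composition is exact.

## Known limitations

* The mixed model's p-values are asymptotic Wald tests; with four
  enclosures the random-intercept variance is weakly identified and can
  estimate to zero in small cohorts.
* The deviation rule needs a defined trial-6 crossing; birds that never
  cross are reported as MISSING_DATA rather than given a deviation ratio.
* Latency is defined geometrically (capture-radius entry), which can
  differ from hand-timed food consumption by a fraction of a second.
* Vincentization requires completion; timed-out trials have no quantile
  path and simply drop from mean trajectories.
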