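# Methods

`shoalnoise` analyses the structure and dynamics of small fish shoals in a
two-half sound-playback design: each group of fish is filmed for one
period without playback (first half) and one with playback (second half),
under one of two between-group treatments (ambient coastal sound vs
pile-driving noise).  This note records the models, the estimators, the
numerical choices, and what the built-in simulator does and does not
emulate.

## Trajectory model and kinematics

Input trajectories are per-fish centroid tracks `(frame, fish_id, x, y)`
at a fixed frame rate, converted to cm by a single pixel scale and placed
on a dense frame grid; tracking dropouts are NaN.  Internal gaps up to
`max_gap` frames (default 30, about 0.5 s at the full-scale 59 fps) are
filled by linear interpolation; longer gaps and gaps touching the series
ends are left missing and excluded pairwise by every metric.  Gap repair
is deliberately conservative: the tracker's identity swaps cannot be
detected from coordinates alone and no correction is attempted.

Velocity is estimated by central differences on boxcar-smoothed positions
(window 5 frames; pixel jitter otherwise dominates the heading estimate at
high frame rates), with one-sided differences at the series ends and at
gap borders.  Speed is the velocity norm; heading is the unit velocity and
is treated as undefined below 0.5 cm/s, since the bearing of a sub-noise
displacement is meaningless.  "Direction" therefore means the direction of
travel, not body orientation — only centroid tracks are available.

## Shoal-structure measures

Per fish and per trial half:

- **Centroid distance** — distance to the arithmetic mean position of the
  group at each frame; frames with fewer than two tracked fish are skipped
  and counted.
- **Nearest-neighbour distance (NND)** and its **mode** — the nearest
  neighbour is re-assigned every frame (ties to the lower fish id); the
  modal NND is the centre of the fullest bin of a fixed-width histogram
  (default 0.5 cm, ties to the smaller distance).  A histogram mode is
  used rather than a kernel density because it is reproducible and its
  tie-breaking is explicit.
- **Bearing angle** to the nearest neighbour — the unsigned angle between
  the focal heading and the focal-to-neighbour vector, folded to
  [0, 180]° (left-right symmetry assumed); 0° is dead ahead, 90° directly
  beside, 180° dead behind.  Frames are split into front (< 90°) and
  behind (>= 90°) and summarised separately by arithmetic means of the
  folded angles.
- **Perpendicular / parallel offsets** — absolute components of the
  focal-to-neighbour vector across and along the focal heading, so
  perp² + para² = NND² frame by frame.  Absolute values are used because
  signed means vanish by left-right symmetry.
- **Heading difference** — unsigned angle between the two headings
  (0° aligned, 180° opposed), the local directional-order measure.
- **Relative-position map** — 2-D histogram of signed neighbour offsets
  in the focal-centred, heading-aligned frame (x = right, y = ahead),
  1 cm bins over ±30 cm, normalised to a probability mass function and,
  for display, smoothed with a Gaussian filter of σ = 6 cells.  The
  smoothed map is renormalised so smoothing conserves total mass exactly
  even for mass near the map border.

## Movement dynamics

For a fish pair (i, j) and integer frame lag τ the **speed
cross-correlation** is the Pearson correlation of speed_i(t) with
speed_j(t + τ) over the valid overlap; the **direction cross-correlation**
is the mean dot product of the two unit headings at the same relative
shift (the normalised-velocity correlation used in leader–follower
analyses of bird flocks).  The curve is scanned over τ in ±`max_lag`
(default 2 s); the **peak** is the maximum of the curve (not the maximum
absolute value) and the **delay** is the lag at the peak, positive when j
follows i.  Ties are broken toward the smallest |τ|, negative before
positive.  Lags whose overlap falls below `min_overlap` (default 100
frames) or where a series is constant are dropped; a pair with no valid
lag is an error.

Each fish contributes one pair per half: its **modal nearest neighbour**
(most frequent NN over the half, ties to the lower id), with the
correlation computed once over the whole half.  Per-frame re-pairing would
fragment the series into segments too short for a stable correlation.
Speed delays are computed but flagged as excluded from inference — speeds
are near-synchronous, so their delays carry no usable signal — while
direction delays are analysed.

When both series are gap-free the per-lag Pearson curve is computed with
prefix sums and a single cross-correlation pass; the masked per-lag loop
is kept as the general path and both are held to agreement with a
brute-force per-lag oracle at 1e-10 in the tests.

## Statistical analysis

Every response is summarised per fish per half and modelled with fixed
effects treatment (between subjects), trial half (within subjects) and
their interaction, and random intercepts for trial and fish-within-trial.
The interaction is tested first; when non-significant (p >= 0.05) it is
dropped and the model refitted with main effects only.

- **LMM responses** (median speed, direction delay untransformed; centroid
  distance and modal NND after log10; peak speed/direction correlations
  after log10(1 − r)): fitted by REML.  On complete balanced data the
  package uses the closed-form ANOVA-stratum solution, which coincides
  with REML there and makes the interaction test the exact F-test of the
  within-fish stratum; the general iterative fit (statsmodels MixedLM)
  covers unbalanced data and the median-speed-covariate refits, and the
  two routes are cross-checked in the tests.  Denominator degrees of
  freedom follow the containment method (interaction and half: n_obs −
  n_fish − q_within; treatment: n_trials − 2); the method is recorded in
  the output so F statistics can be compared like for like.
- **NB-GLMM responses** (perpendicular/parallel offsets, front/behind
  bearings, heading difference — right-skewed positive summaries):
  negative-binomial GLMM with log link and variance μ(1 + μ/k), fitted by
  Laplace-approximated maximum likelihood written for this package
  (inner Newton for the 150 random effects, outer L-BFGS-B over fixed
  effects, two log-variances and log k).  The fit agrees with glmmTMB to
  four decimals on a reference dataset (cross-checked in the tests).  The
  interaction is tested by a likelihood-ratio χ² with 1 df.  Continuous
  summaries are integerised before fitting (degrees for angles, mm for
  offsets), recorded in the output.
- **Dispersion check**: the same fixed-effect structure without random
  effects as an NB GLM (shape estimated by ML); dispersion = Pearson
  χ²/df, passing in (0.5, 2).  Because the shape parameter absorbs global
  overdispersion by construction, the check flags variance *patterns* the
  NB law cannot represent (e.g. heteroscedasticity across design cells or
  near-deterministic counts) rather than simple scale inflation.
- **Effect size of change**: Δ = (half 2 − half 1) per fish, averaged to
  trial level to respect the non-independence of fish within a trial;
  Cohen's d between treatments on the trial-level Δ with pooled SD.
  Positive d means the response increased more (or decreased less) under
  pile-driving.  Trial-level aggregation is a deliberate choice: fish
  within a group are not independent replicates.
- The correlation and delay responses are additionally refitted with the
  fish's median speed as a covariate, because they co-vary with swimming
  speed.  No multiple-testing correction is applied across responses.

## The synthetic experiment

No trajectory data are distributed with the original study, so the
package ships a zonal shoal simulator that reproduces the *statistical
structure* of the experiment — 2 treatments × 15 groups × 4 fish, two
halves, paired-block treatment order randomisation — with known ground
truth, at a desk scale of 15 fps and 60 s halves (the full 59 fps / 300 s
design is a config choice; desk scale keeps the simulation studies within
minutes).

Each fish updates a heading from hard repulsion inside 6 cm, alignment
with neighbours within 20 cm, spring-like attraction toward the local
centroid (strength growing with distance and saturating at the alignment
radius, so the attraction weight sets the equilibrium spacing), a heading
inertia term, wrapped-Gaussian turning noise, and a deflection away from
the octagonal wall (narrowest width 105 cm) inside a 12 cm buffer.
Speeds follow a preferred speed of 12 cm/s (≈1.2 body lengths/s for a
~10 cm juvenile) plus three AR(1) terms: a fast shared group term (near-
white, so it couples neighbours' speeds without slow group drift), a fast
individual term, and a slow individual "personality" offset (τ = 20 s).
A slow shared cohesion state (log-normal drift of the attraction weight,
τ = 8 s) makes the shoal drift between tighter and looser configurations.
One designated fish is a follower: it copies the mean heading of the rest
of the group with a fixed 3-frame (0.2 s) delay, and the leaders ignore
it in their alignment term so the built-in lag remains identifiable
ground truth for the cross-correlation stage.

The playback "disruption" multiplies, from the half boundary on, the
preferred speed, the alignment weight (including the follower's copying
weight), the attraction weight, and the noise scales.  The default
calibration makes both treatments perturb the shoal with the pile-driving
treatment much stronger: ambient (0.9, 0.95, 0.95, 1.1), pile-driving
(0.6, 0.6, 0.7, 1.5) for (speed, alignment, attraction, noise).

The noise architecture is chosen so that, under an identity disruption,
the per-fish-per-half summaries are approximately consistent with the
fitted mixed model (independent fish-level residuals given the trial):
shared processes are fast (their half-means are tiny) while individual
heterogeneity is slow (large independent per-half variation per fish).
This is what makes the null-calibration study meaningful.  Two structural
exceptions are documented below.

What the simulator does **not** emulate: body shape and orientation (only
centroid tracks), tracking noise and identity swaps, wall-following
thigmotaxis, acoustics of any kind, habituation within a half, and any
fitted correspondence to the original fish — effect magnitudes are free
simulator parameters, not estimates.

## Known limitations

- **Pair-level responses and the prescribed random-effects structure.**
  The peak speed/direction correlations of a mutual modal-neighbour pair
  are *identical numbers* for both fish (the curve of (j, i) is the mirror
  of (i, j)), and the direction delays are exactly opposite.  At least one
  mutual pair always exists among four fish (the most co-adjacent pair is
  mutual for both members).  Random intercepts for trial and
  fish-within-trial cannot represent this within-pair residual coupling,
  so the interaction test is intrinsically anti-conservative for the two
  correlation peaks (observed null rejection ≈ 0.10–0.18 at α = 0.05) and
  conservative for the signed direction delay (rejection ≈ 0–0.03): the
  duplicated values shrink or inflate the within-trial error estimate in
  opposite directions.  The modal NND is affected in attenuated form: the
  NND series of the two members of a mutual pair are nearly identical, so
  their modes are partially duplicated (observed null rejection ≈ 0.1).
  No generator design removes this; it is a property of the response
  definitions plus the model structure, and it will be present in real
  data analysed the same way.  The same coupling limits the power of the
  modal-NND interaction test in the disruption experiment: with the
  default effect calibration the other four headline measures reproduce
  the expected effect pattern in essentially every replicate, the modal
  NND in only a minority.
- The closed-form REML path truncates negative variance-component
  estimates at zero; the iterative path may settle on a slightly
  different boundary solution.  Both flag boundary fits.
- The Laplace approximation slightly biases NB-GLMM variance components
  for very small k; at the shapes arising here (k in the tens) the
  agreement with glmmTMB is numerically exact for practical purposes.
- The modal NND inherits the histogram discretisation (half a bin width);
  at the default 0.5 cm bin this is visible in the response's noise
  floor.
- Degrees of freedom for the LMM F-tests use containment; software using
  Satterthwaite or Kenward–Roger will print different denominator df for
  the same data (the method is recorded in every output row).
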