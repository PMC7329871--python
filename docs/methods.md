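# Methods

This note documents the models, conventions and numerical choices
behind `echogaze`, and what the synthetic-data generator does and does
not emulate.

## Geometry and conventions

The flight chamber is 9 m (x, along the aisle) × 4.5 m (y) × 2.5 m.
The origin sits at the chamber corner nearest the start position;
horizontal bearings use the chamber frame (x-axis = 0°, y-axis = +90°),
wrapped to (−180°, 180°].  Angular differences are always minimal
differences; Δpulse direction is their absolute value.

The aisle is framed by chain lines at y = 1.25 and 3.25 m (the aisle
width is not reported in the source material and is configurable).
Three obstacle walls hang into the aisle from alternating sides at
x = 4.5, 5.5 and 6.5 m — evenly placed inside the accurate measurement
band, 2–5 m from the frontal wall, which is where the course was built
precisely because direction errors there are below 3°.  A permeable
wall is three 4-cm chains at 22-cm spacing (lateral span 0.48 m); a
reflective wall is a 1-m acrylic board sharing the same inner (free)
edge, so the flight gap is identical in both conditions.  The start
position is 1.3 m behind wall 1, centred in the aisle.

Twenty microphones sit at 1.2 m height: six on the frontal wall at
0.75-m spacing and seven per side wall at 1.1-m spacing, centred on
each wall.  Extra channels (e.g. board-embedded microphones) can be
appended through the arena config.

**Flight sections.**  Section boundaries are the x positions of walls
1 and 2, half-open so a point exactly on a boundary belongs to the
later section; section 3 extends from wall 2 to the end of the flight.
This makes the sections a partition of every emitted pulse, which is
required for per-section counts to sum to flight totals (the reported
per-section multiple-pulse means sum to the flight-level mean).

## Signal processing

Spectrograms follow the study's analysis settings: Hanning window of
1,024 points of which 512 are zero-padding (512 real samples), 98%
overlap (hop = 10 samples = 20 µs), fs = 500 kHz.  Pulse detection
thresholds the in-band (20–150 kHz) frame energy at −45 dB re the file
maximum — the source material states no detection threshold, only the
−25 dB tFM₂ criterion, so the threshold is configurable — and merges
supra-threshold regions separated by < 2 ms.

The tFM₂ (terminal downward FM sweep of the second harmonic) is
isolated within each detected pulse as the last contiguous run of
frames whose peak frequency falls > 1.5 kHz below the CF₂ plateau while
remaining within 25 dB of the maximum-energy portion; the first frame
of that run is the emission time.  The ~10 ms offset between true
pulse onset and tFM₂ onset is deliberately left uncorrected (it cancels
in IPIs and is irrelevant to position at 125-Hz tracking).  Windowing
biases each onset by a constant ≈ 0.3 ms, which likewise cancels in
IPIs; the tests bound per-onset error at 1 ms and IPI error at two
hops.

## Direction reconstruction

Per pulse and channel, arrival times are `t + r/c` with c = 344 m/s
(22 °C chamber; the speed of sound is not reported and is config).
Corrected levels add back spherical spreading re 1 m and absorption at
2.4 dB/m (65 kHz) and subtract per-channel sensitivity offsets.
Offsets come from a reference-tone pre-measurement (107 dB, 65 kHz,
1 m) and are expressed relative to the median channel, so a single
deviant channel is attributed its full excess.

The directivity fit is nonlinear least squares of
`b + A·exp(−(θ−μ)²/2σ²)` against corrected levels in dB over
microphone bearing.  Choices the source leaves open, made here:

* **dB domain** (configurable sensitivity analysis is possible by
  fitting linear pressure instead); the free baseline `b` makes μ
  exactly invariant to global gain.
* Bearings are unwrapped around the best-level channel so the fit
  never straddles the ±180° seam; initial values are the level range,
  best-channel bearing and σ₀ = 30°.
* Validity gates: ≥ 5 channels spanning ≥ 40° of bearing, ≥ 3 dB of
  dynamic range, σ ≤ 180°.  Channels occluded by a reflective board or
  within 6 dB of the noise floor are excluded before fitting.  Pulses
  with failed fits propagate missing directions and are dropped from
  gaze metrics (counted in the localization log).

On noise-free synthetic levels the reconstruction is exact to
numerical precision across the measurement band and ±60° of beam aim;
the acceptance grid verifies the < 3° system bound end to end.

## Kinematics and strobe grouping

Speeds are central differences of the 125-Hz positions with a 5-sample
moving average (window configurable); maximum flight speed is taken
from flight start to the first crossing of wall 3.  The meandering
width Δd is the absolute y-difference between the first prominent
lateral extremum (0.05-m prominence on the smoothed track) and the
following extremum of opposite sense.  Strobe groups use the strict
40-ms rule; an IPI of exactly 40 ms splits groups.  "Number of
multiple pulses" counts pulses belonging to multiple-type groups
(matching the reported pulse-count axes); group counts are exported
alongside.

## Synthetic-data generator

The generator's defaults are the study conditions; they were fixed by
calibration to the reported estimated marginal means of the
experiments the generator emulates, and were not tuned to test
outcomes.

* **Cohorts**: 7 bats per condition, flights 1 and 12 (intermediate
  flights interpolate log-linearly).
* **Counts**: per-flight totals are Poisson with cell means 52 → 29
  (permeable 1st → 12th) and 51.9 → 37.0 (reflective), times a bat
  random intercept (SD 0.12 on the log scale).  A per-bat
  "cautiousness" couples slow flight to high emission (−0.25 log
  counts per m/s of speed intercept), reproducing the negative
  speed–count relation.
* **Strobe mix**: pulse shares of multiples are the ratio of the
  reported multiple-pulse to total-pulse means (e.g. 28.8/52 → 8.2/29
  permeable); singles default to 3.5% of pulses; multiple groups are
  size 3 or 4 (0.6/0.4).  Multiple groups are drawn at flight level
  and allocated to sections as whole groups by weights matching the
  reported per-section means, so small cells cannot silently lose
  multiples; doublets and singles fill the remaining section budgets.
  Within-group IPIs are uniform on [25, 39) ms, between-group gaps
  lognormal with 80-ms median, floored at 42 ms (the reported
  material fixes only the 40-ms boundary).
* **Trajectories**: a cubic spline through the gap waypoints realises
  the requested meandering width; the along-path speed ramps to the
  drawn maximum just before wall 3 (cell means 2.5 → 3.4 m/s permeable,
  2.6 → 2.8 reflective; bat SD 0.35, residual SD 0.30) and relaxes
  toward landing.  In the permeable condition Δd decreases with speed
  at −0.23 m per m/s (the reported 80 → 20 cm range over 1.4–4 m/s);
  in the reflective condition Δd declines only mildly with flight
  number.  Waypoint jitter (SD 2 cm) keeps flights from being
  identical.
* **Gaze**: scan amplitude 30° (flight 1) → 8° (flight 12),
  alternating sides per strobe group; in-wall gazing probabilities use
  the reported raw rates per condition and flight (7%/23% permeable,
  25%/8% reflective).  Note the reported 1st-flight rates sentence is
  internally inconsistent (it pairs "three times higher in permeable"
  with raw ratios pointing the other way); the generator and the
  metrics report raw ratios only and do not adjudicate.
* **Beam/levels**: Gaussian beam in the dB domain (σ = 25°, off-axis
  attenuation depth 40 dB, source level 120 dB), spherical spreading,
  2.4 dB/m absorption, optional per-channel offsets and dB-level
  noise; reflective boards hard-occlude blocked channels to the noise
  floor ("boards do not permit sensing the space behind").
* **Audio**: CF-FM pulses (1.5-ms up-sweep from 55 kHz, 10 ms of CF₂
  at 69 kHz, 2.5-ms down-sweep to 50 kHz) phase-continuous at
  fs = 500 kHz; scheduled times are tFM₂ onsets.

What the generator does **not** emulate: echoes returning to the bat,
receiver/cochlear processing, 3D (vertical) beam structure, chain-level
acoustic scattering, collision avoidance dynamics, or learning
trajectories beyond the configured interpolation between flights 1 and
12.  Passing tests therefore demonstrate that the analysis pipeline
recovers known structure of this class — not that it would be robust
to every artefact of real array recordings.

## Mixed models

All models carry a bat-ID random intercept.  Gaussian responses use
statsmodels `MixedLM` fitted by ML (so that likelihoods, AICc and
bootstrap LRTs are comparable across fixed-effect structures), with a
plain-regression fallback when the variance sits on the zero boundary.
Poisson log-link GLMMs are fitted by maximum likelihood with an
adaptive Gauss–Hermite quadrature (15 nodes; per-group posterior modes
by damped Newton), the same scheme as `glmer(nAGQ = 15)`; one test
checks coefficients, random-intercept SD and likelihood differences
against lme4 through Rscript.  Standard errors come from a
central-difference observed information matrix.

Conventions and open-design choices:

* **Speed covariate** is z-scored before Poisson fits.  The reported
  slope −1.5 with its accompanying marginal predictions is only consistent
  with a standardised scale (a raw-m/s slope contradicts the reported
  66 → 27 pulse drop over 1.7 → 3.8 m/s), so the standardised slope is
  the recovery target; the accompanying reported SE (1.1, vs z = −7.5)
  is inconsistent with itself and is not used.
* **Estimated marginal means** average cell predictions over other
  factors on the link scale and back-transform (the emmeans
  convention).  CIs use a t quantile with between-group degrees of
  freedom (n_bats − 1): at 7 bats the EMM uncertainty is dominated by
  the between-bat variance, and this df convention gives 95% intervals
  that empirically cover generator truth at the nominal rate (93–97%
  band verified over 800 replicates), where plain normal quantiles
  undercover (~92%).
* **Pairwise contrasts** are Tukey-adjusted via the studentized-range
  distribution on z-ratios (Bonferroni and unadjusted styles are also
  emitted, mirroring the dual post-hoc styles reported for this design).
* **Type-II Wald χ²** tests each term in the model containing all
  terms that do not include it (marginality respected).
* **Parametric bootstrap**: responses are simulated from the fitted
  null, both models refitted (warm-started, covariance skipped), and
  p = (1 + #{T* ≥ T}) / (n_ok + 1); non-convergent refits are dropped
  and counted.  Type-I error at nominal 0.05 is verified to lie in
  [0.03, 0.07] over 500 null-true cohorts.
* **AICc** uses k = fixed effects + variance parameters;
  **R²** follows the Nakagawa–Schielzeth variance partition with the
  lognormal approximation `ln(1 + 1/λ̄)` for the Poisson
  observation-level variance; **overdispersion** is Pearson χ² over
  residual df at conditional (posterior-mode) means.
* The **collinearity screen** computes Pearson ρ, t and df and
  triggers the reported model split at |ρ| > 0.5 — the generator's
  coupled meandering width and flight number trigger it by
  construction.

## Problem sizes

Acceptance-style checks run at the study's scale where that scale is
the point (7 bats × flights 1 and 12) and average marginal means over
20 seeded replicates; the direction-fidelity grid uses 125 noise-free
position/direction pairs; bootstrap calibration uses 500 replicate
cohorts with 19 bootstrap simulations each (at that size the nominal
0.05 decision reduces to "observed statistic exceeds all simulated
ones", keeping the check exact and cheap); audio round-trips use
ten-pulse schedules.  These sizes were chosen as the smallest that make
the statistical claims sharp.

## Known limitations

* The Poisson GLMM supports a single random intercept — sufficient for
  the bat-ID design, not for crossed or nested random effects.
* Satterthwaite/Kenward–Roger df are not implemented; LMM contrasts
  use residual-df t statistics and GLMM contrasts use z statistics
  (reported GLMM tables for this design likewise omit df).
* Direction reconstruction is horizontal-only by design; elevation is
  out of scope.
* The detection stage assumes the rendered CF-FM pulse family; real
  recordings with overlapping echoes or Doppler-shifted CF₂ would need
  threshold/band retuning.
* `section_histograms` assumes gaze points are tagged with the wall
  they were computed against; pulses emitted past wall 3 have no gaze
  point and drop out of the histograms (they still count in totals).
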