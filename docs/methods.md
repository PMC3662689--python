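# Methods

## The scientific question and the model

A person planning a speeded reach implicitly weighs her own motor
uncertainty.  The package implements the full analysis chain for asking
whether the *internal model* of that uncertainty — the error
distribution implied by a person's choices — matches the *true*
distribution of her movement endpoints.

True endpoints around an aim point are modelled as a bivariate Gaussian
with per-axis standard deviations σh, σv (mm) and correlation ρ.  We
parameterize it by the geometric-mean variance σ² = σh·σv and the
anisotropy η = σv/σh, so σh² = σ²/η and σv² = σ²·η.  η = 1 means
isotropy; this convention makes the variance and shape dimensions
orthogonal and matches the scale on which anisotropy ratios (≈1.1–1.6
for upward reaching) are usually reported.  The analysis treats the axes
as uncorrelated; the `correlation_sensitivity` diagnostic quantifies the
error so incurred (for |ρ| ≤ 0.44 and the design's rectangles it is
below 2 percentage points of hit probability).

The probability of hitting a target is the Gaussian mass over the target
region.  For axis-aligned rectangles with ρ = 0 this is a product of
normal CDF differences; with ρ ≠ 0 it is the bivariate normal rectangle
probability (absolute tolerance 1e−9).  For circles it is a 1-D chord
integral evaluated by Gauss–Legendre quadrature after mapping the circle
to an angle variable; the node count scales with r/σh, and an adaptive
fallback covers extreme radius-to-σ ratios.  When a rectangle's hit
probability saturates toward 1 in floating point, the *miss* probability
(computed from survival functions) is matched instead, which preserves
resolution.

The subject's internal model is either a Gaussian of the same form with
free parameters (σ̃², η̃), the *area-matching* rule (compare target
areas; the σ̃² → ∞ limit of the Gaussian model), or a uniform disk (used
for the motor-lottery thought experiment).  The *equivalent radius* of a
rectangle under a model is the circle radius the model judges equally
hittable; it is found by bracketed root finding on log radius (relative
tolerance 1e−8) between the rectangle's inscribed and circumscribed
circles, which bracket the root by set inclusion.

## Choice task, staircases, psychometric model

Choices between a rectangle and a circle of radius r follow a Weibull
psychometric function P(choose circle) = 1 − exp(−(r/a_j)^γ) with a
per-rectangle position a_j and one steepness γ per session; the
equivalent radius is its 50% point, r_eq = a_j (ln 2)^{1/γ}.  The joint
MLE profiles γ (the per-rectangle likelihoods separate at fixed γ, and
are maximized by a vectorized golden-section search); the outer search
uses five log-spaced starts plus bounded refinement.  Perfectly
separable data push γ to the declared cap of 50 and are flagged.

Synthetic subjects answer through the same Weibull family, with the
position parameter set to r_eq*/(ln 2)^{1/γ} so the subject is
indifferent exactly at her internal model's equivalent radius r_eq*.
Making generation and fitting self-consistent is deliberate: parameter
recovery then tests the estimation chain rather than a modelling
mismatch, and γ → ∞ recovers a deterministic chooser with threshold
r_eq*.  No lapse parameter is generated or fitted; the lapse behaviour
of real subjects in this task is unknown, and inventing one would
change the generator in an unverifiable way.

Circle radii are driven by transformed up–down staircases with
multiplicative (log10) steps.  Design 1 pairs each of 10 rectangles
(4:1 and 1:4, short sides {0.60, 0.90, 1.35, 2.025, 3.0375}×σ̄ — a
geometric ladder, ratio 1.5, spanning sub- to supra-σ̄ sizes) with a
1-up/2-down and a 2-up/1-down track of 50 trials (steps
0.115/0.075/0.05/0.04 log units by reversal epoch); design 2 uses 4
sizes, one 1-up/1-down track of 60 trials (steps 0.15/0.1/0.08/0.06)
per rectangle, and 600 instead of 300 training reaches.  Staircases
start at each rectangle's area-equivalent radius, an anchor that favours
neither hypothesis.  Tracks are interleaved round-robin with a seeded
shuffle within rounds.  The step epoch advances on the reversal event
itself; the new step applies from the next update.  Simulated tracks
converge near the 70.7%, 29.3% and 50% points of the responder's
psychometric function, as transformed up–down theory predicts.

## Internal-model fit and model comparison

Measured log equivalent radii are modelled as the model-predicted log
radii plus iid Gaussian noise of SD σ_e (log units).  The Gaussian
internal model has parameters (σ̃², η̃, σ_e); σ_e has a closed-form MLE
at fixed (σ̃², η̃), so the search is a 2-D grid
(σ̃²/σ² ∈ [0.1, 1000] × η̃ ∈ [0.25, 4], log-spaced) followed by
Nelder–Mead refinement on log parameters.  The area-matching alternative
predicts sqrt(w·h/π) and has σ_e only.  σ_e is floored at 1e−6 log units
so a perfect fit keeps a finite, dominating likelihood.

Because area-matching is nested in the Gaussian family, subjects are
classified by λ = 2(logL_G − logL_A) against the 95th percentile of χ²
with df = 2 (three parameters vs one).  Two caveats are intrinsic to
this recipe and are checked empirically rather than assumed: the null
sits on the *boundary* of the Gaussian parameter space (σ̃² → ∞), and n
(the number of rectangles) is small.  The fit therefore includes the
exact boundary limit as a candidate, which enforces λ ≥ 0 by
construction, and the test suite measures the empirical type-I rate
under area-matching generators (≈4% at the nominal 5% criterion).
Area-matching generators drive fitted σ̃² into the upper grid region
with a vanishing likelihood gap — the signature seen in real
area-matchers, whose reported σ̃² estimates blow up.

Confidence intervals for σ̃²/σ̂² and η̃/η̂ come from a bootstrap
"virtual experiment": endpoints are resampled nonparametrically from the
non-timeout reaches; staircase responses are regenerated parametrically
from the psychometric curves fitted to the original data, with the
staircases re-run adaptively (not replaying the original radii); the
full fitting chain is repeated and 2.5/97.5 percentiles taken.  1000
replicates is the reference setting; simulation-heavy tests use fewer
(stated below).  This is a plug-in percentile bootstrap: it treats the
fitted psychometric curves as the truth when regenerating responses, so
its intervals are expected to run slightly narrow; the nested coverage
simulation in the test suite quantifies this (see Limitations).

## Motor lotteries and efficiency

The expected-gain simulation uses the classic two-circle reward/penalty
landscape: reward +100 in a green circle, penalty (−100 or −500) in a
red circle of the same radius 8.97 mm at center distance {1, 1.5, 2}×
radius; endpoints in the overlap collect both.  By symmetry the optimal
aim lies on the axis through the centers; the search is a coarse scan
plus bounded scalar refinement (well below 0.001 mm), verified against a
2-D grid in the tests.  Uniform-disk gain surfaces can be exactly flat
near the optimum (disk inside the reward circle, clear of the penalty);
ties break toward the smallest displacement from the green center.

Efficiency of an internal model is the true expected gain at the
model-optimal aim divided by the true maximum, averaged over conditions.
The default aggregation is the mean of per-condition ratios; a
ratio-of-means alternative is exposed as a flag, since either reading is
defensible for a single summary percentage.  The uniform-disk thought
experiment uses disk radius 8.1 mm, i.e. 2× the true per-axis SD of
4.05 mm, so the disk matches the Gaussian's per-axis SD (for a uniform
disk of radius R the per-axis SD is R/2).  Variance misestimation is
expressed as σ̃ = 2σ (4× variance) and σ̃ = σ/2 (1/4 variance).

## Synthetic-data generator: what it does and does not emulate

Defaults: σh = 4 mm, σv = 5.76 mm (η = 1.44, the typical vertical
elongation), ρ = 0, 5% timeouts, 300 or 600 training reaches per the
design, Weibull choice steepness γ = 4 (mid-range of plausible choice
consistency).  Timeout trials carry no endpoint and are excluded
upstream, mirroring the exclusion rule of the task.  One master seed
spawns independent named substreams (endpoints, choices, bootstrap), so
modules are testable in isolation and full runs are byte-reproducible.

The generator emulates the statistical structure the analysis assumes —
Gaussian endpoints, Weibull choice noise, stationary internal models.
It does not emulate trajectory kinematics, movement times beyond the
timeout flag, lapses, learning within a session, or display jitter
(presentation-only in the task).  Passing recovery tests therefore
demonstrates that the estimation chain is correct and well calibrated
under its own assumptions, not that real subjects satisfy them; the
distributional diagnostics (Q-Q linearity, F test) are the tools for
checking the assumptions on real data.

A feedback-task mode exposes a drift-rate knob (internal-model
parameters drifting toward truth per block, default 0 — i.e. off).  No
fitted learning rule is shipped: observed feedback effects identify no
specific rule, so the package provides the mechanism without inventing
dynamics.

## Numerical choices

- Quadratures: Gauss–Legendre, 128 nodes (512 when r/σh ∈ (10, 50],
  adaptive quadrature beyond); all hit probabilities agree with
  10⁷-draw Monte-Carlo oracles within 3 MC standard errors in the tests.
- Root finds: Brent on log radius, inscribed/circumscribed bracket.
- Sample SDs use the n−1 denominator.
- Q-Q "linearity" is operationalized as the correlation between sample
  and standard-normal quantiles (the original check was visual).
- The log base for staircase steps is log10 (conventional in adaptive
  psychophysics; configurable, since step sizes in "log units" do not
  fix the base).
- `EquivalentRadiusTable` tabulates log equivalent radii on a 60×33
  log-grid over (σ̃², η̃) and interpolates with bicubic splines;
  interpolation error (≲1e−4 log units in the fitting region) is far
  below the response-noise scale.  Tables are scale-equivariant
  (`ScaledTable`), so one table per design serves all subjects.
- Simulation scales in the test suite: classification rates use 100
  seeds per generator type; the nested bootstrap-coverage simulation
  uses 100 outer replicates at 200 bootstrap replicates each; the
  type-I calibration uses 1000 radius-level subjects.  These sizes give
  binomial noise well inside the asserted bands.

## Known limitations

- The percentile bootstrap is plug-in parametric for the choice stage
  and its CIs run slightly narrow: nested-simulation coverage sits near
  93–95% (vs the nominal 95%) at 200 bootstrap replicates, and degrades
  to ≈85–90% if the replicate count is cut to 100, where the percentile
  endpoints themselves get noisy.  This is a property of the procedure
  itself, faithfully implemented; BCa or double-bootstrap corrections
  are out of scope.
- The χ²(df=2) reference for the nested test is asymptotic and the null
  lies on a parameter boundary; the empirical type-I rate (~4%) is
  mildly conservative, which is the expected direction.
- η̃ becomes unidentifiable as σ̃² grows (the predicted radii of all
  rectangles converge to area radii); fits report η̃ in that regime but
  its CI will span the grid.
- Correlated-Gaussian circle probabilities are not implemented (the
  analysis never needs them; centered circles are rotation-insensitive
  only approximately when σh ≠ σv).
- The uniform-disk model's equivalent radius is ill-defined when the
  disk fits entirely inside the rectangle (any circle containing the
  disk ties); the root-find then returns the smallest tying radius.
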