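# Methods

This note documents the models implemented in `smtrack`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Synthetic data model

The generator (`smtrack.synthetic`) emulates sparse single-molecule imaging
of a DNA polymerase in exponentially growing *B. subtilis* together with a
replisome-marker channel.

**Cells** are ideal spherocylinders — a rectangle capped by two
semicircles — with Gaussian length and width (defaults 3.48 ± 0.4 μm and
0.695 ± 0.05 μm, matching typical measured cell dimensions), discretized to
≥ 48 vertices with the cap apices as explicit vertices so the poles lie on
the polygon.  Real segmented outlines are irregular; the idealization buys
exact analytic geometry (length, width, area, centerline) for testing, and
any outline with two pole landmarks can be substituted through the same
`CellOutline` type.

**Foci** (replisome markers) number 1 + Bernoulli(0.67) per cell (mean
1.67) and sit at the quarter and three-quarter long-axis positions on the
midline, with 0.12 μm Gaussian jitter, rejection-resampled into the
polygon.  A lone focus occupies one quarter position at random so the
population average stays bimodal.

**Molecules** draw a diffusive state from a configurable mixture (default
28% at 0.08, 25% at 0.23, 47% at 0.98 μm²/s — the static / intermediate /
fast decomposition typical of a clamp-interacting polymerase), keep it for
life, and perform 2D Brownian motion with per-axis step variance `2 D Δt`
and specular reflection at the polygon boundary.  Specular reflection
preserves the uniform stationary distribution, which the g(r) = 1 null
depends on.  State interconversion is deliberately absent: transition
kinetics are not a quantity any stage estimates, and a possible extension
rather than an assumption.

**Photophysics** is single-exponential bleaching (τ_bleach default 1.10 s)
quantized to whole frames (a track spanning `ceil(T/Δt)` frames), plus
Bernoulli blinking that removes interior frames only and never two in a
row, so gaps are at most one frame — matching what the linker is allowed to
bridge.  In long-exposure mode, bound molecules additionally carry a
dissociation clock (τ_bound default 1.9 s); the observed on-time is the
minimum of the two exponentials, which is exactly the rate-additivity
premise of the bleaching correction.  No triplet states, multi-step
bleaching, or chromatic offset (measured negligible, ~11 nm) are simulated.

**Localization noise** is additive Gaussian per axis; the short-exposure
default pair (26.5, 26.0) nm reproduces σ_xy = 37.1 nm, the long-exposure
pair (17.4, 18.1) nm gives 25.1 nm.  PSF widths are drawn per track
(Gaussian, mean 1.424 px, SD 0.3605 px — numbers chosen so the fixed-cell
calibration reproduces the 0.703–2.145 px static gate) with small
per-localization jitter; in long-exposure mode mobile molecules get widths
above the gate (mean 3.2 px, truncated at 2.3 px), emulating motion blur at
the fitted-width level rather than by sub-frame integration, because every
consumer of long-exposure data reads only the fitted width.

**Rendering** paints each visible localization as a symmetric 2D Gaussian
(peak 200 counts over a 100-count background, SNR ≈ 10 after shot noise)
onto a field with 106 nm pixels, applies Poisson noise, and adds the
2065-count EMCCD offset into a 16-bit image.  The pixel convention is
stated once and used everywhere: pixel (row i, col j) has its center at
`origin + ((j+0.5)·px, (i+0.5)·px)`.

What passing tests show — and do not.  Recovery on this generator
demonstrates the estimators are correct *given the model*: Brownian states,
Gaussian noise, exponential photophysics, ideal cell geometry.  Real data
add segmentation error, non-uniform background, overlapping emitters,
z-defocus, and state interconversion; results there inherit none of the
guarantees tested here.

## Detection and linking

Candidates are local maxima of a σ = 1 px smoothed image above a robust
(MAD-based) noise floor, inside the cell polygon.  Each candidate is fit in
a 9×9 window with a symmetric 2D Gaussian (amplitude, sub-pixel centroid,
width, background).  The keep/reject rule is a one-sided t-type test of the
fitted amplitude against its standard error from the fit's residuals and
Jacobian, at significance α (defaults 1e-5 short exposure, 1e-6 long
exposure).  On pure-noise images this yields false-positive counts that
fall monotonically with α and essentially no detections at 1e-5.  Focus
calling runs the same detector on an average projection (first 20 frames)
and additionally requires the fitted background to exceed the 2065-count
camera offset, suppressing off-cell false positives.  Fits with singular
curvature are discarded and logged.

Linking is an online optimal assignment: per frame, active tracks compete
for spots under a cost of squared displacement, solved as a bipartite
matching with birth/death options (deterministic and order-independent, in
contrast to greedy nearest-neighbor).  Each particle's search radius is
`5 × sqrt(4 D̂ Δframes)` pixels from its own running mean squared frame
displacement, clipped to configured bounds (new particles start at the
upper bound; 3 px upper bound in long-exposure mode); one-frame gaps are
bridged when allowed.  Tracks need ≥ 2 spots to exist and ≥ 5 localizations
to enter analysis.

## Calibrations

All three gates come from fixed-cell (all-static) data.  Gaussian fits to
distributions are least squares on a Freedman–Diaconis histogram of the
central peak with iterative |z| > 3 trimming — fixed-cell data carry a
small mobile tail (incomplete fixation), and trimming makes the fit
reproducible without a hand-drawn cut; results are insensitive to the
exact trim.

* **Precision**: per-track mean subtracted, pooled per-axis offsets fit
  with Gaussians; each track's offsets are rescaled by `√(m/(m−1))`
  because subtracting an m-point mean removes 1/m of the variance —
  without this, heavily bleached (short) tracks bias the precision low by
  ~10%.  σ_xy is the quadrature sum.
* **PSF gate**: Gaussian fit to per-track mean widths; window = mean ± 2 SD.
* **D\* threshold**: Gaussian fit to the fixed-cell D\* distribution;
  threshold = mean + 2 SD.  With the default noise this lands near 0.1
  μm²/s; the working default cutoff is 0.14 μm²/s, and classification uses
  a strict `D* < cutoff`.

## Diffusion analysis

MSD is the mean squared single-frame displacement; displacements spanning a
blinking gap are excluded from numerator and denominator rather than
rescaled, so the MSD never mixes timescales (a choice the data format
forces us to make explicit; rescaling by the doubled interval is the
plausible alternative).  `Δt` defaults to 14.7 ms — the frame-to-frame
clock including readout — not the 13.9 ms integration time, because the
displacement clock is frame spacing.  D\* requires ≥ 5 localizations and
truncates longer tracks to their first five, so all values follow the
exactly-four-step density; tracks with fewer than four valid steps after
gap exclusion are dropped from the mixture fit.

The mixture fit is least squares of the three-term density against a
histogram (bin width 0.05 μm²/s on [0, 3]; the fit is insensitive to the
binning, which a test checks).  The constraint is enforced by
parameterizing `A₃ = 1 − A₁ − A₂` with box constraints and a penalty
against negativity; several starts are tried and species are reported
sorted by D.  When two components converge onto one true species the split
between them is arbitrary — recovery claims are about the summed weight
near a given D.

The two-state jump-length fit consumes empirical CDFs (lags 1–4 frames, up
to 4 jumps per track per lag, truncation at 5.05 μm, 0.01 μm bins; tracks
of any length contribute).  Each state contributes
`1 − exp(−r²/(4(D·kΔt + σ_loc²)))`; the free state's weight at lag k is
scaled by an axial-retention factor `P_stay(D, kΔt)` — the probability a
molecule starting uniformly in a slab of depth dZ = 0.7 μm has not left it
— computed by Monte-Carlo with substepped absorbing boundaries and
tabulated over a log-spaced D grid per fit.  This replaces the published
polynomial approximation used by the original jump-length tool; equivalence
to that polynomial is not claimed, only the defining property (monotone in
lag and D, → 1 as dZ → ∞), which tests verify.  Optimization restarts from
three spread initializations within the D_bound ∈ [1e-4, 0.1],
D_free ∈ [0.5, 25] μm²/s boxes; solutions pinned at a bound are flagged.
Residuals are reported without a pass/fail goodness rule.

## Cell coordinates and profiles

One pole maps to (0, 0), the pole axis is rotated onto x, and coordinates
are divided by length and width with the short axis centered at v = 0.5.
Trajectories are reduced to their mean position first.  Pole labeling is
arbitrary, so long-axis results can be presented pole-folded
(u → min(u, 1−u)).  The short axis is normalized by the maximal width, so
points in the polar caps map strictly inside (0, 1) — accepted.  Nucleoid
profiles sample the pole-to-pole centerline at pixel pitch with
nearest-pixel rounding, normalize x by cell length, interpolate onto a
101-point grid (density unstated in the source analyses; 101 resolves
structure at the ~1% level), average across cells, and min-max normalize —
an idempotent operation, as a test checks.

## Radial distribution function

The experimental observable is the per-trajectory mean over localizations
of the distance to the nearest focus (the alternative reading — distance
from the trajectory's mean position — is available behind a switch, and
both are exercised in tests).  Each normalization repeat draws one uniform
point per trajectory inside the same cell outlines (matching counts
per cell), histograms both sets as densities (25 nm bins to 1 μm), and
ratios them; 100 repeats are averaged.  Two spread measures are stored:
`sem`, the SEM over the repeat curves (which quantifies only the
Monte-Carlo normalization noise), and `repeat_sd`, the SD over repeats,
which estimates the sampling noise of a single draw of this size and is
the correct yardstick for judging whether an experimental curve is
consistent with uniformity.  Bins whose random histogram is empty in some
repeats are averaged over the defined repeats and reported with
`n_defined`; the strict `valid` mask marks bins defined in every repeat.
An independent random–random control quantifies the finite-sample noise
floor; with n points per bin its 3σ band is `3/√n`.

## Binding lifetimes

Static molecules are selected by mean PSF width inside the closed gate
interval.  Durations are frames spanned × frame time; tracks shorter than
5 frames are excluded and the exponential fit is left-truncated at that
threshold, which by memorylessness isolates the long-timescale decay from
the short-lived contamination the duration distributions carry.  The
default estimator is the truncated MLE; because durations are quantized to
whole frames the counts are geometric and the MLE is
`τ = −Δ/ln(k̄/(1+k̄))` with k̄ the mean excess in frames — the naive mean
excess is biased low by ≈ Δ/2, which would propagate to a ~40% error in
the corrected lifetime at these timescales.  A histogram least-squares
alternative (one frame per bin) is available behind a switch and agrees
with the MLE within 5% on synthetic data.  The correction
`τ_bound = τ_app·τ_bleach/(τ_bleach − τ_app)` is the exact inverse of rate
composition (property-tested); `τ_app ≥ τ_bleach` is an error, signaling
miscalibration.  A fixed-cell bleaching estimate exceeding a fifth of the
observation window is flagged censored (the movie end, not bleaching, is
then terminating a non-negligible share of tracks).  Uncertainty is a
nonparametric bootstrap over tracks.

## Problem sizes and seeds

Simulated studies use sizes at which the estimators' sampling error is
comfortably inside the claimed recovery bands: 5000 four-step tracks for
the mixture fit, 10⁴ jumps per lag for the two-state fit, 200 cells × 10
trajectories with 100 repeats for g(r), 2000 fitted durations per arm for
lifetimes, and a 10-cell, 15-frame movie for the detection/linking oracle.
One master seed fans out through `numpy.random.SeedSequence` so modules
can be re-run independently; identical seeds give byte-identical outputs.

## Known limitations

Ideal cell geometry (no segmentation error); no emitter-overlap modeling in
detection (dense regions under-count); no state interconversion; no 3D PSF
or z-dependent width; the jump-length axial correction is Monte-Carlo
rather than the published polynomial; bleaching is strictly
single-exponential.  The D\* statistic conflates localization noise with
motion (E[D*] = σ²/Δt for an immobile molecule), which is exactly why the
fixed-cell threshold calibration exists.
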