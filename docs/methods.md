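# Methods

This note documents the models, estimators and numerical choices behind
`lysomech`, and what validation on the synthetic generators does and does
not establish about real data.

## Curvature–calcium coupling

**Boundary extraction.** Objects come in as integer label masks (0 =
background). The inclusion filter retains objects whose mean
membrane-marker intensity is strictly over 300 a.u. and whose size is
strictly over 200 pixels (both thresholds configurable; the mean was
chosen over the maximum for noise robustness). Interior holes are filled —
an organelle mask is a filled disk-like region, so holes are segmentation
noise. The ordered contour is produced by Moore-neighbor tracing with
Jacob's stopping criterion, restricted to pixels with at least one
4-neighbor outside the object, and normalized to counter-clockwise
orientation (positive shoelace area) so the interior lies to the left.
Objects smaller than 5 px, multi-component objects, and line-like objects
(no 2×2 solid block) are rejected with an error naming the object.

**Curvature estimator.** Signed Menger curvature: κ at point pᵢ is the
reciprocal circumradius of the circle through (pᵢ₋ₖ, pᵢ, pᵢ₊ₖ), k = 5
boundary steps by default, computed as 2·cross(d₁, d₂)/(|d₁||d₂||d₃|);
collinear triples give exactly 0, and the sign is positive where the
contour bulges outward. Before the circle fit, contour coordinates are
smoothed with a circular moving average (window 3 by default, odd, 1
disables). The smoothing matters: raw pixel contours carry half-pixel
lattice jitter that inflates the three-point circle estimate by ~16 % on a
20-px-radius digital circle, while with window 3 the median error on
circles of radius 10–40 px is 1–4 % and the curvature maximum at an
ellipse vertex (semi-axes 45/22.5 px) is recovered within ~8 %. Larger
smoothing windows flatten genuine curvature extrema (window 5 loses ~10 %
at the ellipse vertex), so 3 is the default; both window parameters are
exposed. κ is computed in px⁻¹ and converted to µm⁻¹ with the pixel size;
the correlation statistic is invariant to this unit choice.

**Sampling points and local intensities.** Only points with κ ≥ 0 (bulged
regions) are analyzed; points with κ exactly 0 are retained. At each
retained point a 5×5-pixel window (≈ 0.11 µm² at the default pixel size of
0.0663 µm/px, which is derived from that window-area figure and
overridable everywhere) is clipped at the image border and intersected
with the filled object mask, so only boundary and interior pixels
contribute — exterior background would dilute the membrane-proximal
signal. The normalized calcium intensity is the window mean of the calcium
channel divided by the window mean of the membrane channel, correcting for
local membrane density. Points whose window retains fewer than 6 eligible
pixels, or a non-positive membrane mean, are dropped with a logged count.

**Correlation statistic.** Per frame and object, the Pearson
product–moment correlation between κ and normalized calcium over the
retained sampling points (Spearman available behind a flag). Frames with
fewer than 3 points or zero variance in either variable yield an undefined
coefficient and are skipped, not zero-filled. The per-lysosome summary r̄
is the unweighted mean of defined per-frame coefficients; objects are
linked across frames by greedy nearest-centroid tracking (links beyond
max_displacement_px are refused; a one-frame gap ends the track — no gap
bridging or merge/split resolution). Known statistical limitation:
neighboring sampling points are spatially autocorrelated, so the effective
sample size per frame is smaller than the point count; the per-frame
coefficient is reported as-is, without autocorrelation correction, and no
causal or lagged structure is examined.

## Morphometrics

Area is pixel count × pixel size². Circularity 4πA/P² is computed
self-consistently on the outline polygon — the traced boundary smoothed
with a window-5 circular moving average — using that polygon's shoelace
area and segment length, and clamped at 1.0. A raw √2-weighted chain code
overshoots the perimeter of smooth shapes by ~5 % and depresses digital
disk circularity to ≈ 0.92, while smoothing the polygon relaxes the pixel
staircase toward the smooth outline the mask rasterizes: digital disks
score ≈ 1.00 and axis-aligned squares and rectangles stay within 0.04 of
their closed forms (π/4, 8π/36). Setting the window to 1 recovers the
plain chain-code convention.

Peripheral positioning: the cell mask is eroded with a disk structuring
element of radius shell_depth/pixel_size (an isotropic 5-µm inward offset
by default); the shell is the cell minus the erosion, and a lysosome is
peripheral when its centroid pixel falls in the shell (an any-overlap
variant is available; centroid was chosen as deterministic for large
organelles). A centroid outside the cell mask is an error, as is an empty
object list (the fraction is undefined, not 0). Colocalization is plain
Pearson over mask pixels with no thresholding or background correction.

## Calcium responders

F(t) = (raw(t) − bg)/(raw(0) − bg), with bg a scalar (e.g. the mean of a
background region) or a per-frame series; a non-positive denominator is an
error, and F(0) is exactly 1. A cell is a responder iff max F − 1 > 0.70
(strict), applied to the peak of the trace; no smoothing is applied before
classification by default. The classification is invariant to affine
camera gain. The fold-change generator shows the sharpness of the rule:
noise-free folds of 1.5 and 1.70 are negative, 2.0 positive, and with
noise, misclassification is confined to folds within a few noise standard
errors of 1.70.

## Pressure-clamp analysis

**Step amplitudes.** Each protocol step is a zero-pressure baseline window
followed by the pressure step (defaults 0.2 s and 0.5 s). The amplitude is
the mean over the last 50 % of the step minus the baseline mean — a
steady-state convention appropriate for slow, non-inactivating stretch
currents; a peak mode is available. Suction pressures are negative;
dose–response fits use |P|.

**Dose–response.** I(P) = I_max/(1 + exp((P₅₀ − |P|)/s)) by least squares
(two-state Boltzmann, the field convention for half-activation pressure);
a fit-free P₅₀ by linear interpolation at half-maximal amplitude is also
reported, along with a flag when the fitted P₅₀ falls outside the sampled
range. Initialization: I_max from the largest amplitude, P₅₀ from the
first half-crossing, s from a tenth of the pressure range. Degenerate
(all-equal) amplitudes and fewer than 4 distinct pressures are rejected.

**I–V.** The reversal potential is linearly interpolated between the
bracketing sign-change pair (exact zeros taken directly); the chord slope
across that pair is reported as the slope conductance. No sign change —
the non-permeant-cation case — raises a "no reversal in range" error
rather than extrapolating.

**Non-stationary noise analysis.** Per time sample, the ensemble mean I
and across-sweep variance σ² are formed (≥ 20 sweeps required); baseline
variance and baseline mean current from a pre-step window are subtracted.
Samples are pooled into 10 equal-count bins by mean current, and the
binomial parabola σ² = iI − I²/N is fit by least squares. One numerical
subtlety: the regression uses the within-bin means of I and I² as the two
regressors. Under the model the bin average of σ² is exactly linear in
those moments, whereas squaring the bin-mean current biases the quadratic
term (by ~14 % when the mean current sits at a few discrete step levels,
as in stepwise protocols). Ensembles with no gating variance, or a
variance–mean relation that is not a concave parabola through the origin,
are rejected. γ = i/(V_hold − E_rev) is reported in pS when both
potentials are supplied, and the apex identities I_apex = Ni/2,
σ²_max = Ni²/4 hold exactly on the fitted parabola.

## Synthetic generators

**Shapes** are star-convex polar curves r(θ) = r₀(1 + Σ aₖcos(kθ + φₖ))
about the centroid, with exact curvature from
κ = (r² + 2r′² − r r″)/(r² + r′²)^{3/2}; Σ|aₖ| < 1 guarantees positivity
and simplicity, and an exact parametric ellipse is provided separately.
Star-convexity trades generality for an analytic curvature oracle
(∮κ ds = 2π is verified on every accepted shape).

**Movies.** The label mask is the rasterized filled polygon; the membrane
channel fills the object at the membrane intensity; every object pixel's
calcium value is α + β·κ of its nearest analytic boundary point plus
Gaussian noise. The noise is drawn per contour block of 5 px arc length
rather than i.i.d. per pixel: the analysis averages intensities over a
5×5 window, and per-pixel noise would be attenuated by that averaging
while the curvature signal is not, so the realized point-wise correlation
would exceed the designed one. Matching the noise correlation length to
the sampling window preserves the designed correlation
ρ = β·sd(κ)/√(β²var(κ) + σ²) (computed over the κ ≥ 0 analysis
population) through the measurement chain.
`coupling_for_correlation` inverts this relation to build fixtures at a
requested ρ. Frame-to-frame variation is rigid drift; no topology changes,
photobleaching, PSF convolution or fission/fusion events are modeled.
Seeding: one master seed spawns one substream per frame, so extending a
movie never perturbs earlier frames, and changing the seed changes only
the noise.

**Gating currents** use a Boltzmann open probability in |P| and an
independent binomial draw of the open-channel count at every sample (the
fast-gating limit — no dwell-time correlation is modeled), so the ensemble
mean and variance are exactly Nip and Ni²p(1−p) + σ_noise² at every time
point. Default parameters: N = 100 channels, i = 0.1 pA, P₅₀ = 45 mmHg,
slope 6 mmHg, protocol −10…−80 mmHg in 10-mmHg steps of 500 ms — a
high-threshold, small-conductance mechanosensitive channel regime.
Simulations in the test suite run at 500–2000 Hz sampling; the generator's
default is 10 kHz, matching typical acquisition.

**What passing tests show.** Recovery on these fixtures demonstrates that
the estimators are correct for their generating models — linear
curvature-coupling with block-correlated noise, star-convex shapes, rigid
motion, binomial gating. Real recordings add segmentation error,
photophysics, organelle deformation, spatially structured noise and gating
kinetics, none of which the generators emulate; performance there is
bounded, not guaranteed, by these results.

## Problem sizes

Default validation runs use 2000 analytic points per shape, 50-frame
movies with ~175 retained sampling points per frame for coupling recovery,
100 replicates for noisy Boltzmann fits, and 200-sweep ensembles across 20
master seeds for noise-analysis recovery — sizes at which the measured
quantities are stable to a few percent.
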