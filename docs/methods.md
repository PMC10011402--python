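# Methods

## Line model and conventions

A *body line* is an ordered pair of cubic Bézier segments sharing a junction
point.  Positional continuity (C0) is required to an absolute tolerance of
1e-9 canvas units; tangent-direction continuity (G1) — anti-parallel handles
into and out of the junction within 1e-6 rad — is required by default and can
be waived per line.  Coordinates are y-up; signed curvature is positive for
a left (counter-clockwise) turn, so mirroring a line through a vertical axis
negates its curvature profile.  An S-shaped line is one whose signed
curvature changes sign exactly once.

Arc length is computed per segment by adaptive quadrature of ‖B′(t)‖
(relative tolerance 1e-8).  Curvature profiles sample κ at `n` positions
equally spaced in arc length over the whole two-segment line (default
n = 500; doubling n changes Histogram Difference entries of the body-line
family by under 2%).  Fitted lines are G1 but generally not G2, so κ can
jump at the junction; a profile sample landing exactly there records the
mean of the two one-sided values.  Inflections are located on a dense
(n = 1024) profile and refined by bisection to 1e-6 of the total length;
curvature magnitudes below 1e-9 of the profile maximum count as zero, so a
straight line has no inflections.

Mean absolute curvature (MAC) is the arc-length-weighted average of |κ|
(trapezoid rule on the profile).  It summarises how curvy a line is but not
*where* it curves, which is why line similarity uses the full curvature
histogram instead.

## Histogram Difference

All lines under comparison are profiled at the same sampling density and
binned on shared equal-width edges (default 20 bins) spanning the pooled
curvature range.  The pooled range is taken from high-resolution profiles
(≥ 4096 samples) so that the binning does not depend on the working sampling
density; out-of-range values are clipped into the end bins.  Frequencies are
scaled to percent (so HD ∈ [0, 200]) or kept as counts — the scale is always
explicit, never inferred.  With `absolute=True` the magnitudes |κ| are
binned, making the comparison invariant to left/right-facing presentation.
Nearest-candidate matches break ties toward the lower candidate index and
carry an explicit tie flag.  Every similarity matrix carries its binning
metadata (edges, scale, sampling density, absolute flag), because HD values
are only meaningful relative to a stated binning.

## Body-line fitting

`fit_sline` minimises Σ_k ‖B(t_k) − q_k‖² over the control points of a
two-segment G1 line whose endpoints interpolate the first and last contour
points (a body line spans a fixed anatomical extent).  The junction index —
the contour point where the two cubics meet — defaults to the sign change of
the smoothed discrete (three-point circumscribed-circle) curvature, i.e. the
inflection, so that each cubic fits a one-signed arc; it can be overridden.

The optimisation has three stages, each of which can only keep or lower the
residual (the reported `rms_history` is non-increasing):

1. *Alternation.*  Footpoint parameters start at normalized cumulative chord
   length.  Each round solves two linear least-squares problems — one with
   free junction handles to estimate the shared junction-tangent direction,
   one exactly G1 along that direction — and then refines each footpoint by
   at most five guarded Newton steps.  An alternative block step that
   re-corresponds the parameters by arc length on the current curve is taken
   whenever it fits better (contours are digitized nearly uniformly along
   the locus).
2. *Joint refinement.*  The alternation stalls in a flat valley: a
   one-parameter family of G1 cubic pairs traces nearly the same locus with
   different speed, and coordinate-wise updates cannot move along it.  A
   Levenberg–Marquardt pass over the nine geometric parameters (inner
   handles, junction, two junction-handle lengths, junction-tangent angle),
   with footpoints re-projected inside every residual evaluation, descends
   to the locus optimum.  On noise-free data this recovers the generating
   control points to ~1e-9 of the bounding-box diagonal.
3. *Identification.*  With noisy data the footpoint objective leaves the
   valley direction ill-determined.  Arc length along the locus is
   parameterization-invariant, so the data's per-segment arc fractions are
   estimated from the footpoints of the refined curve and the line is
   re-fitted with the correspondence pinned to those fractions.  The step is
   accepted unless it materially worsens the orthogonal fit.

**Identifiability caveat.**  When one segment is nearly straight (the body
lines' upper arc turns only ~14°), its two inner control points can slide
along the arc while changing the traced locus by ~5e-4 units per unit of
slide.  No estimator can pin such points from noisy locus data: at noise
σ = 0.5 on a height-300 line their individual errors reach tens of units
while every other control point is recovered to well under 1% of the
bounding-box diagonal and the locus itself stays within ~1 unit of the
truth.  Recovery is therefore summarised by the *median* over the eight
control-point errors, which tracks the identified majority; downstream
quantities (curvature histograms, HD) depend only on the locus and are
unaffected by the slide.  Convergence failure is reported via the
`converged` flag, never an exception.

## Split-plot ANOVA

`mixed_anova` handles one within-participant factor and one or two crossed
between-participant factors, participants nested in the between cells, one
observation per participant × within-level (incomplete participants are
dropped and listed).  Between-stratum sums of squares come from a Type III
(deviation-coded) decomposition of the participant means, scaled by the
number of within levels; within-stratum sums of squares from the same
decomposition of the participant-centred scores, whose within-factor terms
are orthogonal to participants in a balanced-within design.  On balanced
data the full decomposition is exact (total SS is conserved to 1e-8
relative) and matches both a definitional cell-means oracle and pingouin.

Sphericity is handled by the Greenhouse–Geisser epsilon estimated from the
pooled within-group covariance of the within-level scores (pingouin uses the
total covariance; the two differ only through between-group mean
differences).  Epsilon multiplies both degrees of freedom of every
within-stratum effect; corrected and uncorrected dfs are both reported.
Effect size is generalized eta squared with all error strata in the
denominator: η²_G = SS_effect / (SS_effect + SS_between-error +
SS_within-error), the standard definition for fully manipulated mixed
designs.  Degenerate inputs: an effect with zero SS reports F = 0, p = 1; a
zero-variance table additionally reports ε = 1.

Post-hoc contrasts are paired *t* tests on all C(k, 2) within-level pairs,
pooled across the between groups (the design collapses over them once no
interaction is present), with p_adj = min(1, p·C(k, 2)) and df = n − 1.

## Synthetic data: what it emulates, and what it does not

**S-line family.**  The real body lines were extracted from photographs not
bundled here, so the θ-to-geometry mapping is this package's own stand-in:
each line is two circular-arc-like Bézier segments joined G1 at the
inflection (junction at 35% of the height), the upper arc turning a fixed
14° and the lower arc 2θ + 14°, which realises a chord-deflection angle of
exactly θ at the junction.  Larger θ gives a deeper curve.  (The anatomical
angle is defined between thoracic spine and sacrum on photographs; for a
height-spanning abstract line, a chord-to-chord angle of 32–54° with the
anatomical orientation is geometrically infeasible, and nothing downstream
depends on the direction of the θ-to-depth mapping — only the order and
spacing of the family matter.)  Handle lengths are skewed (±0.4) so
curvature grades smoothly toward the junction, as fitted body lines do;
without that grading every histogram degenerates to two spikes and HD
saturates.  After construction the line is uniformly scaled so its
bounding-box height is exact (default 300 units).  Mean absolute curvature
is strictly increasing in θ over [20°, 70°].

**Reference family.**  The seven-member stand-in for the historical S-line
family shares the body-line construction and differs only in its deflection
grid (8°, 19°, 30°, 43.5°, 50°, 58°, 66°), chosen once so that member 1 is
nearly straight, MAC increases strictly with the index, and members 4 and 5
are the Histogram-Difference neighbours of the 44° and 49° body lines.  The
shared construction is deliberate: HD compares curvature *distributions*,
and structurally incommensurable families saturate the statistic at its
maximum.  The historical engraving's exact geometry is not reproduced.

**Contours.**  `sample_contour` places n points equally spaced in arc length
within each segment, one sample exactly on the junction (so a noise-free
contour is representable by the fitting model), plus isotropic Gaussian
noise.  Real digitized contours have correlated, anisotropic errors and
uneven spacing; fit-recovery results here are therefore best-case.

**Ratings.**  rating = stimulus mean + gender offset (women) + participant
intercept + participant × stimulus latent value + context noise, clipped to
the instrument scale.  Study-1 defaults: 918 raters (467 men), 0–10 scale,
stimulus means (5.45, 6.55, 7.35, 7.30, 6.50), gender offset +1.29 (grand
means 6.63 vs 7.92), SDs (0.50, 0.40, 0.30).  Study-2 defaults: 98 raters
(33 men), 1–100 scale, means (43, 52, 60, 59.8, 43.5), no gender or
direction effect, SDs (12, 10).  The SDs are calibrated to two published
constraints — the two rating contexts correlate at ρ > 0.68 per stimulus,
and fewer than 1% of draws hit the scale bounds (the generator warns when a
realization exceeds that) — which makes the noise smaller, and hence F and
η²_G larger, than in the real studies; a bounded-scale Gaussian model cannot
match the reported effect sizes and the clipping constraint simultaneously.
Passing tests show the qualitative effect structure is detected, not that
real effect magnitudes are reproduced.  Random streams are per participant
and per component, so enlarging the sample leaves existing participants'
rows byte-identical.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: 500-sample
curvature profiles with 20 bins; 100-point contours with noise σ ∈
{0, 0.5, 2} and 50–100 Monte-Carlo seeds for fit recovery; 20 seeds for the
end-to-end rating simulations at the full study sizes (918 and 98
participants).

## Known limitations

* HD depends on the binning; matching any externally reported HD table
  requires the original curves and binning, neither of which ships here.
* The ANOVA's unbalanced-data behaviour is Type III with deviation coding;
  other software may partition differently (pingouin agrees on balanced
  designs and to ~0.1% on the study-sized unbalanced ones).
* The ANOVA requires complete within-factor data per participant; missing
  cells drop the participant (listwise) rather than being imputed.
* The rating generator's additive Gaussian model understates the skew and
  heaping of real visual-analogue ratings.
* Contour extraction from photographs is out of scope; contours enter as
  ordered point lists.
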