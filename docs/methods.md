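# Methods

## Problem

Individual differences in face and car recognition ability correlate with
the cortical thickness (CT) of the face-selective fusiform region (rFFA2) in
opposite directions: face ability negatively, car ability positively. The
*opposite correlation effect* (OCE) folds this crossover into a single
statistic — face ability is multiplied by −1, summed with car ability, and
the composite is correlated with CT — so that a small two-group study can
test whether the crossover is attenuated in one group (here, an autism
group against typically developing controls). This package implements the
full analysis chain on synthetic data: laminar CT measurement from traced
cortical boundaries, behavioral aggregation, the OCE with its between-group
Fisher-z comparison, and the associated power analysis.

## Laminar profiling

Given superficial (gray–CSF) and deep (gray–white) boundary contours on a
slice, traces are drawn from every superficial point to its nearest deep
point and vice versa (duplicated endpoint pairs collapsed); an all-pairs
rule is available but produces oblique non-local traces on curved ribbons.
Intensity is sampled along each trace at 101 equally spaced normalized
depths by bilinear interpolation, with depth 0 fixed at the gray–CSF border
regardless of trace direction. A degree-4 polynomial is fitted by ordinary
least squares to the mean profile over all traces (pooled across slices for
a subject), and the two roots of its second derivative, when both lie
strictly inside (0, 1), partition total CT into superficial / middle / deep
compartments:

    sup = d1·CT,  mid = (d2 − d1)·CT,  deep = (1 − d2)·CT.

Total CT is the mean Euclidean trace length times the pixel size. The
reported total is the float sum of the three parts, so the partition
identity is exact. Degenerate fits — |c4| < 1e−12, complex roots, or fewer
than two interior roots — raise a "no admissible laminar split" error
carrying the root diagnostics rather than returning a spurious subdivision.

The quartic is a *summary*, not a segmentation: its inflection points track
intensity transitions only approximately, and the approximation quality
depends on the profile shape (see calibration below).

## Phantom generator

The ribbon phantom renders a horizontal cortical band (optional one-period
sinusoidal bend, amplitude `curvature` mm) on a 0.1875 mm pixel grid (the
reconstruction grid of the ultra-high-resolution acquisitions; the 0.194 mm
acquisition grid can be configured). Each pixel's normalized depth comes
from its signed perpendicular distance to the midline; expected intensity
is a piecewise-plateau function of depth with logistic partial-volume
transitions at the CSF border, the two internal laminar boundaries
(default depth fractions 1/3 and 2/3), and the WM border, plus i.i.d.
Gaussian noise. Ground-truth contours (midline offset ± half thickness
along the local normal) are stored with the image.

Default contrast is a monotone intensity ladder: CSF 200 > superficial 120
> middle 80 > deep 40 > WM 0 (arbitrary units; the analysis is invariant to
affine intensity maps). This choice is deliberate: for a symmetric
"dark middle band" profile the fitted quartic's inflections sit ≈0.065 depth
units *outside* the true transitions — a structural bias of the quartic
summary — whereas in the monotone family the bias can be zeroed exactly.
The four interface widths (0.019, 0.033, 0.021, 0.024 depth units) were
solved through the full rendered pipeline (pixel sampling and bilinear
interpolation contribute blur comparable to the widths themselves) so that
the quartic-inflection estimator is unbiased at the default geometry and
contrast. Away from that operating point the estimator re-acquires a bias
that grows with |thickness − 2.44 mm| (≤0.013 depth units across the
simulated cohort range 2.2–3.0 mm, ≈0.02 at 2.0 or 3.2 mm) and with
curvature (≈0.01 at 0.3 mm amplitude). Noise at SD 4 (5% of the CSF–GM
contrast) adds ≈0.004 SD per subject without bias. Passing recovery tests
therefore show the estimator is consistent with the generator's geometry
near the calibrated conditions — they do not show that quartic inflections
recover cytoarchitectonic boundaries in real tissue, where the profile
shape is unknown.

## Cohorts and behavior

Cohorts are drawn per group from a 4-variate normal over (face, car, novel,
thickness) with a specified correlation structure, validated positive
semi-definite at construction; thickness is rescaled to the group's
mean/SD (defaults 2.2 ± 0.25 mm TD, 2.7 ± 0.2 mm AUT, reflecting the
thicker-ribbon group difference the analysis is agnostic to). Default
targets: TD face −0.55, car +0.45, novel 0; AUT −0.05, +0.05, 0 (an
attenuated OCE of roughly the 0.1 scale the power analysis conservatively
assumes). Abilities are mutually uncorrelated by default, mirroring the
treatment of the two opposite correlations as independent effects.

Raw task scores, when needed, are simulated from the three latent
abilities: two tasks per category loading √0.7 on their latent, accuracy
tasks clipped to [0, 1], and the novel-object matching task generated as
binomial same/different counts from a latent d′ (scored with the 1/(2N)
extreme-rate correction). Aggregates are means of two pooled-sample
z-scores (sample SD); pooling across groups is essential — within-group
standardization would erase the group differences the comparisons test.
Group behavioral tests are one-tailed (controls > autism) pooled-variance
t-tests by default — the printed pair (t = 2.7, df ≈ 31, p = .006) is
consistent only with a directional pooled test — with Welch available, and
Bonferroni correction over the six tasks.

## OCE statistics

Per group, the OCE is the Pearson correlation of (car − face) with a CT
measure, p two-tailed from t with n−2 df; the difference-of-correlations
reading corr(car, CT) − corr(face, CT) is reported alongside. Group
differences use the Fisher transform: z = (atanh r₂ − atanh r₁)/SE,
SE = √(1/(n₁−3) + 1/(n₂−3)), reported as a normal deviate with the
comparison ordered group2 − group1 (autism minus control reproduces the
published negative signs). Regional specificity within a group uses
Williams' test for two dependent correlations sharing one variable
(df = n−3). The novel-object control is a first-order partial correlation
(closed form; df = n−3). Group spread differences use the Brown–Forsythe
variant of Levene's test (absolute deviations from the group median) with
η² from its one-way ANOVA decomposition; the median centering is a
robustness choice, as the exact originally-used variance test is not
identifiable from the published statistics alone.

## Power

Analytic power of the two-sided Fisher-z comparison is
Φ(|Δz|/SE − z_{α/2}) + Φ(−|Δz|/SE − z_{α/2}); required equal per-group n
starts from the closed form 2((z_{α/2}+z_power)/Δz)² + 3 and is finished by
integer search for the minimality contract. A vectorized Monte-Carlo
routine draws bivariate-normal cohorts and applies the same test.

The analytic formula is a large-sample approximation. Simulation shows its
error is real but small at the study's scale: at (r₁, r₂) = (0.946, 0.1)
with n = (17, 16) the Monte-Carlo power exceeds the analytic 0.9925 by
≈0.002 — larger than the binomial SE at 10⁴ simulations — and at n = 15
with opposite-sign correlations the gap reaches ≈0.035, driven by the bias
of atanh r̂ (≈ρ/2(n−1)) which cancels for same-sign pairs and accumulates
for opposite-sign ones. Analytic-vs-simulation agreement is therefore
asserted within two binomial SEs on same-sign grids at n ≥ 30, and as an
absolute 0.005 bound at the small-n study scenario. The empirical type-I
rate of the comparison at n = (17, 16) is ≈0.051 (10⁵ simulations).

Published power figures reproduced analytically: required n of 9 (OCE
0.946 vs 0.1) and 24 (0.752 vs 0.1) at 80% power, α = .05 two-sided;
achieved power 99% / 22% / 62% for OCEs 0.946 / 0.506 / 0.752 at
n = (17, 16). For the superficial/middle sample sizes the analytic formula
gives 79 and 99 against published 77 and 97 (and 18% vs 19% for the middle
power level) — consistent with the original figures coming from a
simulation-based tool; these are documented, not asserted.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.default_rng` seeded explicitly;
a run's global seed spawns per-stage child seeds via `SeedSequence`, and
every output CSV records the seed and a hash of the scientific
configuration. Test-suite simulation sizes are chosen to make each check
sharp at desk scale: cohort-consistency checks at n = 10⁴ (±0.03 band),
null calibration at 2 000 simulated cohort pairs, power grids at 4 000–10⁴
simulations, phantom recovery on single slices of 64×≈40 px.

## Known limitations

- The quartic-inflection estimator is calibrated, not universally
  consistent: recovery of arbitrary layer fractions or contrasts within
  ±0.02 is not attainable with a degree-4 summary, and the phantom does not
  emulate veins, bias fields, or through-plane partial volume.
- The phantom is 2-D; no k-space/susceptibility physics, no multi-slice
  co-registration error.
- Cohort simulation draws ability composites directly from the target
  correlation structure; measurement error in the behavioral tasks is
  modeled only in the optional raw-score generator.
- The Fisher-z power analysis assumes bivariate normality and independent
  groups; no power analysis is provided for the dependent-correlation
  (Williams) comparisons.
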