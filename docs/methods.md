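# Methods

This note documents the models, numerical choices and known limitations of
`vaelab`. It is the package's own account of its science; every empirical
number quoted here is computed by the test suite or the examples.

## Paradigm model

A *block* is one cell of the design (fixation condition × adaptation
duration × disparity) and contains four cycles of adaptation phase + test
phase. One adaptation pass presents 5 repetitions (500 ms stimulus + 300 ms
ISI) at each of 7 visual azimuths with a 1 s inter-set interval, counted
after every set including the last: 7 × (5 × 0.8 + 1.0) s = 35 s per pass,
so 1–4 passes give 35/70/105/140 s. This "last interval counted" convention
is forced by the printed durations and is the only timing arithmetic that
reproduces them.

Auditory positions are always head-centred. The condition rules are:

| condition | fixation | auditory azimuth |
|---|---|---|
| eye+head-consistent | 0° | visual + offset |
| eye-consistent | at visual | 0° + offset |
| head-consistent | at visual | visual + offset |
| variable-disparity | 0° | visual + offset, offset drawn per set |

The *disparity profile* of a sequence is the per-event difference between
the head-centred auditory azimuth and the visual position expressed in a
chosen frame (head frame: the visual azimuth; eye frame: visual −
fixation). Each condition is "consistent" (single-valued profile at the
block offset) in its nominal frame and smeared uniformly over
offset ± {0, 10, 20, 30}° in the other; the variable-disparity condition is
smeared identically in both, which is exactly the structure it exists to
reproduce.

Test-phase azimuths are drawn uniformly **with replacement** from the
13-value ±30° grid, independently per test phase; nothing in the design
description implies balancing within a 10-trial phase, and the per-cycle
analyses assume none. The 10 s inter-cycle countdown and ≥1 min inter-block
break are carried as schedule metadata only. Degenerate requests (0 passes,
unknown condition, off-grid disparity) raise immediately rather than
returning empty schedules.

## Stimulus synthesis and spatialization

*Pink noise.* White Gaussian noise is shaped in the frequency domain by
1/√f (power ∝ 1/f) with brick-wall limits at 100 and 4000 Hz, then
RMS-normalized. The averaged Welch spectrum of many realizations has an
in-band slope of −10 dB/decade (tested at ±1.5) with <1% out-of-band power.

*Amplitude modulation.* The 3 dB depth is interpreted as the
peak-to-trough ratio of a linear-amplitude sinusoidal envelope:
env(t) ∈ [10^(−3/20), 1], so 20·log₁₀(max/min) = 3 dB exactly. The
alternative reading (a sinusoid in dB) differs negligibly at this depth and
is not used.

*Gating.* 25 ms raised-cosine half-windows; ramp length in samples is
`round(0.025 × fs)` (1103 at 44.1 kHz).

*Room model.* The image-source method is applied in 2-D (floor plan only):
the description specifies room width/depth and planar listener/source
geometry, so no floor/ceiling reflections are modelled. Images of a source
at (x, y) in a W × D room form the lattice (±x + 2mW, ±y + 2nD) with
reflection count |2m − p_x| + |2n − p_y|; all images with count ≤ 5 are
kept. Each image contributes one pulse with delay = distance/c (c fixed at
343 m/s) and amplitude = r^order / distance, where the pressure reflection
coefficient is r = √(1 − a) for energy absorbance a — hence r = 0 and a
direct-path-only response at a = 1, and impulse-response energy is monotone
non-increasing in a. Pulses are placed by nearest-sample rounding at
44.1 kHz (≤ 11 µs timing error); no fractional-delay interpolation or
band-limiting is applied to individual pulses.

One geometric caveat: with the default geometry (4.2 m width, 2.5 m source
arc, listener on the mid-line) the arc leaves the room beyond ≈57°
azimuth. Source positions are therefore validated per request; all azimuths
the paradigm actually uses (±50° at most, adaptation events in the
variable-disparity condition) lie inside the room.

*Binaural rendering.* The built-in spherical-head HRIR uses the Woodworth
ITD τ(θ) = (a/c)(θ + sin θ) with head radius a = 8.75 cm (≈0.66 ms at 90°)
and a first-order low-pass head shadow on the contralateral ear whose corner
frequency drops with incidence angle. The shadow filter is applied
zero-phase (magnitude only) so that the interaural lag is carried entirely
by the ITD term; the anechoic cross-correlation lag between ears then equals
the Woodworth ITD to within one sample. Spatialization convolves
wave ⊛ room IR ⊛ HRIR per ear, using the *same-azimuth* HRIR for all
reflections — the room IR and the direction-dependent filter factorize, as
in a "reverberant HRTF" constructed once per azimuth. Loaders accept
measured HRIR sets of arbitrary length from per-azimuth stereo WAVs or SOFA
files; no measured set is bundled. Output levels are normalized to 0.9 peak
full scale; free-field calibration in dB(A) is out of numerical scope.

## Observer model

Responses to a test stimulus at azimuth *a* in a block with disparity Δ,
duration T and fixation condition c are

    r = g·a + b − sign(Δ) · (M_c / 2) · (1 − exp(−T / τ_c)) + ε,  ε ~ N(0, σ²),

with probability p_out replaced by a uniform draw over the outlier range.
The exponential saturation is a modelling choice: the phenomenon is known
to approach saturation within the durations used, but no functional form is
established, and the time constant τ_c is not identifiable from four
durations with realistic noise — it is a generative device, not an
estimand. The shift is constant across test azimuths (no gain change), no
inter-cycle carryover or within-phase decay is modelled, and the −20 > +20
intercept contrast converges to M_c(1 − e^{−T/τ_c}) by construction, which
is what makes exact recovery checks possible.

Default population parameters (means, with between-participant jitter SDs
in parentheses): gain 0.9 (0.08), bias 0° (2°), σ = 5°, p_out = 0.02 over
±90°, asymptote contrasts M_c = 6° for eye+head-consistent and 4° for the
others (1.5°), τ_c = 40 s for eye+head-consistent and variable-disparity,
60 s otherwise (10 s). These are plausible magnitudes for this class of
paradigm — a response gain slightly below 1, localization scatter of a few
degrees, aftereffects of a few degrees that are larger when both frames are
consistent — and are **not** estimates of any measured dataset. What passing
tests show is that the pipeline recovers whatever structure the generator
plants at these noise levels; they cannot show that real observers obey the
linear/exponential model.

## First-level analysis

Outlier screening operates on the bivariate (stimulus, response) points of
one participant × condition cell: minimum-covariance-determinant location
and scatter (subset fraction h = ⌈0.75 n⌉) give robust squared Mahalanobis
distances, thresholded at the χ² quantile with 2 df at 1 − α (α = .01
default). MCD is the standard robust-distance estimator for this screening
role; on a singular robust scatter the classical covariance is used with a
warning, and if that is singular too nothing is rejected. Because the
FastMCD subset search is row-order dependent, trials are sorted into a
canonical order first, making the pipeline invariant to trial order. On
clean Gaussian data the empirical rejection rate at α = .01 is ~1–2%
(robust distances are slightly liberal in the tails); contamination at rate
p is rejected at ≈ p.

Bias and gain are the intercept and slope of per-cell OLS (response on
stimulus azimuth) with closed-form standard errors. Cells need ≥3 kept
trials and ≥2 distinct azimuths; rank-deficient cells raise an error naming
the cell. The VAE magnitude is bias(−20°) − bias(+20°), positive when
perception recalibrates toward the visual offset; the gain change is the
same contrast of slopes. A cycle filter restricts the pipeline to one
adapt/test cycle for per-cycle re-analysis without extra machinery.

## Second-level analysis

*ANOVA.* The two-way repeated-measures ANOVA uses the full balanced SS
decomposition with each effect tested against its own subject × effect
interaction error. Greenhouse-Geisser ε is computed per effect from the
contrast-projected between-subject covariance — an orthonormal contrast
basis C for the effect (Kronecker product for the interaction) gives
ε = tr(CSC′)² / (d·tr((CSC′)²)) — which reproduces R's `car` values exactly
on shared fixtures, including the interaction ε where simpler
collapsed-covariance approximations disagree. ηP² = SS_eff/(SS_eff +
SS_err); ηG² follows the Olejnik–Algina/Bakeman formulation with all
factors treated as manipulated (all subject-variance terms in the
denominator). The mixed-design ANOVA uses the split-plot decomposition
(between effect against subjects-within-groups; within effects
GG-corrected with the pooled within-group covariance) and supports unequal
group sizes. Missing cells are an error — the designs are complete, and
imputation would silently change the estimand.

*Trend contrasts.* Orthogonal polynomial coefficients over the (equally
spaced) duration levels — (−3,−1,1,3)-proportional for the linear trend at
k = 4 — are tested against the pooled subject × duration interaction error
with df = (k−1)(n−1); the pooled error term is inferred from the reported
degrees of freedom of the analysis this mirrors.

*Effect sizes and Bayes factors.* d_z = mean(diff)/SD(diff);
g_av = mean(diff)/mean(SD₁, SD₂) with the exact small-sample correction
J(df) = Γ(df/2)/(√(df/2)·Γ((df−1)/2)) at df = 2(n−1). The JZS Bayes factor
uses the default Cauchy prior (scale √2/2) on the standardized effect and
evaluates the one-dimensional g-mixture integral by adaptive quadrature; an
independent route (marginalizing the noncentral-t likelihood over the
Cauchy prior directly) agrees to <0.1%, as does pingouin. Bayes factors for
ANOVA effects (multi-effect g-prior models) are deliberately not provided —
only t-test BFs — since they require a different model family.

*Power.* Exact two-tailed power from the noncentral t distribution
(noncentrality d_z√n, df = n−1); the minimum-n search is a simple upward
scan. The repeated-measures-ANOVA sample-size figure that software such as
G*Power produces depends on unstated convention choices (assumed
correlation among repeated measures, nonsphericity, effect-size mode) and
is therefore not computed here.

## Problem sizes and calibration checks

The test suite calibrates the type-I error of both ANOVA engines on 2000
null simulations each (uncorrected p on iid — hence spherical — data, where
the F test is exact; the GG-corrected p is separately checked to be ≥ the
uncorrected one, i.e. conservative under estimated ε). End-to-end recovery
uses one 20-participant cohort at σ = 5° (gain within ±0.05, bias within
±1°, each condition's generative contrast within the across-participant 95%
CI) and 60 replicate cohorts for the null-interaction rejection rate, with
per-replicate outlier machinery disabled for the null calibration since no
contamination is generated. These sizes give comfortably informative checks
while keeping the default suite quick to run.

## Known limitations

- The spherical-head HRIR is a parametric stand-in: it carries correct ITD
  and plausible ILD but no pinna spectral cues, so it supports azimuth
  arithmetic and binaural-cue tests, not perceptual validation.
- The room model is planar and omits floor/ceiling reflections and
  frequency-dependent wall absorption.
- The observer is linear with additive shift; real response distributions
  (edge effects at the response range, motor noise, lapses structured in
  time) are richer than the Gaussian + uniform mixture.
- First-level fits are per-cell OLS; a mixed-effects variant pooling across
  participants is out of scope.
- Statistical routines assume complete balanced designs (the mixed ANOVA
  tolerates unequal group sizes only).
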