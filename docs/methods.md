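# Methods

## Reference table and trait classification

The measurement model assumes the IgG-Fc N-glycan electropherogram resolves
22 peaks carrying 29 structures.  Trait classification operates on the
modified Oxford grammar `F? A{1,2} B? ([3|6]G1 | G2)? S{1,2}?` with the
structural constraints galactoses ≤ antennae and sialic acids ≤ galactoses.
Biantennary structures are classed by galactose count (G0/G1/G2, sialylation
not affecting the class); monoantennary structures fall outside the scheme
and are classed `other`.  With the shipped roster this makes the G0 and G1
member sets exactly the four agalactosylated and ten monogalactosylated
structures of the trait formulas.

The four agalactosylated and ten monogalactosylated members are fixed by the
trait definitions; the identity of the remaining 15 structures is a package
choice: twelve digalactosylated biantennary forms (F/B variants × S0/S1/S2)
and three monoantennary forms (A1, FA1, A1B).  Comigration is expressed by
listing several structures per peak, dominant first; a peak's
galactosylation type is always that of its dominant structure, with no
quantitative comigration threshold.

GU positions are package defaults in the 4–12 range typical of APTS-labeled
biantennary IgG glycans, strictly increasing, minimum spacing 0.3 GU;
sialylated species elute earliest (reversed-polarity CE), then neutral
structures by size.  Only internal consistency between renderer and
annotator matters for correctness, which is what the round-trip tests
check; the table is overridable (and serializable as CSV) for instruments
with different effective mobilities.  The matching tolerance defaults to
0.1 GU, below half the minimum inter-peak spacing, so nearest-neighbour
assignment is unambiguous by construction.

## Trace processing

* **Baseline**: rolling minimum followed by box smoothing, window 0.75 min
  (≈5× the widest expected peak).  Because a minimum filter sits below the
  mean noise level, the valley level of the corrected trace is re-centred at
  zero (median of sub-5σ samples) before integration; otherwise every peak
  area would inherit a positive bias proportional to its width.
* **Noise**: robust SD from the 25th percentile of absolute successive
  differences (scaled for half-normality).  A low quantile is used rather
  than the median because in a crowded trace a large fraction of successive
  differences lies on peak flanks.
* **Detection**: local maxima with height and prominence ≥ `min_snr` (default
  5) × noise, plus a relative height floor (default 0.2% of the tallest
  peak).
* **Integration**: trapezoid rule over apex ± 4.5 σ̂ (σ̂ from the measured
  FWHM), clipped at midpoints between adjacent apexes.  For resolved
  Gaussian peaks this captures >99.97% of the area and is robust to noise
  dips that defeat valley-walking boundary rules.
* **Migration-time normalization**: all apex times are rescaled so the
  co-injected APTS-maltose internal standard lands at its reference time
  (10.38 min in the package's nominal separation — a config default; no
  published value exists).  This exactly undoes any run-wide multiplicative
  mobility drift.
* **GU calibration**: monotone piecewise-linear interpolation through the
  detected dextran-ladder peaks (DP 2–15 by default), giving knot exactness
  by construction; edge segments continue linearly outside the ladder span.
  Piecewise-linear was chosen over splines because monotonicity is
  guaranteed rather than hoped for, and the ladder is dense enough (1 GU
  spacing) that interpolation error is ≪ the 0.1 GU matching tolerance.
* **Relative intensities**: each assigned peak's area over the summed area of
  assigned peaks.  By default unassigned peaks are excluded from the
  denominator (the profile describes the annotated 22-peak set); a flag
  includes them, reporting the unassigned mass separately.

Degenerate inputs behave conservatively: flat or all-noise traces yield an
empty peak list (not an error); a profile with no assigned peaks is an
error; a subject with G1 = 0 gets an undefined (NaN, flagged) ratio rather
than infinity and is excluded from ratio-based statistics.

## Statistics

Group comparisons are nonparametric: Mann-Whitney U (exact null distribution
for small untied samples, tie-corrected normal approximation otherwise) and
Kruskal-Wallis with Dunn's post hoc z tests on pooled mid-ranks, pairwise p
multiplied by the number of comparisons.  "Correlation with disease
activity" is operationalized as the OLS slope of the trait on the activity
marker with HC3 robust standard errors; heterogeneity between two strata is
the robust Wald test of the activity × stratum interaction, with per-stratum
slopes and 95% CIs derived from the joint fit.  Covariate-adjusted group
contrasts use a linear model of the trait on group indicators plus age and
sex (optionally CRP); a logistic variant (group membership on trait plus
covariates) is provided because published phrasing is compatible with either
model family.  Missing data are handled complete-case per analysis, with
dropped-row counts reported.  The Bonferroni correction for the
pre-specified family of 12 secondary hypotheses is `min(1, 12p)`; corrected
results carry a flag so the correction cannot be applied twice.

Stratification bins follow the printed labels: age bins are right-closed
(≤25, 25–45, 45–65, >65; age 45 → "25–45"), CRP bins are left-closed
([0,5), [5,10), [10,15), [15,∞) mg/L; CRP 5.0 → "5–10"), and
disease-duration quartiles cut at the sample 25/50/75 percentiles,
right-closed.

## Synthetic data

The generator defines the study conditions: three presets transcribe the
published baseline characteristics — RA (n = 178, age 55.0 ± 12.4, 78.3%
female, CRP mean 19.4 ± 30.6 mg/L as a gamma model, ACPA 53.9%, RF 76.4%,
SE 53.9%, sulfasalazine 47/178, ratio median 1.25, IQR 1.09–1.56), axSpA
(n = 126, age 44.3 ± 8.4, 65.1% female, CRP 5.8 ± 10.3, HLA-B27 69.8%,
AS/nr-axSpA 64/62, ratio 0.89, IQR 0.79–1.09) and HC (n = 119, age
55.2 ± 13.5, 78.2% female, no CRP, ratio 0.95, IQR 0.77–1.13).  RA disease
duration is drawn by quantile interpolation through the printed quartile
medians (0.5, 2.6, 7.6, 16.6 years); axSpA duration is log-normal matched to
its median/IQR.  Five RA subjects are masked on CRP/DAS28/ESR, mirroring the
173/178 availability of activity markers.

`log(G0/G1)` is a linear predictor — age slope 0.006/yr in all cohorts; CRP
slope 0.006 per mg/L in RA (steeper by +0.002 in SE carriers, shallower by
−0.002 in RF positives, matching the direction of the reported slope
heterogeneity), 0.001 in axSpA, absent in HC; ACPA +0.07, SE +0.03,
sulfasalazine −0.11 — plus Gaussian residual.  Because CRP and serostatus
enter asymmetrically, the intercept and residual SD are solved numerically
at preset-calibration time (40 000 systematic draws under a fixed internal
seed, bisection on the residual SD) so the *population* median and IQR of
the ratio equal the preset targets; a preset whose systematic spread already
exceeds the target IQR is rejected as infeasible (negative residual
variance).  Effect magnitudes not printed anywhere (slopes, log-scale
offsets) are package defaults chosen to match the direction and rough size
of the reported subgroup medians; they are defined once, as part of the
study conditions, not tuned.

Each subject's (ratio, G0%) pair is realized exactly on the 22-peak vector
by class-wise tilting of the healthy base composition (G0 peaks scaled to
the target G0 sum, G1 peaks to G0/ratio, all remaining peaks rescaled to the
leftover mass), so `compute_traits ∘ compose_profile` is the identity to
1e-6.  The per-subject G0+G1 share is drawn around cohort-level values
(0.747 RA / 0.690 axSpA / 0.727 HC, SD 0.02) implied by the published
median ratio and G0% pairs; the healthy default composition carries
G0+G1 = 71.8%.

The renderer draws Gaussian peaks (σ = 0.015 + 0.0015·t min, widths growing
with migration time) at the times implied by a gently nonlinear true
migration model t(GU) = 8.0 + 1.15·GU + 0.02·GU², together with the maltose
standard (25% of total glycan area) and the DP 2–15 ladder on a second
channel; white noise is scaled so the smallest rendered peak attains a
target SNR, a shared multiplicative drift (SD 1%) affects both channels,
and a slow linear + sinusoidal baseline drift rides on the noise.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: instrument-specific peak asymmetry (tailing),
comigration-ratio variation within a peak (the dominant structure is
rendered as the whole peak), within-subject technical replicate variance,
IgG-subclass heterogeneity, ELISA titers beyond binary serostatus, and any
longitudinal structure.  Recovery results certify the pipeline's numerics,
not the biology.

## Problem sizes and numerical choices

End-to-end recovery is assessed at SNR ≥ 50 with traces sampled at 8 ms,
where trait recovery is within 0.5% relative error.  The acceptance script
uses 50 cohort realizations per preset (Monte-Carlo SE of the reported means
≈ 0.004–0.005 on the ratio scale); the in-suite version of the same check
uses 3 seeds per cohort with correspondingly wider tolerance.  Calibration
checks use 2000 null simulations for the heterogeneity test size (accepted
band 0.035–0.065 at nominal 0.05) and 100 replications for CI coverage.
Sample-median estimates at cohort size n ≈ 120–180 carry a small negative
finite-sample bias on the right-skewed ratio scale (≈0.8% at n = 119),
visible in recovery comparisons and inherent to the estimand, not a
pipeline artifact.

## Known limitations

* The 15 non-G0/G1 structures and all GU positions are plausible defaults,
  not measured assignments; results depending on G2/sialylation traits are
  conditional on that choice.
* Dunn's adjustment is Bonferroni-style (conservative) rather than
  rank-based stepdown.
* The logistic adjusted-comparison variant is a documented alternative, not
  the primary model; the two need not agree at small n.
* The renderer's symmetric Gaussian peaks make integration easier than on
  real CE traces with tailing; detector saturation is not modeled.
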