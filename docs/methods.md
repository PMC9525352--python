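# Methods

## Scope

`dntbattery` implements the hazard-characterization arithmetic of a human
cell-based developmental-neurotoxicity (DNT) in vitro testing battery:
concentration-response fitting and benchmark-concentration (BMC) estimation,
specificity classification of DNT effects against viability/cytotoxicity,
most-sensitive-endpoint (MSE) determination, ToxPi-style potency scaling with
a merged MSE + ToxPi prioritization, and crude exposure-margin calculations
from biomonitoring data.  Wet-lab acquisition, image quantification and
transcriptomics are out of scope; the package starts from plate-level well
values and ends at ranked hazard summaries.

## Concentration-response models

All responses are percent of solvent control (an unaffected well sits at
100).  Two model families are fitted to replicate-level wells against log10
concentration; the solvent control (c = 0) is used only for normalization and
never enters the fit.

**Variable-slope sigmoid (4PL).**

    y(c) = bottom + (top - bottom) / (1 + 10^((log10 EC50 - log10 c) * h))

The sign of the Hill coefficient h carries the orientation (h < 0 falls with
concentration); after fitting, parameters are normalized so that
top >= bottom.  Starting values are tried with both orientations and the
lower residual sum of squares wins.

**Bell (biphasic).**  Some endpoints rise above the control level at low
concentrations and fall below it at higher ones (e.g. a transient induction
of oligodendrocyte differentiation followed by suppression).  A product of
two sigmoids cannot represent this shape — it returns to the same baseline at
both concentration extremes — so the bell is parameterized as a sum of two
logistic transitions anchored at the control level:

    y(c) = 100 + (top - 100) * U(c; EC50_1, h1) + (bottom - top) * U(c; EC50_2, h2)

with U a rising unit logistic and both Hill coefficients positive.  For
c -> 0 the curve evaluates to 100 (the anchor is fixed by the
percent-of-control normalization, which removes one free parameter and
stabilizes the 6-parameter fit); between well-separated half-maximal points
it plateaus near `top`, and at high concentrations it approaches `bottom`,
which may lie below 100.

**Model selection** is by AICc over converged fits (k = number of curve
parameters + 1 for the residual variance), with exact ties resolved toward
the sigmoid.  Optimizer failure is reported as `converged = False`, never an
exception; flat data converge to top ≈ bottom and simply yield a censored
BMC downstream.

## Benchmark concentrations

The BMC at benchmark response b (the BMR, in percent of control) is the
lowest concentration at which the fitted curve deviates from 100 by at least
b points in the adverse direction — below `100 - b` for decrease-adverse
endpoints, above `100 + b` for increase-adverse ones, whichever comes first
for `both`.  Deviation is measured from the control level, not from the
fitted top plateau.  For the sigmoid the crossing is solved in closed form;
for the bell each limb is bracketed on a log grid and refined with Brent's
method to ~1e-13 relative tolerance.  A curve that never reaches the
threshold at or below the highest tested concentration is *censored* — a
valid outcome, not an error — and carries no confidence interval.

Default BMRs follow the battery conventions: 20% for neurosphere (NPC)
endpoints, 25% for the UKN neurite/migration endpoints, 10% for the UKN2
viability reference.  All are configuration, not code, because per-endpoint
BMRs are calibrated to assay variability and may legitimately differ between
laboratories.

## Bootstrap confidence intervals

CIs come from a nonparametric bootstrap that resamples replicate wells
within each concentration group — *including the solvent-control group*:
each resample redraws the control wells and renormalizes, so the uncertainty
of the control mean (≈ 2.2% with five wells at 5% noise) propagates into the
BMC.  Omitting this term visibly undercovers (≈ 82% instead of ≈ 90% in the
package's own calibration experiment).

Because groups are small (3-5 wells), plain with-replacement resampling
underestimates the variance of each group mean by the factor (n-1)/n.  The
resampled deviations from the original group mean are therefore inflated by
sqrt(n/(n-1)) before refitting — the standard finite-sample scale correction
— restoring Var(mean*) = s^2/n.  The interval is the 2.5/97.5 percentile
band of the bootstrap BMC distribution, widened if necessary to include the
point estimate.  Refits are warm-started at the full-data parameters; a
resample whose refit fails or censors is dropped, and when more than half
are lost the CI is flagged unreliable.  Fixed seeds make the CI exactly
reproducible; noise-free series short-circuit to a degenerate interval equal
to the point estimate.

At the study's operating conditions (7-point 1:3 dilution from 20 µM, five
replicates, 5% well noise, 200 resamples) the package's calibration
experiment over 200 simulated screens gives a median absolute log10 BMC
error of ≈ 0.025 and CI coverage of ≈ 90-92%.  Percentile intervals from
small per-group samples remain slightly anticonservative; profile-likelihood
or BCa intervals were evaluated and brought no material gain here.

## Specificity classification

NPC-family endpoints are classified by the overlap of the DNT endpoint's BMC
CI with those of its paired viability/cytotoxicity references:

* no overlap -> **specific**;
* overlap >= 10% -> **unspecific**;
* strictly between -> **borderline**.

The overlap fraction is the intersection length divided by the DNT
interval's length (configurable to the reference or the shorter interval):
the question being asked is whether the DNT effect is explainable by
cytotoxicity within the DNT effect's own concentration range.  Multiple
references (e.g. CTB plus LDH) combine worst-case — the largest overlap
decides — and migration endpoints can be configured LDH-only.  The 10%
boundary is inclusive on the unspecific side.

UKN-family endpoints instead use the ratio of point BMCs,
viability BMC / endpoint BMC, with inclusive cutoffs 1.3 (UKN2 migration),
4 (UKN4 neurite area) and 3 (UKN5 neurite area); at or above the cutoff the
hit is specific, below it unspecific.  No borderline category exists for
these assays.  A censored endpoint BMC is `no_hit` in either family; a
censored viability BMC makes the ratio effectively infinite (specific).

**Degenerate-CI fallback.**  On noise-free data the bootstrap collapses
every CI to a point and interval overlap becomes uninformative (two distinct
points never overlap, so everything would be called specific).  When the DNT
and all active reference CIs are degenerate, classification falls back to
the viability/DNT BMC ratio: <= 1 unspecific, >= 3 specific (3-fold being
the battery's own similarity range), in between borderline.  The call
records which basis produced it (`ci_overlap` vs `viability_ratio`).

**MSE.**  A compound's most sensitive endpoint is the lowest BMC among its
*specific* hits (unspecific or borderline BMCs never win), with lexicographic
endpoint order as the documented tie-break; a compound with no specific hit
has no MSE.

## Prioritization

Each endpoint is a ToxPi slice.  BMC x (µM) transforms to `-log10(x) + 6`;
censored entries are set to the sentinel 10^6 µM first, which maps to
exactly 0.  Because the raw transform does not itself live in [0, 1], slices
are divided by the per-endpoint maximum across compounds (so 1 marks the
lowest BMC within each endpoint; a global-maximum strategy is available as a
switch).  The compound score is the weighted mean of its slices, equal
weights by default.  Profiles are clustered agglomeratively (Euclidean
distance, average linkage) on rows pre-sorted by compound id so the tree is
order-invariant.

The merged ranking puts the MSE first: compounds with specific hits sort by
ascending MSE BMC, but BMCs within overlapping 3-fold ranges
([BMC/3, BMC*3], closed transitively) are treated as equipotent and ordered
by descending ToxPi score inside the tie group.  Compounds without a
specific hit rank last, in ToxPi order.  Transitive closure is a deliberate
reading: pairwise overlap alone does not induce a consistent grouping.

## Exposure conversions

Biomonitoring values arrive per gram of matrix lipid (ng/g lw) or per
volume (ng/mL).  Conversions:

    ng/g lw:  µM = value x fat(g/L) / M(g/mol) / 1000
    ng/mL:    µM = value / M            (ng/mL = µg/L)

with fat contents 5.8 g/L (serum/cord blood) and 33 g/L (breast milk), and
bundled literature molar masses.  Daily intake assumes 1 L breast milk/day:
nmol/day = µM x 1000, reported as integers (half away from zero).  The
hazard-exposure margin is log10(BMC/exposure) in orders of magnitude.
Reported molarities round to 4 decimals.

The bundled survey table carries both the computed molarity and the µM
column published with the raw values (`um_reported`).  The two agree for the
volume-based rows (TCIPP excepted, whose published entry is inconsistent
with its standard molar mass), but the lipid-based published molarities sit
a consistent factor ~10 *above* the stated formula.  The package follows the
formula and keeps both columns side by side rather than reverse-engineering
the table; intake headlines use the reported column they were published
with.  All margins are deliberately crude IVIVE (100% bioavailability, no
metabolism, 1:1 blood-brain transfer) and outputs carry that caveat as
metadata.

## Synthetic screens

The generator emulates the battery's plate design: a geometric serial
dilution (default 1:3, 7 concentrations from 20 µM), 3-5 replicate wells,
and solvent controls, with additive Gaussian noise on the percent-of-control
scale (default SD 5% — chosen as a realistic well-to-well spread for
image-based neurosphere endpoints; the assays' true well-level variances are
not published, so this is a free parameter).  Controls are simulated around
100 with the same spread so downstream normalization is non-degenerate.
Each scenario pairs a DNT curve with reference curves whose shift encodes an
intended label, and the generator *asserts* that the analytic
viability/DNT BMC ratio of the noiseless curves is consistent with that
label (>= 3 specific, <= 1 unspecific, between borderline for NPC;
the assay's own cutoff for UKN; censored DNT for negative).  Ground truth
records the analytic BMC of the noiseless curve — for bells, the lowest
adverse crossing, i.e. the ascending limb unless only a decrease is adverse.

The canonical 12-scenario battery spans 4 specific, 1 borderline, 3
unspecific and 4 negative constructions across both classification families.
Exactly one borderline scenario is included by design: under noise, the
borderline band (CI overlap strictly between 0 and 10%) is a knife edge, and
a single such scenario bounds the expected label-recovery loss at one.

What the generator does *not* emulate: raw fluorescence units,
plate-position effects, heteroscedastic or correlated noise,
between-individual/passage variability, and image-derived artifacts.
Passing recovery tests therefore demonstrate the correctness and calibration
of the estimation machinery under the stated noise model, not robustness to
every failure mode of real screens.

## Numerical choices and degenerate inputs

* Fits run on log10 concentration with parameter bounds generous around the
  data range; Hill magnitude is bounded to [0.05, 15].
* AICc uses k = parameters + 1; a zero-residual fit floors the RSS at
  1e-300, which still orders models correctly.
* Flat or all-censored inputs propagate as censored BMCs, empty MSEs, zero
  slices and last-rank positions — never as errors.
* Significance flags: one-way ANOVA across concentration groups gates
  Bonferroni-corrected two-sided t-tests of each concentration against
  control (the correction spans only the k concentration-vs-control
  comparisons, matching post-hoc-versus-control usage; correcting over all
  pairwise contrasts is a configuration away in spirit but not implemented).
  The alpha boundary is inclusive (p <= 0.05 flags).  Identical constant
  groups yield no flags.
* Determinism: every stochastic step takes an explicit seed; per-series
  seeds derive from the master seed and the compound/endpoint labels via
  CRC32, so adding a scenario does not shuffle the streams of the others.

## Known limitations

* Published Table-1-style hit calls cannot be re-derived: the underlying
  well-level screen data are not public.  Validation therefore combines the
  published worked numbers (conversions, intakes, MSE ordering) with
  simulation studies at the battery's plate design.
* Percentile bootstrap CIs from 3-5 wells per group are near, but not at,
  nominal coverage (see above).
* The exposure module performs no kinetic modelling; margins are screening-
  level comparisons only.
* The bell model fixes its zero-concentration anchor at 100; strongly
  miscalibrated controls would bias bell fits before renormalization.
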