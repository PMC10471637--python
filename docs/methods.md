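# Methods

## The prediction rule

A doubled ST + GT four-strand graft stacks both tendons twice, so its
diameter is well approximated by the sum of the two tendons' mean
cross-sectional diameters. On a transverse MRI slice each tendon is an
ellipse-like section with a major diameter D and minor diameter d, reported
by the measuring workstation at 0.1-mm resolution. The rule is

PGD = (D_St + d_St)/2 + (D_Gr + d_Gr)/2, rounded up ("by excess") to the
next full millimetre.

Two numerical choices matter:

* **Exact arithmetic on the measurement grid.** Diameters are stored as
  integer tenths of a mm; tendon means are therefore exact at two decimals
  (integer hundredths) and the PGD ceiling is computed in integer
  arithmetic. No binary floating-point drift can move a value across a
  rounding boundary.
* **Exact integers are not bumped.** "Round up to the next full mm" is
  read as the ceiling function: a raw PGD of exactly 7.00 mm predicts a
  7-mm graft, not 8. The rounding exists to guarantee tunnel fit, and an
  exact 7.00-mm graft fits a 7-mm tunnel.

Which measurements feed the headline prediction is a protocol choice the
source material leaves open; the default is reader 1 at the baseline (t0)
session, and a consensus mode averaging both readers' tendon means (exact
on the 1/200-mm grid) is provided for sensitivity analyses.

## Agreement statistics

Predicted and actual sizes are integer mm, so agreement is three-way:
concordant, under-prediction (predicted < actual, the clinically risky
direction) and over-prediction. Each fraction gets a two-sided exact
Clopper–Pearson interval by default; Wilson is available as an option
(both reproduce the published rounded intervals for the 78/8/6 of 92
breakdown, which was verified before the default was frozen).

Chance-corrected agreement uses linearly weighted Cohen's κ with
disagreement weights |i−j|/(k−1) on the consecutive integer grid spanning
the union of observed sizes — unobserved interior categories are kept so
the weights reflect true millimetre distance. When both raters put all
mass in a single category the expected disagreement is zero and κ is
undefined; the package flags this explicitly rather than returning 0 or 1.
The verbal label (McHugh bands: ≤.20 None, .21–.39 Minimal, .40–.59 Weak,
.60–.79 Moderate, .80–.90 Strong, >.90 Almost Perfect) is applied to κ
rounded to two decimals, so e.g. κ = 0.797 is labelled "Strong".

Percentages are carried at full precision in all results and JSON; integer
percent display (rounding half away from zero) happens only in the
markdown rendering, so downstream consumers never suffer double rounding.

## Reproducibility statistics

Bland–Altman on paired series: bias = mean difference, sd with the n−1
denominator, CoR = 1.96 × sd, limits of agreement = bias ± CoR. The
alternative repeatability definition 2.77 × within-subject SD (from a
one-way components-of-variance model) is documented here for reference but
is not the default, matching the common Bland–Altman usage. The analysed
quantity is each tendon's mean diameter (D+d)/2 — the quantity that enters
the prediction — with a diagnostic mode for major/minor separately.
Orientations are fixed: intra = t0 − t1month for the same reader, inter =
reader1 − reader2 at t0 (readers ordered by identifier), so the sign of a
reported bias is interpretable. Whether the source study's inter-reader
comparison used t0 for both readers or averaged sessions is not stated;
t0-vs-t0 is the default and the session is a parameter.

## Descriptive comparison

Median/IQR use linear interpolation of order statistics (quantile type 7).
The Wilcoxon signed-rank comparison is run on the *rounded* predicted vs
actual sizes: the raw PGD sits on average about half a millimetre below
the integer surgical size purely because of the ceiling construction, so a
raw-vs-actual signed-rank test would reject for any cohort; the rounded
prediction is the clinically compared quantity. Zero differences are
discarded (Wilcoxon's original treatment; Pratt optional). For ≤ 25
non-zero differences the exact sign-flip null distribution is enumerated —
valid under tied |d| because the distribution conditions on them — and
larger samples use the normal approximation with tie and continuity
corrections. All-zero differences are reported as a flagged degenerate
outcome with p = 1.

## The synthetic cohort generator

No raw measurement data accompany the study this package models, so the
generator emulates the data's *structure*, per patient:

1. true mean tendon diameters drawn Normal(st_mean, st_sd) and
   Normal(gt_mean, gt_sd); true major/minor derived from the mean and a
   fixed cross-section eccentricity (major/minor ratio) and materialised
   on the 0.1-mm grid — the tendon size as the workstation would render
   it, so zero reader noise reproduces measurements exactly;
2. the true PGD (noise-free) is ceilinged, and the actual surgical size is
   generated relative to it: +1 mm with probability `p_under`, −1 mm (or
   −2 mm with probability `over_magnitude_2mm_prob`, default 1/6) with
   probability `p_over`, else equal, clamped to 5–12 mm. Under-predictions
   are always 1 mm, matching the published case breakdown; the single
   published 2-mm case was an over-prediction, hence the 1/6 default;
3. each of the 8 measurements (2 readers × 2 sessions × 2 tendons) adds
   Normal(0, noise_sd) reader noise and quantizes to the grid; within a
   tendon the pair is reordered so major ≥ minor (the mean is unaffected).

One PRNG stream drives the whole cohort; the seed and full configuration
are recorded in the cohort metadata.

Defaults (all calibration choices, not measured population values):
st 4.3 ± 0.45 mm, gt 3.2 ± 0.40 mm (sum ≈ 7.5 mm median raw PGD, matching
the published median), eccentricity 1.2, noise_sd 0.03 mm, quantum 0.1 mm,
p_under 0.087 and p_over 0.065 (the published 8/92 and 6/92 discordance
rates), male fraction 73/92, ages uniform over 18–55 (demographics carry
no effect on tendon size — none is modelled in the source).

**Choosing noise_sd.** With measurements quantized to 0.1 mm, a reader-
noise SD of 0.03 mm flips a measurement to the neighbouring grid point
~10% of the time, which puts the expected per-tendon CoR near 0.06 mm —
inside the published 0.06–0.11 mm range and robustly within the package's
own calibration band of 0.03–0.15 mm across seeds (verified over 200
replicates).

**Concordance attenuation.** The same noise occasionally shifts a rounded
prediction across an integer boundary (~1.5% of patients at the default
noise), so the realized concordance of a noisy cohort averages about 1–1.5
percentage points below p_equal = 1 − p_under − p_over = 84.8%. This is a
genuine property of quantized measurement, not an artefact: a real
reader's concordance is attenuated the same way. Consequently the tests
separate the two mechanisms, as the generator's design intends: parameter
recovery (class fractions within 3 SEs over 200 replicates of n = 92) and
the law-of-large-numbers concordance check are run on noise-free cohorts,
while default-noise cohorts are required to land within 3 binomial
standard errors of 85% at n = 92. A single noise_sd cannot make the noisy
mean concordance sit within 1% of 84.8% *and* keep the CoR in the
published range; the CoR calibration was kept.

## What passing tests do and do not show

The generator reproduces the study's structure — quantization, repeated
readers/sessions, discordance concentrated at ±1 mm, sizes on 6–10 mm —
but not features of real cohorts it has no information about: correlation
of tendon size with sex/height, reader-specific systematic bias,
session-ordering effects, non-Gaussian tendon size distributions, or any
relationship between tendon eccentricity and measurement difficulty.
Passing tests therefore validate the *statistical machinery* (the rule's
arithmetic, the agreement/reproducibility estimators, their calibration
under a known generative model), not the clinical accuracy of the rule on
new patients. Cohort-level published values that depend on the raw data
(κ = 0.797, the exact CoRs, the IQRs) are checked as properties and
orders of magnitude, not reproduced digit-for-digit.

## Problem sizes

Default analyses run at the study's n = 92. Monte-Carlo checks use 200
replicates of n = 92 (parameter recovery, concordance), n = 10,000 paired
differences (Bland–Altman closed-form recovery) and 2,000 null replicates
at n = 92 (Wilcoxon type-I error), which keeps the full suite around ten
seconds on one CPU.

## Known limitations

* The CSV schema fixes two readers and two sessions; more general designs
  (3+ readers, repeated-measures Bland–Altman) are out of scope.
* κ confidence intervals and hypothesis tests on κ are not provided.
* No proportional-bias (difference-on-mean) regression in the
  Bland–Altman output.
* Figure rendering is limited to exporting per-pair (mean, difference)
  CSVs for external plotting.
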