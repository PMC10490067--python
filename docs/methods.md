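# Methods

## Data model

A cohort is cross-sectional: one visit per child, with `age_months`
(validated to [1, 72]; ages supplied in days are divided by 30.4375 at
load), `mwf` (strictly inside (0, 1)), and one non-negative daily-intake
column per nutrient named in an attached dictionary. Rows are sorted by
(age, subject id) on construction, so every downstream scan is invariant
to input row order. The packaged dictionary holds 88 nutrients of which
25 are flagged excluded (redundant aggregates such as total fats and
total phospholipids; nutritionally non-essential amino acids; methionine
and phenylalanine on safety grounds), leaving the 63 analysed nutrients.
Only the counts and the named removals are externally anchored; the
remaining entries are an editable fixture.

## Sliding-window scan

The scan refits, for every window of 25 consecutive age-sorted children
(stride 1 by default) and every nutrient, the ordinary-least-squares model

    mwf ~ 1 + log(age) + intake + intake * log(age)

recording β₂ (the intake main effect), its two-sided t-test p-value with
n − 4 degrees of freedom, and sign(β₂). Windows where the intake is
constant are flagged degenerate (p recorded as NA and excluded from all
downstream denominators) rather than fitted.

**Centering.** Within a 25-child window log(age) is nearly constant, so
the `intake` and `intake·log(age)` columns are almost collinear (variance
inflation 10²–10⁴ for windows above ~2 years). In the raw parametrization
β₂ is the association extrapolated to log(age) = 0, i.e. age = 1 month,
and its standard error absorbs the full collinearity — the test has
essentially no power. By default the scan therefore centers log(age) at
the window median, making β₂ the association at the window's own age.
Centering is a reparametrization: fitted values, residuals, and the
interaction's p-value are identical; only the meaning (and power) of the
β₂ test changes. `center_log_age=False` restores the raw design. The
logarithm base is immaterial either way (it rescales β₁/β₃ and leaves all
p-values unchanged, which is tested).

**Nutrient intakes enter untransformed**; standardization happens only in
the blend models. Window counts follow
`floor((N − window_size)/stride) + 1`; each window is labelled by the
median age of its members.

## Window detection

The p-value map is binarized (1 where p₂ < α and β₂ > 0; a `signed` mode
keeps significant-negative cells as −1) and convolved with the 3×3 Sobel
kernel oriented along the age axis with replicate-padded borders, so a
constant map has zero edge strength everywhere. Edge strength at a window
position is the nutrient-summed gradient magnitude.

**Smoothing scale.** Under a stride-1 scan, adjacent windows share 24 of
25 children: a genuine transition appears as a ramp about one window
long, and significance speckle is autocorrelated at the same scale
(a single influential child perturbs 25 consecutive fits). Summing raw
gradient magnitudes lets speckle accumulate, and in pilot simulations the
profile over-segmented badly. The detector therefore averages the
*signed* per-nutrient gradient over `window_size/stride` positions before
taking magnitudes: speckle gradients alternate in sign and cancel, while
a coherent ramp survives. At stride = window_size (non-overlapping
windows) this reduces to the plain profile.

**Peaks → boundaries.** Candidate boundaries are profile local maxima
after non-maximum suppression (minimum separation again one overlap
length), retained when stronger than mean + 1 SD of the profile, or the
top-k when a boundary count is forced for confirmatory runs. Peak ages
are rounded to whole months; the boundary month belongs to the earlier
window and windows abut. Adjacent windows whose 50%-rule selections come
out identical are merged and re-scored until stable — a boundary is only
a boundary if the nutrient associations actually differ across it. On
null cohorts every segment selects nothing, so the segmentation collapses
to a single window, which is the tested null behaviour (at
stride = window_size; with heavily overlapping windows a single noise
cluster can sustain a spurious local selection, a resolution limit we
document rather than suppress).

**Selection (50% rule).** Per window and nutrient, the significant
fraction is (#significant-positive scan windows with age-mid inside the
segment) / (#non-degenerate scan windows inside), and the nutrient is
selected when the fraction reaches 0.5; the recorded sign is the majority
sign among its significant fits there.

## Trend classification

Within each detected window, `mwf_on_nutrient` (default) regresses MWF on
[1, log(age), intake] and takes the intake slope; `intake_on_age`
regresses intake on [1, log(age)] and takes the age slope — the two
defensible readings of a per-window "trend". Labels: increasing if
slope > 0 and p < 0.05, decreasing if slope < 0 and p < 0.05, stable
otherwise; p = 0.05 exactly is stable ("below" is strict), and windows
with < 5 children or constant intake yield an NA row with a reason.

## Blend models

Rows are split 75/25 by a seeded uniform draw (train size
round(N·0.75)). Predictors and outcome are z-scored on training
statistics; consequently all reported RMSEs are in SD units of the
outcome. The elastic net tunes the mixing parameter over
{0.1, …, 1.0} and a 50-value penalty path by 10-fold CV, then applies the
one-standard-error rule (largest penalty within one SE of the CV
minimum) — under a permuted outcome this collapses to the empty model,
which is tested. The random forest (500 trees by default) tunes
features-per-split over {1/3, √p, all} by the same CV; its importance is
permutation importance measured on held-out folds only. Evaluation on
the test rows: Spearman ρ (average ranks on ties), 95% CI by
tanh(atanh ρ ± 1.96/√(n−3)), RMSE of standardized predicted minus
standardized observed.

The shadow-feature selector duplicates every candidate with its values
permuted, fits a forest on real + shadow columns, and scores a hit when a
candidate's impurity importance beats the best shadow; over 20
re-permutation rounds a candidate is confirmed (rejected) when its hit
count is significantly above (below) half by a one-sided binomial test at
0.05, rejected candidates are dropped, and the loop repeats until stable
(≤ 10 iterations). At least 5 shadow columns are always kept (tiling
permuted copies when few candidates remain) so the max-shadow null does
not weaken as the pool shrinks. Selected-but-unconfirmed features are
not returned.

Candidate sets: all 63 non-excluded nutrients (untargeted), category
subsets (micronutrients = minerals + vitamins; lipids = polar lipids;
amino acids; fatty acids), or a window's own 50%-rule selections for
per-window runs; across-age runs include age as a predictor, listed
first in the ranking when selected. Windows with no candidates produce an
explicit "no combination identified" row.

## Synthetic cohorts

Ages are uniform on [6, 60] months (n = 293 by default). Baseline
MWF = a + b·log(age) with a = 0.10, b = 0.045, giving ~0.18 at 6 months
to ~0.28 at 60 — a plausible magnitude and growth shape for a
myelin-sensitive readout at these ages; these are package defaults, not
estimates. Gaussian noise (SD 0.004) is added, and the generator *fails*
(rather than clipping) if any MWF leaves (0, 1); the baseline was chosen
to leave > 4σ of headroom under the default effects.

**Intakes.** Per window, each nutrient is drawn from a [min, max]
truncated normal calibrated so the truncated mean and SD match a packaged
reference table of per-window means, SDs, and ranges. Calibration is a
nested solve — for each σ the mean equation is solved exactly for μ (the
truncated mean is monotone in μ; solved in standardized space with
erfcx-stable tail formulas), leaving a 1-D root-find in σ for the SD.
For several rows the printed SD is at or above the printed mean with a
lower bound of 0, which no truncated normal can reach (the μ → −∞ limit
is a truncated exponential with SD < mean); such rows fall back, with a
warning, to matching the mean exactly and the closest achievable SD.
True intake distributions are likely right-skewed; moment matching
reproduces printed moments, not shape. Intakes are independent across
nutrients by default; an equicorrelation knob (Gaussian copula) exists to
stress-test collinearity handling. The default panel is 30 nutrients;
windows without a printed row for a nutrient reuse the nearest printed
window's parameters.

**Effects.** Each `EffectSpec` adds `effect × z(intake)` to MWF for
children in its active windows, where z uses the window's exact truncated
moments. Defaults plant five nutrients per window at 0.015 MWF per SD
(micronutrients in 6–20 months, polar lipids/HMO in 21–30, lipids and
amino acids in 31–60), with boundaries at 20 and 30 months; a child's
window is its age rounded to the nearest month, boundary month to the
earlier window. All planted structure is exported as `SyntheticTruth`.

**What recovery tests can and cannot show.** With k equal planted
effects in a window, the per-nutrient GLM sees the other k − 1 as
residual noise, capping the β₂ t-statistic noncentrality at
√window_size/√(k−1) — 2.5 for the defaults — independent of effect size
or noise level. Per-scan-window power is then ~0.65, the 50% fraction
hovers near its threshold, and per-window recall of the full planted set
plateaus around 0.5–0.6 while precision stays ≈ 1 and boundary
localization stays within ~1–2 months (the strong coherent edges
survive). A two-effects-per-window configuration (noncentrality 3.5) is
used in the unit suite to show the selection machinery itself recovers
planted sets when the information is there. None of this speaks to real
cohorts, where effect structure, intake correlation, and confounding are
unknown and no ground truth exists.

## Numerical and reproducibility notes

- Scan OLS uses `numpy.linalg.lstsq` plus an explicit (X'X)⁻¹ for the β₂
  standard error; equivalence to a normal-equations oracle and to
  statsmodels is asserted to 1e-8 over seeded fixtures.
- Rank-deficient window designs are reported degenerate, never fitted.
- All stochastic stages accept a seed; the pipeline propagates one global
  seed and records it (plus a config hash) in the report directory, and
  re-running a report is byte-identical.
- Problem sizes in the shipped verification suite (20 replicates for
  recovery and null checks, 100/200-tree forests in the heaviest loops,
  100,000 draws for moment checks) were chosen so the whole suite runs in
  minutes on one CPU.

## Known limitations

- The 50%-rule recall ceiling under many simultaneous equal effects is
  intrinsic to per-nutrient scanning (see above); a joint model would be
  required to attribute overlapping effects.
- Boundary resolution is limited to roughly one window span; windows
  narrower than that cannot be resolved and may be absorbed or merged.
- The Fisher-z CI for Spearman ρ is an approximation (exact small-sample
  intervals are not attempted).
- No confounder adjustment anywhere; associations are predictive, not
  causal.
- Cross-sectional only: one visit per child, no longitudinal
  trajectories.
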