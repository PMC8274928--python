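# Methods

## Pressure–area model

The lumen cross-sectional area of a pressurised arterial segment is
modelled with the three-parameter arctangent (Langewouters) relation
`A(P) = Am·[½ + (1/π)·arctan((P−P0)/P1)]`. The model assumes a sigmoidal
area–pressure curve symmetric (in compliance) about `P0`: compliance is
the Lorentzian `C_A(P) = (Am/πP1)/(1+x²)` with `x = (P−P0)/P1`, peaking at
`P0` with value `Am/(πP1)` and falling to half its peak at `P0 ± P1`.
Distensibility is `D_A = C_A/A`; note that `Am` cancels in `D_A`, which
therefore carries only two free parameters — this matters for the
degrees of freedom of distensibility curve comparisons (below).

Parameters and units: `Am` mm² (> 0), `P0` mmHg (finite, may lie outside
the measured grid), `P1` mmHg (> 0). The measured grid is the protocol's
10 static pressures, 15–300 mmHg.

## Per-sample processing

Triplicate inner-diameter readings are averaged **at the diameter level**
first, then converted to area under a circular-lumen assumption
(`A = π d²/4`) — the minimal assumption consistent with a single
longitudinal-view diameter per video loop. A ruptured sample keeps all
points up to its last completed pressure; the rupture pressure is
metadata, not a data point.

Fitting is bounded nonlinear least squares (trust-region reflective,
analytic Jacobian) with a data-driven start (`Am₀ = 1.05·max A`; `P0₀` the
grid pressure whose area is nearest `Am₀/2`; `P1₀` half the pressure
interquartile range) and bounds `Am ∈ (0, 10·max A]`, `P0 ∈ [−10³, 10³]`,
`P1 ∈ (0, 10⁴]` mmHg; cost-reduction tolerance 1e-10. A fit needs at
least 5 distinct pressures (3 parameters + 2 residual df) — truncated
series below that floor are reported as `insufficient_data`, constant-area
series as `degenerate`; neither is silently dropped. `R²` is
`1 − RSS/TSS` with TSS about the mean observed area, computed for the area
fit only. Maximal compliance is the closed form `Am/(πP1)` at `P0`
(clipped to the pressure range when `P0` falls outside it); maximal
distensibility has no closed-form argmax and is located on a 0.1 mmHg
grid with local quadratic refinement. The summary table reports both the
fitted `Am` and the largest measured area, so either convention of
"maximal area" can be checked against raw data.

## Curve comparison between age groups

The age effect on a whole curve is the nested extra-sum-of-squares
F-test: fit one curve to all points pooled versus one curve per group;
with k groups and p parameters per curve,
`F = [(RSS_p − RSS_s)/(p(k−1))] / [RSS_s/(N − pk)]` on `(p(k−1), N − pk)`
df. For the area curve the points are the observed (P, A) pairs (p = 3).
Compliance and distensibility have no directly observed values, and an
F-test needs data-level residuals, so the analytic forms are fitted to
finite-difference points: consecutive-grid slopes `ΔA/ΔP` at midpoint
pressures (further divided by the midpoint-interpolated area for
distensibility). The compliance family has p = 3 (peak height, `P0`,
`P1`); the distensibility family p = 2 (`Am` cancels).

**Residual weighting.** Diameter measurement error is multiplicative
(constant coefficient of variation), so area residuals have standard
deviation proportional to the area itself — a ~5-fold SD range across the
grid. The nested F distribution assumes homoscedastic residuals, and with
raw residuals the null rejection rate roughly doubles. The nested fits
therefore scale each residual by its noise scale: the observed area for
area points; `√(A_i²+A_{i+1}²)/ΔP` for compliance points (divided by the
midpoint area for distensibility), which propagates both the area noise
and the uneven grid spacing. With this weighting the area-curve test is
calibrated (empirical null rejection ≈ 0.04–0.06 at nominal 0.05 over
1000 simulations). `weighting="none"` restores raw residuals.

Degenerate inputs (separate-fit RSS below 1e-12 of the weighted total sum
of squares, e.g. two noise-free identical groups) return p = 1 with a
degeneracy flag rather than a spurious effect. Each group fit also starts
from the pooled optimum, guaranteeing `RSS_pooled ≥ RSS_separate` up to
optimizer tolerance.

Known limitations: residuals are treated as independent across pressure
points within a sample; between-horse correlation is not modelled (a
caveat shared with per-point pooled curve regressions generally). The
finite-difference compliance/distensibility points of one sample share
area observations, so adjacent residuals are negatively correlated and
those two tests run conservative (near-zero null rejection in
simulation); their significant results are therefore trustworthy, their
power understated. A label-permutation version of the test
(`permutation_nested_f`) provides an assumption-light cross-check; in
simulation its accept/reject direction at 0.05 agrees with the F-test in
≳95% of replicates at strong effects and at null.

Group curves for plotting can be the pooled-points fit (default) or the
mean of per-sample parameters; both are implemented.

## Summary-metric and histology ANOVA

Maximal area, maximal compliance and maximal distensibility are compared
with separate univariate two-way fixed-effects ANOVAs (age, location,
interaction; type-II sums of squares), with pairwise location contrasts
using the pooled residual variance, Bonferroni-adjusted over C(k,2)
pairs, and a compact-letter display (insert-and-absorb) summarising which
locations are indistinguishable.

Histology outcomes (intima–media thickness; overall area% of elastin,
smooth-muscle actin, collagen I and III) are analysed per horse ×
location with horse as a random factor nested in age group. The
implementation uses the classical expected-mean-squares construction
rather than an iterative REML fit: sequential decomposition
age | horse(age) | location | age×location, with `F_age =
MS_age/MS_horse(age)` and location/interaction tested against the
horse×location residual. This is exact under the balanced horse×location
layouts the generator produces, fast enough for simulation-based
calibration tests, and matches standard "univariate ANOVA with a random
factor" software behaviour. When each horse contributes a single row the
horse stratum is confounded with the residual and the analysis falls back
to a two-way fixed-effects ANOVA, noted in the result. Location
contrasts use the residual-stratum mean square with Bonferroni
adjustment.

Aggregation order follows the measurement protocol: five frames are
averaged per slide layer first, then layer means are thickness-weighted
(`overall% = pct₁·w₁ + pct₂·w₂`, `w = t/(t₁+t₂)`). This is not
equivalent to weighting frame-by-frame and then averaging when thickness
varies across frames; a test documents the non-equivalence on a
counterexample. Single-layer walls (the proximal aorta always; the
distal aorta in horses without a visible media split) bypass the
weighting, and thickness outcomes omit the proximal aorta, whose wall
exceeded the measurable range. Area% outside [0,100] is rejected at
parse time, never clipped.

## Synthetic cohort generator

The generator emulates the reference experiment's structure — 6 young vs 14 old horses;
4 mechanically tested locations × 10-pressure grid × 3 replicate
diameters; 7 histology locations × up to 2 media layers × 4 stains × 5
frames — with these defaults:

* **Vessel mechanics**: per location × age, `Am` equals the reported
  group-mean maximal area (e.g. young proximal aorta 3313 mm², young
  common carotid 100 mm²); `P0 = 112.5` mmHg, the midpoint of the
  100–125 mmHg range where equine maximal compliance occurs; `P1 =
  Am/(π·C_max)` backed out of the reported maximal compliance (young
  proximal aorta ≈ 58.6 mmHg).
* **Between-horse spread** (synthetic assumptions, not reported values):
  `Am` SD equals the reported group SD; `P1` SD 20% of `P1`; `P0` SD
  10 mmHg. Draws are truncated to the valid parameter domain.
* **Measurement noise**: 2% multiplicative SD per replicate diameter
  reading, a plausible ultrasound caliper repeatability (no repeatability
  figure is reported). Averaging three replicates leaves ≈2.3% area
  noise.
* **Rupture**: optionally, a configurable fraction of old-group samples
  (default 10% when enabled, informed by the reported 8/78 ruptures,
  7 of 8 in old horses) lose grid points above 250 mmHg.
* **Histology**: horse-level overall means drawn from the reported
  per-location mean ± SD (truncated normal on [0,100]); the two media
  layers receive mean-preserving contrasts (inner layer +12 percentage
  points smooth-muscle actin, −12 elastin) so thickness-weighting
  recovers the overall value exactly; frame-to-frame SD 3 percentage
  points; thickness measurement CV 5%; inner-layer thickness fraction
  0.6; the distal aorta shows two layers in 40% of horses.

Everything is a pure function of (configuration, seed).

What the generator does **not** emulate: within-horse correlation across
locations, pressure-history (viscoelastic) effects, non-circular lumina,
asymmetric rupture mechanics, stain-specific segmentation error, or any
systematic bias between ultrasound calipers and true geometry. Passing
tests therefore certify the statistical machinery under the stated noise
model, not the field validity of those assumptions.

## Problem sizes used in the checks

Simulation-based checks use sizes chosen to keep Monte Carlo error small
relative to the tolerances: 1000 null datasets for the F-test
calibration (95% binomial half-width ≈ 0.014 around 0.05), 200+ samples
for the recovery medians, 25 replicate cohorts (≥150 young proximal-aorta
samples) for the reference-mean reproductions, and 60 replicates for the
permutation cross-check and histology power checks.
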