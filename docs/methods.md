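# Methods

## Problem and model

Intraoperative hyperspectral imaging (HSI) records tissue reflectance between
500 and 1000 nm and summarizes it into four unitless indices in [0, 1]:
near-infrared perfusion (NIR), superficial oxygen saturation (StO₂), organ
hemoglobin index (OHI) and tissue water index (TWI). The GLIMMER score turns
two of them into a bedside classifier for MGMT promoter methylation in
diffuse glioma:

    score = [OHI ≤ 0.606] + [TWI ≥ 0.501],   score ≥ 1 ⇒ predicted methylated

with the reference standard being the mean pyrosequencing methylation
percentage across CpG sites 74–80, dichotomized at ≤ 8% (unmethylated,
boundary inclusive). The biological rationale is that methylated tumors tend
toward lower cellular density (more water → higher TWI) and reduced
perfusion (less hemoglobin → lower OHI). All boundaries are inclusive
exactly as written; both a fixed rule and data-derived cut-offs
(Youden-optimal per-index thresholds) are supported.

## Index computation

Indices are two-band contrasts on the absorbance curve A(λ) = −log₁₀ R(λ):

    c = (Ā_signal − Ā_reference) / (Ā_signal + Ā_reference)
    index = clamp((c − c_lo) / (c_hi − c_lo), 0, 1)

Band means use the stored wavelength grid with inclusive bounds and no
interpolation (deterministic); a fully reflective tissue (zero absorbance in
both bands) is assigned c = 0; out-of-bounds contrasts saturate rather than
error, matching the 0–100% semantics of the device indices. −log₁₀ is
conventional optical density; a base change would be absorbed by the
rescaling bounds. The vendor's exact band definitions are not public, so the
shipped defaults (OHI: 500–650 vs 700–800 nm; TWI: 880–1000 vs 700–880 nm;
NIR: 825–925 vs 655–735 nm; StO₂: 570–590 vs 740–780 nm; contrast bounds
(−1, 1) throughout) are approximations chosen for the qualitatively correct
monotonicity — hemoglobin absorption raises OHI, the 970 nm water overtone
raises TWI — and are fully overridable via the `index_definitions` config
key. Whether the device's StO₂ is a band contrast or a fitted
oxy/deoxy unmixing is unknown; a band contrast is used.

## ROC machinery

Candidate thresholds are the observed marker values with inclusive
positivity (`marker ≤ t` for lower-positive markers such as OHI, `≥ t` for
higher-positive such as TWI), matching how clinical cut-offs are reported.
The AUC is the tie-corrected Mann–Whitney statistic
(#concordant + ½·#tied) / (n₊·n₋), which equals the trapezoidal area under
the empirical ROC polygon (asserted to 1e-12 in tests). DeLong confidence
intervals use per-case placement values with variance S₊/n₊ + S₋/n₋ and a
Wald interval clipped to [0, 1] on the additive scale (the published
intervals are truncated at 1, consistent with clipping, not a logit
transform); perfect separation yields a zero-width interval. A stratified
percentile bootstrap (resampling within each class, seeded) serves as the
independent interval method. Youden-optimal cut-offs maximize
sens + spec − 1 over observed values; ties are broken by higher specificity,
then by the less inclusive threshold — the tie-break is not stated in the
clinical reporting convention, so specificity-first was chosen and is
documented here.

## Association analyses

The continuous-variable model is a two-predictor logistic regression
(intercept + OHI + TWI) fitted by Newton iterations (statsmodels `Logit`,
gradient tolerance 1e-8, max 100 iterations), with Wald standard errors from
the inverse observed information and the model AUC (fitted probabilities vs
truth) with a DeLong CI. Coefficient uncertainty is reported as
estimate ± SE. Quasi-separation is flagged (converged = False, warning) when
any |coefficient| exceeds 25; under complete separation, where the
information matrix is singular at the Newton iterates, a quasi-Newton
fallback (BFGS on the negative log-likelihood, pseudo-inverse covariance)
still reports estimates honestly flagged as unreliable. No Firth penalty is
applied — separation is flagged, not corrected. Group comparisons use the
Welch t-test with Satterthwaite degrees of freedom (the score groups'
spreads differ markedly, e.g. SD ≈ 22 vs ≈ 5 percentage points), and
categorical contrasts use the two-sided Fisher exact test with the
point-probability definition (the tail-doubling variant is available behind
a flag). No multiple-testing correction is applied anywhere, and the report
says so.

## Synthetic data

Because the study's raw per-patient measurements are unpublished
("available upon request"), three synthetic sources stand in for them.

**Reflectance forward model.** R(λ) = s·exp(−L·μₐ(λ))·(1 + ε), clamped to
(0, 1], with ε ~ N(0, noise_sd) i.i.d. per wavelength and
μₐ = c_Hb·[SO₂·ε_oxy + (1−SO₂)·ε_deoxy] + w·μ_water. The chromophore
pseudo-spectra are analytic Gaussian shapes — ε_oxy = G(542,12) + G(576,10),
ε_deoxy = 1.2·G(555,18) + 0.4·G(760,25), μ_water = G(970,45) +
0.25·G(835,30) — not literature extinction coefficients; they keep the
package dependency-free while preserving the monotone physics the analysis
relies on (more water deepens the 970 nm trough, more hemoglobin deepens the
visible band). Defaults: scatter baseline 0.85, path length 1, grid 500–1000
nm in 5 nm steps.

**Index-level cohorts.** Per MGMT class, (OHI, TWI) from a bivariate normal
clamped to [0, 1], NIR/StO₂ from independent clamped normals, and the
methylation percentage from a rejection-sampled truncated normal (iteration
cap 10⁶, then clamping) confined to the class's side of the 8% cut — so
generated status and percentage can never disagree. Defaults encode the
study conditions: 19 methylated / 6 unmethylated (76% prevalence), class
index means from the illustrative methylated-like (OHI 0.54, TWI 0.72) and
unmethylated-like (OHI 0.75, TWI 0.31) patterns, NIR/StO₂ means at the
cohort medians (0.45/0.51), methylation-percentage means/sds reusing the
published score-group summaries (31.5 ± 22.3 vs 7.9 ± 5.4) as the closest
available estimate of class separation, molecular fractions 64% IDH-wild-type,
68% grade 4, 60% TERT-mutant, 12% 1p/19q codeleted (codeletion restricted to
IDH-mutant cases; IDH-wild-type cases are graded 4, as the current tumor
classification implies). Spread and correlation parameters (sds 0.06–0.10,
ρ(OHI,TWI) = −0.3) were fixed once as plausible for index data of this kind.

**Physics-level cohorts** draw tissue parameters uniformly from
class-disjoint ranges (methylated: water 0.55–0.80, hemoglobin 0.40–0.80;
unmethylated: water 0.20–0.45, hemoglobin 1.00–1.40), simulate a spectrum
per case and compute the indices, giving an end-to-end path on which,
noise-free, every methylated TWI exceeds every unmethylated TWI.

**Reconstruction fixture.** A deterministic 25-patient table encoding
exactly what the published operating points force: among 19 methylated
cases, 15 OHI-positive, 16 TWI-positive, 18 positive on at least one
(hence 13 on both, by inclusion–exclusion), 1 on neither; among 6
unmethylated, a single TWI-only false positive. Index values are
synthetic — deterministic numbers on the correct side of each cut-off
(0.55/0.65 OHI bands, 0.70/0.40 TWI bands, +0.001 per row against ties) —
so every cut-off-determined quantity (confusion counts, sensitivity,
specificity, predictive values, accuracy, Youden, the three-level score's
AUC of 108/114 ≈ 0.95, and the 16-case IDH-wild-type grade-4 subgroup's
100%/75%/93.8%) is recomputable, while per-index AUCs and the logistic
coefficients are *not* reproduced by construction and are validated by
statistical properties instead (parameter recovery at n = 20 000, null
calibration, oracle agreement). The assignment of the single false positive
to the glioblastoma subgroup is inferred from the subgroup counts, not
stated outright; the fixture adopts that inference. Demographic annotations
beyond IDH/grade and the cohort-level percentages are synthetic filler.

## What passing tests do and do not show

The generators emulate the two-class index structure, the dichotomization
consistency and the monotone optics; they do not emulate spatial tumor
heterogeneity (one spectrum per case), measurement drift, ROI-placement
error, or any survival/treatment structure. Tests passing on synthetic
cohorts therefore validate the statistical machinery and the score's
arithmetic, not the clinical performance claim itself, which only external
patient data can test.

## Numerical choices and problem sizes

Every stochastic routine is a pure function of (configuration, seed);
reports are byte-identical across reruns (timestamps are opt-in and outside
the deterministic portion). Degenerate inputs have named outcomes: zero
total band absorbance → contrast 0; zero-denominator diagnostic ratios →
NaN (never silently 0); empty subgroups degrade gracefully without aborting
the overall analysis; single-class labels raise a dedicated error. Test
problem sizes were chosen to make the checks sharp yet quick: 10 000 draws
per class for generator-mean recovery (tolerance 0.01), 20 000 cases for
logistic recovery (10% relative), 1 000 random instances for the
AUC/trapezoid and Youden-oracle identities, 2 000 bootstrap replicates at
40 + 40 cases for the DeLong/bootstrap width comparison (20%), and exhaustive
hypergeometric enumeration for Fisher tables with total ≤ 40.

## Known limitations

Default band definitions are stand-ins for the vendor's proprietary
formulas; per-index absolute values are therefore not comparable to device
output, only their orderings. The truncated-normal rejection sampler clamps
after 10⁶ iterations, which at extreme configurations (mean far outside the
truncation interval) biases draws toward the bounds. The two-point score is
fixed to OHI and TWI; no multi-marker search or cross-validation of
cut-offs is provided.
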