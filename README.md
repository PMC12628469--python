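# glimmer-hsi

Diagnostic-performance analysis of intraoperative hyperspectral optical
biomarkers for MGMT promoter methylation in diffuse glioma.

Surgeons need the MGMT promoter methylation status of a glioma *during* the
operation — it changes how aggressively non-enhancing tumor should be
resected — but sequencing-based assays take hours to days. Hyperspectral
imaging (HSI) offers a contrast-free optical proxy: tissue reflectance
between 500 and 1000 nm is summarized into unitless indices, of which the
organ hemoglobin index (OHI) and tissue water index (TWI) track perfusion
and water content. This package implements the two-threshold **GLIMMER
score** built on those indices,

```
score = 1[OHI ≤ 0.606] + 1[TWI ≥ 0.501],    score ≥ 1  ⇒  predicted methylated
```

against the pyrosequencing reference standard (mean methylation across CpG
sites 74–80, unmethylated iff ≤ 8%), together with everything needed to
evaluate it and scores like it:

- **ROC machinery** — threshold sweeps over observed values, tie-corrected
  Mann–Whitney AUC, DeLong variance and confidence intervals, stratified
  bootstrap intervals, Youden-optimal cut-offs (`glimmer.roc`);
- **score engine** — MGMT dichotomization, scoring, classification and
  confusion-matrix metrics with honest handling of undefined ratios
  (`glimmer.score`);
- **association statistics** — logistic regression of status on OHI + TWI
  with model AUC, Welch t, Fisher exact (`glimmer.assoc`);
- **spectral indices** — two-band absorbance contrasts from reflectance
  spectra, with configurable band definitions (`glimmer.spectra`);
- **synthetic data** — a Beer–Lambert reflectance simulator, index-level
  cohort generators matching the study's class structure, and a
  deterministic 25-patient reconstruction table encoding the published
  confusion structure (`glimmer.simulate`);
- a statsmodels-style model object (`GlimmerModel.fit() → GlimmerResults`)
  orchestrating the full pipeline, and a `glimmer` CLI on top of it.

It is aimed at clinical researchers evaluating intraoperative optical
biomarkers and at methodologists who want a tested, reproducible ROC /
composite-score toolkit for small diagnostic cohorts.

## Worked example

```python
from glimmer import GlimmerModel, make_reconstruction_fixture

cohort = make_reconstruction_fixture()   # 25 patients, 19 methylated / 6 not
results = GlimmerModel(cohort).fit()     # fixed published cut-offs
print(results.summary())
```

prints (abridged):

```
GLIMMER score analysis
==========================================================
Cases: 25 (19 methylated, 6 unmethylated; prevalence 76.0%)
Rule: 1 point if OHI <= 0.606, 1 point if TWI >= 0.501; score >= 1 predicts methylated

Overall GLIMMER performance
----------------------------------------------------------
  Confusion: TP 18  FP 1  TN 5  FN 1
  Sensitivity 94.7%  Specificity 83.3%
  PPV 94.7%  NPV 83.3%
  Accuracy 92.0%  Youden 0.78
  Score AUC 0.95 (95% CI 0.87-1.00)

Subgroup {'idh_status': 'wildtype', 'who_grade': '4'} (n = 16)
----------------------------------------------------------
  Confusion: TP 12  FP 1  TN 3  FN 0
  Sensitivity 100.0%  Specificity 75.0%
  Accuracy 93.8%  Youden 0.75
```

Reading: on the reconstruction cohort the score flags 19 of 25 patients as
methylated, correctly classifying 23 (92.0% accuracy); treating the
three-level score as an ordinal marker gives an AUC of 108/114 ≈ 0.95; in
the 16 IDH-wild-type glioblastomas it catches all 12 methylated tumors and
misses one of the four unmethylated ones. `results.to_dict()` exposes every
number unrounded, plus per-index ROC blocks, the logistic model and
exploratory AUCs for IDH/TERT labels.

The same run from the shell:

```sh
glimmer fixture --out fixture.csv
glimmer analyze --cohort fixture.csv --ohi-cutoff 0.606 --twi-cutoff 0.501 \
    --subgroup "idh_status=wildtype,who_grade=4" --report report.json
```

Simulated cohorts come from `glimmer simulate --seed 7 --out cohort.csv`
(index-level) or, in Python, `simulate_cohort_spectra(...)` for the full
physics path from tissue composition through reflectance spectra to indices;
`--derive-cutoffs` re-derives Youden-optimal thresholds from the data
instead of using the fixed rule.

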