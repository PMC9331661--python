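# aromet

One-class prognostic modelling of intensive-care outcome from serum aromatic
metabolites.

Critically ill ICU patients accumulate microbially derived aromatic acids —
metabolites of phenylalanine and tyrosine such as phenyllactic,
*p*-hydroxyphenylacetic and 3-(4-hydroxyphenyl)lactic acid (p-HPhLA) — in
serum, and their admission-day levels carry prognostic information about
survival. `aromet` implements the complete chemometric workflow for turning
an eight-analyte GC-MS panel into a prognostic classifier, for researchers in
clinical metabolomics and chemometrics:

* **Censored cohort tables** — concentrations in µmol/L with explicit
  below-LOD / below-LOQ statuses (`<LOD` / `<LOQ` tokens in CSV), plus
  relative chromatographic peak areas that remain usable above the
  calibration range.
* **Synthetic cohort generation** — log-normal concentration laws matched by
  quantiles to published group medians/IQRs, per-analyte zero-inflation for
  detection occurrence, LOD/LOQ censoring, longitudinal repeat sampling,
  APACHE II scores and injectable high-concentration outliers. No study data
  were ever deposited, so this generator is what makes every stage testable.
* **DD-SIMCA one-class classifier** — PCA of the autoscaled relative-area
  matrix of the target class (healthy volunteers + survivors). Each sample
  gets a score distance *h* = Σ t²ₐ/λₐ and an orthogonal distance
  *v* = ‖x − Pt‖²; both are modelled as scaled chi-squared variables
  d ~ (d₀/N)·χ²(N) with moments-estimated d₀ and N, and combine into the
  full distance **f = Nₕh/h₀ + Nᵥv/v₀ ~ χ²(Nₕ+Nᵥ)**. A sample is accepted
  into the target class iff f ≤ χ²₁₋α(Nₕ+Nᵥ); rejection predicts a
  non-survivor-like profile. The same construction in one dimension gives a
  data-driven cutoff for a single marker.
* **DUPLEX splitting** — deterministic 2:1 calibration/test selection,
  healthy volunteers and survivors treated independently.
* **Outlier workflow** — extreme-fence (q3 + 3·IQR) and multivariate
  (Bonferroni-corrected outer distance limit) screening of survivor
  admission samples, with replacement by later-day samples and the six-group
  partition: Calibration, Test, Survivors (outliers), Survivors (others),
  Non-survivors, Non-survivors (others).
* **Validation** — Procrustes cross-validation (a pseudo-validation matrix
  whose projections reproduce classical segment-wise CV distances on the
  global model), ROC/AUC with a built-in trapezoid vs. pair-counting
  cross-check, exact small-sample Mann–Whitney, tie-corrected
  Kruskal–Wallis and Holm adjustment.

## Worked example

```python
from aromet import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(seed=1, outdir="out"))
print(summary["counts"])
print(summary["false_negative_rates"]["simca_8"])
print(summary["auc"])
```

prints (seed 1):

```
{'calibration': 57, 'test': 28, 'survivors_outliers': 30, 'survivors_others': 20,
 'non_survivors': 35, 'non_survivors_others': 26}
{'calibration': 0.018, 'pcv': 0.07, 'test': 0.071}
{'simca_8': 1.0, 'simca_7': 1.0, 'p_hphla': 0.925, 'apache2': 0.964}
```

Reading this: of the 196 generated samples, the target class (healthy +
non-outlier survivor admission samples) was DUPLEX-split into 57 calibration
and 28 test samples; the fitted acceptance region at α = 0.01 rejects 1.8%
of its own calibration samples (false negatives, close to α); and ranking
samples by the full distance separates non-survivor admission samples from
the target class with AUC = 1.0, ahead of the univariate p-HPhLA
concentration (0.925) and the clinical APACHE II score (0.964). The output
directory additionally contains the serialized models, the six-group
assignment, per-curve ROC points, distance plots (2-D h/v and 1-D full
distance) and a markdown report.

The same pipeline is scriptable from the shell:

```sh
aromet synth --seed 1 --out cohort.csv
aromet run-all --cohort-csv cohort.csv --seed 1 --outdir out
```

## Layout

| module | contents |
|---|---|
| `aromet.cohort` | panel/measurement/cohort types, censoring-aware CSV I/O |
| `aromet.synthetic` | log-normal quantile matching, cohort generator, outlier injection |
| `aromet.preprocess` | half-minimum imputation, autoscaling, outlier screening, six-group assignment |
| `aromet.duplex` | DUPLEX calibration/test splitting |
| `aromet.simca` | PCA, distances, chi-squared DOF estimation, acceptance region, univariate cutoff |
| `aromet.validation` | Procrustes CV, ROC/AUC, Mann–Whitney, Kruskal–Wallis, Holm |
| `aromet.pipeline` / `aromet.cli` | orchestration, plots, report, `aromet` console script |

See `docs/methods.md` for the statistical model, parameter choices and known
limitations.
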