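# Methods

## The classification problem

The cohort has three groups: healthy volunteers, ICU survivors and ICU
non-survivors. Non-survivors do not form a compact class — individual
patients derail metabolically in different directions — so a two-class
discriminant model is inappropriate. Instead a **one-class** model is built
for the "healthy + survivor" target class, and a new admission sample is
declared non-survivor-like when it falls outside the class's acceptance
region. Merging healthy volunteers with survivors both enlarges the
calibration set and prevents healthy subjects with naturally high
phenylpropionic acid from being rejected.

The multivariate input is the matrix of **relative chromatographic peak
areas** (analyte area / internal-standard area), not concentrations: some
non-survivor concentrations exceed the top of the calibration curve, while
relative areas remain meaningful there. An analyte below its detection limit
has no peak, so it contributes relative area 0; a detected-but-unquantifiable
peak (between LOD and LOQ) contributes its measured area.

## DD-SIMCA acceptance region

Given the autoscaled calibration matrix (per-variable mean 0, sample sd 1,
n−1 denominator), PCA retains A = 3 components (configurable). For a sample
x (autoscaled with the *calibration* parameters):

* score distance h = Σₐ tₐ²/λₐ with t = Pᵀx and λₐ the score variances;
* orthogonal distance v = ‖x − P t‖².

Each distance is modelled as a scaled chi-squared variable d ~ (d₀/N)·χ²(N).
The data-driven estimate is the classic method of moments: d₀ = mean(d),
N = round(2·mean²/var), clipped to [1, 250]; the robust variant is
deliberately not used — moments are simple and reproducible. The full
distance

    f = Nₕ·h/h₀ + Nᵥ·v/v₀,  approximately χ²(Nₕ+Nᵥ) for target samples,

yields the decision rule: accept iff f ≤ χ²₁₋α(Nₕ+Nᵥ), with α = 0.01 by
default. On clean target-class data the rejection (false-negative) rate of
held-out samples is ≈ α; this calibration is verified in the test suite with
a Gaussian target class (2000 calibration / 2000 held-out samples, binomial
99% band). The 2-D distance plot uses log(1 + h/h₀) vs log(1 + v/v₀); the
1-D plot uses the full distance on a log axis with vertical jitter.

The **univariate** analogue applies the same construction to a single
positive marker: fit (d₀, N) to the target-class values and cut at
d₀·χ²₁₋α(N)/N. The APACHE II rule is not fitted: it is the fixed clinical
threshold of 19 points (negative prognosis from 20).

## Outlier screening and the six groups

Survivor samples are screened for atypically high concentrations by two
criteria, either of which flags the sample: any analyte above the extreme
fence q3 + 3·IQR of the pooled healthy + survivor concentrations
(half-minimum imputed), and a full distance beyond the outer limit
χ²(1 − γ/n) of a one-class model of the pool (Bonferroni-corrected,
γ = 0.01). The fence multiplier 3 is the conventional "far out" choice; no
published numeric criterion exists for either screen, so both are
configurable.

Per survivor patient, the admission sample enters the modelled class; if
flagged it is replaced by the earliest clean later-day sample; if no clean
sample exists the patient is excluded and its flagged samples form the
"Survivors (outliers)" group. Remaining samples of modelled patients are
*not* screened (matching the stated workflow) and form "Survivors (others)".
Non-survivor samples never enter the model: admission-day samples form
"Non-survivors" (the ROC specificity group), later samples "Non-survivors
(others)". The six groups are pairwise disjoint and exhaustive by
construction (asserted at runtime and property-tested).

## DUPLEX split

The modelled class is split 2:1 into calibration and test, healthy
volunteers and survivors independently, on the same autoscaled area matrix
the classifier uses. The variant implemented: the two mutually farthest
points open the calibration set, the two farthest remaining open the test
set, then the sets alternate taking the remaining point with maximal
min-distance to themselves; the test quota is ⌊n/3⌋ with the remainder to
calibration (52 → 35/17, 36 → 24/12, totals 59/29). Classical DUPLEX leaves
the alternation schedule under-determined for non-1:1 ratios; the quota rule
is this package's resolution and is forced by the 59/29 totals. Ties break
toward the lowest row index, making membership invariant under row
permutation whenever pairwise distances are distinct.

## Procrustes cross-validation

Classical segment-wise CV of a PCA model refits the model per segment; PCV
replaces it with one pseudo-validation matrix usable by the already-fitted
classifier. For each segment, a local PCA is fitted on the complement
(component signs aligned to the global loadings); each held-out row is
rebuilt as x̃ = P·(t·√(λ/λᵏ)) + ê, where t are its local scores and ê its
local residual re-oriented into the global orthogonal complement with norm
preserved. Projected on the global model, x̃ reproduces the local-model
score distance (with global eigenvalue normalization) and orthogonal
distance *exactly*, so the pseudo-set's false-negative rate is the classical
CV one. The default segment scheme is leave-one-out; k-fold is available.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested:

* **Population**: 52 healthy volunteers (one day-0 sample each), 44
  survivors and 35 non-survivors; 28/9/5/1 patients contribute 2/3/4/5
  samples — 196 samples from 131 subjects.
* **Concentration law**: per group and analyte, concentration conditional on
  detection is log-normal with mu = ln(median) and
  sigma = ln(q3/q1)/(2·z₀.₇₅), quantile-matched to the published group
  median/IQR. The fit reproduces the median and quartile ratio exactly and
  the individual quartiles to within a few percent (exactly when the triple
  is log-symmetric). Where the published quantiles are censored tokens, the
  latent quantiles are synthetic choices placed in or near the LOD–LOQ band.
* **Detection**: with probability 1 − detection_fraction the analyte is
  absent (below LOD); fractions are the published per-group detection counts.
  Values drawn below the LOD are censored as below-LOD, between LOD and LOQ
  as below-LOQ (these carry a relative area but no concentration).
* **Longitudinal repeats**: later-day samples share a subject-level
  log-scale shift (sd 0.2) for within-patient correlation; admission samples
  follow the group law exactly. No published trajectory model exists, so no
  time trend is imposed.
* **Areas**: area = concentration × response factor (1.0) × log-normal noise
  (5%), never truncated from above.
* **APACHE II**: rounded log-normal matched to the group quantiles, clipped
  to the scale's range [0, 71]; healthy volunteers have none (treated as 0
  when the clinical score is used for ROC).
* **Outliers**: a configured fraction of survivor samples has one randomly
  chosen quantified analyte multiplied by a factor (default 20); the pipeline
  default rate 0.19 yields roughly 15 altered samples, and the altered row
  indices are returned as ground truth. Analytes are drawn independently —
  no between-analyte correlation structure is published, so none is asserted.

What the generator does **not** emulate: between-analyte correlations,
treatment-response dynamics, batch/drift effects, and the true (unpublished)
empirical tail shapes. Consequently, passing tests demonstrate that the
workflow is implemented correctly and behaves as designed under realistic
censored right-skewed data — not that the published performance numbers are
recovered, which is impossible without the undeposited data.

## Numerical choices and edge cases

* Sample statistics use the n−1 denominator throughout.
* Zero-variance columns abort autoscaling with the column named; the
  pipeline's model-fitting entry points may drop constant columns instead
  (`drop_constant=True`), because rarely detected analytes (published
  detection down to 0–17% in the target groups) can be absent from every
  calibration sample in a finite cohort. The serialized model records the
  variables actually used.
* Half-minimum imputation treats below-LOQ like below-LOD (no separate rule
  is published for the LOD–LOQ band); imputation over a row subset uses the
  whole-table minimum for consistency.
* `estimate_dof` requires ≥3 values and positive variance; DOF clipping to
  [1, 250] bounds the chi-squared quantiles.
* Mann–Whitney switches from exact enumeration to the tie-corrected normal
  approximation above a combined n of 12 (cost/exactness balance);
  Kruskal–Wallis returns (0, 1) for all-identical input.
* DUPLEX with n = 2 puts both points into calibration (the opening pair step
  precedes the quota check).
* Reported false-negative rates are rounded to 3 decimals (1 rejection among
  59 calibration samples → 0.017).

## Known limitations

* The chi-squared acceptance region is approximate for strongly zero-inflated
  area matrices: with many analytes absent in most samples the distance
  distribution is lumpy, and the empirical calibration false-negative rate
  can exceed α by a few percentage points on the default synthetic cohort.
* The univariate marker's discrimination under the generator is bounded by
  the overlap of the fitted log-normals: with the published non-survivor
  p-HPhLA IQR the theoretical AUC of the univariate model is ≈ 0.93, lower
  than a multivariate model that can exploit several shifted analytes at
  once. The ordering univariate-vs-multivariate can therefore differ from
  the published one on synthetic cohorts.
* Component count A = 3 is taken as given (the selection criterion used to
  choose it was not published); it is a parameter everywhere.
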