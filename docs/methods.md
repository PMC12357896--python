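# Methods

## Problem setting

A cohort combines cross-sectional EHR features (demographics, ICD-10
diagnoses, laboratory results) with a longitudinal wearable stream of active
energy burned (AEB) events. The goal is to release a *digital twin* — an
obfuscated or fully synthetic copy — together with quantitative evidence of
(i) how much statistical utility it retains and (ii) how well it protects
participants from re-identification and attribute-inference attacks. Two
twin families are implemented: a titratable statistical obfuscator that
perturbs the original rows in place, and a Gaussian-copula synthesizer that
draws entirely new rows.

## Synthetic cohort generator

All development and testing runs on simulated cohorts whose marginal
structure matches the published summaries of the motivating study cohort:
age 45.4 (16.9) years, height 169.3 (9.9) cm, weight 83 (19.8) kg, 54.84%
female, 58.4% married, 10.2% Hispanic, race proportions
Caucasian/African-American/Asian/Other = 50.6/18.3/19.3/11.9 (renormalized
to sum to one), and twenty ICD parent-letter prevalences (e.g. E 25.9%,
R 30.8%, Z 33.9%). Design choices where only marginals are published:

- **Continuous demographics** are truncated normals (age ≥ 18, height
  120–220 cm, weight 30–250 kg). The underlying location/scale are solved
  numerically so the *truncated* mean/SD equal the published values;
  truncation therefore does not bias the generated moments.
- **ICD co-occurrence** uses a single standard-normal latent factor per
  subject with loading √ρ (default ρ = 0.3), thresholded per letter at the
  probit of its prevalence. This induces positive pairwise co-occurrence
  while matching every marginal prevalence exactly in expectation. The true
  joint dependence of the source cohort is unknown; this is a stand-in, not
  an inference.
- **Wearable events** are laid on a 30-day synthetic calendar (time zones
  ignored). Event counts are Poisson (1/day), durations log-normal (median
  ≈ 22 min) capped below 3 h; 1% of events are drawn as >3 h device errors,
  and 0.7% of subjects have *only* error events (so the third exclusion rule
  fires). Event kcal = duration × a per-subject kcal rate
  (mean 300 kcal/h, SD 60) that depends on weight with slope 1.5 kcal/h per
  kg — the planted signal the outcome-model recovery tests exploit. 34.2% of
  subjects have no wearable data and 14.5% lack anthropometrics, matching
  the published exclusion cascade proportions (1868/5459 and 522/3591).
- **Labs** (default two-analyte panel: hemoglobin 12–16 g/dL, glucose
  70–100 mg/dL) draw results around mid-range with ~10% outside the range
  so high/low flagging is exercised. The two-lab default also makes the
  default outcome-model design matrix exactly 38 covariates, the study
  configuration.

What the generator does **not** emulate: within-subject longitudinal trends,
seasonality, device heterogeneity, realistic joint dependence between
demographics and diagnoses, missingness that is informative rather than
random. Passing tests therefore demonstrate correctness of the algorithms
and the qualitative privacy/utility orderings, not performance on real EHR
data.

## Preprocessing

Exclusions run in the order: no wearable events; missing height and/or
weight (after per-subject averaging); only >3 h events remaining. The >3 h
cut is strict (`duration > 10800 s`); an exactly-3 h event is kept.
ICD codes map to their uppercase leading letter, dropping the
low-representation categories W, U, V, Y, P, X. Patient-level letter
combinations occurring exactly once are consolidated into the closest
overlapping non-singleton combination; "closest" is maximal Jaccard
similarity of the letter sets, ties broken by higher candidate frequency and
then lexicographically — deterministic and biased toward common patterns. A
singleton with no overlapping partner stays as-is and sets the `oth_icd`
flag (a provisional definition; the source tables name the variable without
defining it). Lab results are flagged L/N/H with inclusive boundaries and
summarized as per-subject H/L counts per analyte. BMI and
`avg_aeb_day = sum_aeb / (sum_seconds/86400)` are derived, never raw inputs.

## Cross-sectional sifter

Four controls: per-column artificial missingness proportion, number of
missingness+imputation cycles, proportion of obfuscatable features
targeted, and the neighbour-swap proportion (with a neighbourhood size k).
Presets:

| level  | miss | cycles | features | swap | k |
|--------|------|--------|----------|------|---|
| small  | 0.05 | 1      | 0.25     | 0.05 | 5 |
| medium | 0.15 | 2      | 0.50     | 0.20 | 5 |
| large  | 0.30 | 3      | 1.00     | 0.40 | 3 |

These values are this package's configuration (tunable, not ground truth);
they produce the expected monotone quality/privacy orderings on the bundled
cohorts. Identifiers and fully dependent columns (`bmi`, `any_icd`,
`sum_aeb`, `sum_seconds`, `avg_aeb_day`) are never sifted directly; they are
recomputed from their obfuscated components afterwards.

**Imputation** fits one depth-limited regression tree per masked column
(categoricals via ordinal target codes) and fills each masked cell with the
observed value of a random training row from the same leaf (leaf-donor /
predictive-mean-matching flavour, `min_samples_leaf = 5`). Donor draws keep
imputed values on the observed marginal, which is why per-column shapes
degrade slowly with level while pairwise trends degrade faster — the same
qualitative pattern as the published quality tables — and why detection
classifiers do not trivially separate twins on off-manifold artifacts.
Cells are re-encoded and chained within a pass, and all cycles complete
before swapping (the interleaving is not externally constrained).

**Swapping** selects `round(swap_prop · n)` rows without replacement; each
exchanges its targeted values with one of its k nearest rows under a
Gower-style distance (range-normalized absolute difference for numeric, 0/1
mismatch for categorical, averaged over the obfuscatable features).
Exchanges are symmetric, so per-column value multisets are conserved.

## Longitudinal obfuscator

Three mechanisms, intensities per level: (a) whole-day event blocks
exchanged between subjects adjacent under the Euclidean distance of their
daily-total-AEB profiles (fractions 0.05/0.20/0.40 of subject-day blocks);
(b) uniform start-time jitter within the calendar day (±30 min / ±2 h /
±4 h), durations unchanged; (c) multiplicative log-normal kcal noise
(σ = 0.05/0.15/0.30). Schema and total event count are always preserved;
duration multisets are preserved whenever kcal noise is the only active
distortion. The mechanism set and intensities are this package's design
contract for longitudinal sifting.

## Gaussian copula

Numeric marginals are empirical: ranks map to normal scores
z = Φ⁻¹((rank − ½)/n) at fit time, and sampled latents invert through
linear interpolation of the empirical quantile function. Categorical
columns partition [0, 1] by cumulative frequency (categories ordered by
descending frequency, ties lexicographic); scores use interval midpoints,
sampling uses interval lookup. Empirical rather than parametric marginals
were chosen because the AEB aggregates are heavily skewed and no marginal
family is externally specified. The latent correlation is the Pearson
matrix of the scores, projected to positive definite by clipping
eigenvalues at 1e-6 and renormalizing the diagonal. Constant columns are
stored as point masses outside the correlation. AEB aggregates are
synthesized directly as columns (no sequence model). Anything exposing
`fit(table)` / `sample(n, seed)` can be registered as an external
synthesizer (e.g. a deep tabular generator) and flows through the pipeline
and evaluation identically.

## Evaluation battery

- **Quality** = mean(column-shapes mean, pair-trends mean). Shapes: KS
  complement (numeric) or TV complement (categorical). Pair trends:
  `1 − |ρ_real − ρ_syn|/2` for numeric–numeric pairs; otherwise joint
  contingency similarity with numeric columns discretized into 10 quantile
  bins computed on the real column (synthetic values clipped into the same
  edges). Constant columns fall back to the contingency branch.
- **Diagnostic** = mean(validity mean, structure). Validity is boundary
  adherence (numeric inside the real min–max) or category adherence;
  structure is |shared columns| / |union|.
- **Privacy** = mean of NewRowSynthesis (numeric tolerance 1% of the real
  column range), logistic and SVC detection (5-fold stratified CV, fold-mean
  AUC, `score = 1 − 2(max(AUC, ½) − ½)`), and TableStructure. Inference
  attacks: CAP-style modal guessing on exact quasi-identifier matches
  (default keys: age, gender, race, marital) for categorical targets;
  attacker-regression RMSE over baseline RMSE (capped at 1) for numeric
  targets.
- **Utility** (train on synthetic, test on real): binary targets average
  AdaBoost, decision tree, logistic regression and MLP macro-F1; multiclass
  averages decision tree and MLP; a numeric target is scored by one linear
  regression, R² clipped to [0, 1]. Macro-F1 and clipped R² are this
  package's loss choices for the unit-interval score contract.
- **Regression comparison**: OLS of `avg_aeb_day` on the default covariate
  set (38 columns on the default cohort; aliased columns dropped and
  reported), Wald 95% CIs (±1.96 SE). Per-coefficient CI overlap is the
  symmetric mean of mutual coverage, `100 · ½(I/len_a + I/len_b)`;
  coefficient standardized differences divide by the original fit's SE.
  When aliased-column drops differ between the original and twin fits, the
  comparison restricts to the shared covariates.
- **Univariate table**: standardized differences with pooled-variance
  denominators; the multi-category variant is the Mahalanobis form over the
  first k−1 proportions with averaged multinomial covariance
  (pseudo-inverse on singularity). Sign conventions per variable family are
  anchored to published example cells (demographic binaries print
  original − synthetic; diagnosis flags and continuous rows print
  synthetic − original).

## Numerical and reproducibility choices

All randomness flows from numpy `default_rng`; one pipeline seed fans out
to named per-stage seeds (< 2³¹). Cell-count rounding is half-up
(`round(0.3 · 10) = 3`). Boundary lab values are normal; the magnitude
classes are upper-inclusive (|d| = 0.5 is "small"). Degenerate cases have
explicit conventions: zero-variance sensitive columns score 0 with a
warning; zero-length CIs are points; empty tables round-trip with headers.
Tests and the acceptance script run at a few hundred to ~1000 analytical
subjects and 5 seeds for ordering properties — sizes at which the
generator's parameter-recovery checks are well-powered on one CPU.

## Known limitations

The sifter's imputation engine and the longitudinal mechanisms are this
package's own designs honoring the published control surface, not
re-implementations of any proprietary engine; bit-level agreement with
other obfuscators is out of scope, as are deep generative synthesis (CTGAN
is supported only through the registry), relational multi-table synthesis,
differential-privacy accounting, and validation on real EHR data. Published
headline values from the restricted cohort (e.g. overall privacy 0.83 at
the largest level, 83.1% mean CI overlap) are qualitative ordering anchors:
the package reproduces the orderings and the arithmetic, not the
cohort-specific magnitudes.
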