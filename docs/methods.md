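# Methods

`agrimet` implements the statistical workflow used to ask whether the
agricultural production system (conventional `C` vs two organic regimes
`O1`, `O2`) leaves a detectable, year-stable signature in the untargeted
LC-MS metabolome of a crop grown in a controlled two-year field trial.
This note documents the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic test bed does and does not
show about real data.

## Study design and data model

The design is 3 production systems x 3 replicate field plots x 2 harvest
years = 18 biological samples.  Every sample is extracted in technical
duplicate, every third plot is sampled in duplicate, extraction happens in
two batches each carrying six pooled extraction-QC extracts (one after
every 4th sample) and one extraction blank per 10 samples, and every 10th
instrument injection is a pooled injection QC.  Positive- and negative-mode
acquisitions form separate peak lists that are cleaned independently and
concatenated only after replicate averaging (~6,000 molecular features
combined).

A feature table is a (features x injections) intensity matrix plus
per-feature annotations: ionization mode, m/z (amu) and retention time
(seconds; a "1 min" void-volume rule is stored as 60 s).  Missing values
are NaN, never 0.

## Pre-treatment

Applied in order, per ionization mode:

1. **Ringing filter.** Instruments emit low-intensity satellite peaks on
   the higher-m/z side of intense ions.  A feature is removed when a
   surviving, more intense feature exists within 0.5 s retention time,
   0 < delta m/z < 0.3 amu, and the candidate is at strictly less than 20%
   of its intensity.  Candidates are visited in descending reference
   intensity so a removed satellite never anchors further removals.  The
   reference intensity is the median over sample-role injections — the
   rule's source protocol says "intensity" without qualifier; the median is
   robust and consistent with the blank rule.
2. **Blank filter.** A feature is removed when
   median(samples)/median(extraction blanks) < 5; a blank median of zero
   keeps the feature (the ratio is unbounded above the threshold).
3. **Void-volume filter.** Features with retention time strictly below
   60 s are removed (unretained material).

All boundary comparisons are strict exactly as quoted ("less than 20 %",
"less than five", "less than 1 min"); values at the boundary are kept.

**Normalization.** Each injection's intensities are multiplied by one
scalar so its median feature intensity equals the grand median of the
per-injection medians (computed per mode).  Even-count medians use the
arithmetic mean of the two central values.  All injections — samples, QCs
and blanks — are normalized uniformly; the source protocol does not state
whether QC/blank injections were included, and uniform treatment keeps the
downstream batch-factor and blank-ratio computations on one scale.

**Batch correction.** Per feature, the scaling factor is
median(extraction-QC intensities, batch 2) / median(batch 1); batch-2
intensities are divided by it (batch 2 is scaled toward batch 1).
Injection QCs play no part — they monitor instrument drift and are never
used for correction.  A zero batch-1 QC median leaves the feature unscaled
with a logged warning.

**Averaging.** Technical and sampling replicates are averaged
(arithmetic mean) down to one row per biological sample; pos- and neg-mode
features are concatenated.  A sample that lost one mode entirely gets that
mode's features imputed with the per-feature median of same-year samples,
with a warning.

**Precision.** Method precision is the per-feature relative standard
deviation (100 x SD/mean, n-1 denominator) over extraction-QC injections,
summarized by its median across features.

## Univariate analysis

Each feature (and each agronomic trait) is tested by a **two-way additive
ANOVA** with production system and year as crossed factors; the interaction
sum of squares is pooled into the error term.  The additive model is the
one that reproduces the published trait p-values from printed cell
summaries (e.g. a yield year effect of 1.3e-5; an interaction model gives
4.7e-5), so it is the model of record.  `anova_from_summary` reconstructs
the identical decomposition from per-cell means and SDs — within-cell SS is
sum (n-1)SD^2 — and is exactly equivalent to the raw-data ANOVA.  Designs
must have proportional cell frequencies; this covers both the balanced
3x2 layout and the pooled two-level comparison of C (n=6) against O1+O2
(n=12), which gains power because the two organic regimes are statistically
indistinguishable.

**Fold changes** are ratios of group means (C over pooled organic) computed
per year and averaged arithmetically across years, reported as a magnitude
>= 1 plus a direction.  Averaging ratios rather than log-ratios is a
documented choice; with two years and moderate folds the difference is
small.

**Multiple testing** uses the Benjamini-Hochberg step-up procedure in an
adaptive variant: the number of true nulls m0 is estimated from the
p-value quantile plot by the least-slope rule (scan slopes
(1 - p(i))/(m + 1 - i) from the smallest p; at the first decrease take
m0 = min(ceil(1/slope + 1), m)), and q(i) = min over j >= i of
p(j) * m0 / j.  Fixing m0 = m reproduces plain BH.  The estimator is
pluggable because quantile-plot variants differ between references;
least-slope is the most common and is unbiased to within 10% on uniform
nulls at m = 2,000.  m - m0 is reported as the estimated number of true
differences.

**Compact letters** for trait tables come from pairwise pooled-variance
Student t tests (df = 2n-2, alpha = 0.05); groups in a maximal clique of
the non-significance graph share a letter.

**Overlap vs chance**: for two significant-feature sets of sizes n1, n2 in
a universe of m, the chance expectation is n1*n2/m and the upper tail is
hypergeometric — used to show that system- and year-affected feature sets
overlap no more than chance, i.e. the two effects hit independent parts of
the metabolome.

## Multivariate analysis

All variables are **scaled to unit variance** (mean 0, SD 1, n-1
denominator); zero-variance variables are dropped with a warning.  PCA is
computed by SVD of the centered matrix with the sign convention that each
component's largest-magnitude loading is positive, making results
invariant to variable ordering.  Score plots carry a Hotelling T^2 (0.95)
ellipse with semi-axes sqrt(var(t_i) * T2crit),
T2crit = 2(n-1)(n+1)/(n(n-2)) * F_alpha(2, n-2).

**OPLS-DA** (two classes, coded 0/1, decision threshold 0.5) uses the
single-y orthogonal-projections algorithm: the predictive weight
w ∝ X'y (unit norm, computed once); each orthogonal component takes
w_o ∝ p - (w'p)w from the current loading p, deflates X by t_o p_o', and
the predictive component t = Xw, c = y't/t't is fitted on the deflated
matrix.  By construction t is orthogonal to every orthogonal score and w
to every orthogonal weight; with zero orthogonal components the model is
exactly the first PLS1 component.  New samples are deflated by the stored
orthogonal loadings before prediction.

**Internal cross-validation** is sevenfold: each sample is predicted once
by a model not trained on it, PRESS = sum (y - yhat_cv)^2 and
Q2(cum) = 1 - PRESS/SSY.  Folds are deterministic contiguous blocks over
samples ordered by (class, position).  Blocked folds were chosen over
round-robin stratification because stratification makes every held-out
fold's class mean mirror its training split: on pure-noise data the null
Q2 then piles up at zero with ~30% positive mass, whereas blocked folds
(training splits still always contain both classes) yield Q2 <= 0
essentially always — the honest null behavior a model-size criterion needs.
Unit-variance scaling is computed once on the full matrix before internal
CV, mimicking the behavior of the commercial software this workflow
standardizes on; external validation strictly refits scaling on training
data only.

**Model size** starts at zero orthogonal components and adds one while
Q2(cum) improves by more than 0.01 (configurable; the commercial rule is
unpublished).  A best model with Q2 <= 0 means "no model", reported as
"0 + 0 + 0"; otherwise models print as "1 + k + 0" (predictive +
X-orthogonal + Y-orthogonal; the last is always 0 for a single y).

**CV-ANOVA** assigns a p-value to a cross-validated model:
F = ((SSY - PRESS)/df1)/(PRESS/df2) with df1 = fitted components + 1 and
df2 = N - 1 - df1; PRESS >= SSY clamps F to 0 (p = 1).  The df convention
follows the published CV-ANOVA description; the source protocol gives no
formula.

**VIP.** VIP_j = sqrt(K * sum_a s_a (w_aj/||w_a||)^2 / sum_a s_a) over the
predictive component (share s = explained y-variance R2Y) and, by default,
the orthogonal components (share = their explained X-variance R2X); the
mean of VIP^2 is exactly 1, so VIP > 1 marks above-average contributors.
A predictive-only variant is available by flag; whether the reference
workflow used total or predictive-only VIP is not stated.

**Year-variable refinement.** Because the growth year dominates the
metabolome, a year-vs-year OPLS-DA is fitted (size chosen by CV), and all
variables with VIP > 1 are removed.  Removing year-dominated — rather than
system-uninformative — variables avoids enriching false-positive system
contributors.  The refined variable set feeds the system models and the
**external validation**: train on one year's 9 samples, predict the other
year's 9 (scaling refit on the training year), both directions; the figure
of merit is the correct classification rate against the 6/9
majority-class baseline.

**ROC.** Predicted class scores from external validation are summarized by
a ROC curve (thresholds swept over unique scores, ties grouped) and the
pair-counting AUC = (concordant + tied/2)/(n_pos * n_neg), with the
conventional samples as positives (the authentication framing: detect
conventional product among organic-labeled samples).  Significance is the
exact one-sided Mann-Whitney permutation p: all C(n, n_pos) assignments of
the positive labels to the observed midrank-tie-broken ranks are
enumerated and p is the fraction with U >= observed.  For 3-vs-6 this
gives 1/84 = 0.012 for a perfect ranking and 4/84 = 0.048 for U = 16;
a normal approximation (~0.010) would misstate these and is deliberately
not provided.  Enumeration is limited to 10^6 labelings.

## Synthetic data generator

The generator emulates the full design above so every stage can be scored
against ground truth.  Per-feature baseline intensities are log-normal
(log10 drawn uniform on [3.5, 6.5]); all effects are multiplicative:

* **System effect** on a random fraction of features (default 0.40,
  matching the estimated proportion of truly system-affected features),
  fold drawn uniform from [1.14, 2.53] and applied to C samples in a
  random direction; O1 and O2 are identical by default (they were
  indistinguishable in the trial), with a switch for distinct organic
  effects.
* **Year effect** on an independently drawn fraction (default 0.55), folds
  from [1.18, 6.45] applied to the second year.  Independent sampling
  makes the system/year overlap a chance overlap by construction.
* **Batch factor** per feature, uniform on [0.80, 1.25], multiplying
  batch-2 extracts (including the extraction QCs that estimate it).
* **Technical noise**: log-normal with CV 0.18, calibrated so the median
  extraction-QC RSD lands near the published 18.3%; the per-feature CV of
  the real instrument is unknown, so a common CV is a modeling choice.
* **Artifacts**: ringing satellites for features above the 95th intensity
  percentile (Poisson rate 2.0, capped at 7 per parent) at m/z offsets
  strictly inside (+0.01, +0.2) amu, retention shifts within +-0.5 s and
  2-10% of the parent's intensity, mirroring the parent's pattern across
  injections; and blank-borne signals (5% of features) present at full
  strength in blanks and samples alike.  Ordinary features show 0.2%
  carryover in blanks.

Replicate 1 of every sampling unit is extracted in batch 1 and replicate 2
in batch 2.  This balanced split means residual batch-correction error
(the QC-median factor is itself noisy) hits every sample equally and
cancels from all between-sample contrasts; with randomized batch
assignment it aligns with design factors by chance and visibly inflates
null ANOVA p-values.  Injection order is randomized under seed control;
generation is bit-reproducible for a fixed seed.

What the generator does **not** emulate: chromatographic drift, adducts,
isotope patterns, correlated features from shared compounds, missing
injections, heavy-tailed per-feature noise, or plot-level biological
variance beyond the technical term.  Passing tests therefore demonstrate
that the pipeline recovers the effects it models under the study's
geometry and noise scale — not that real cabbage data would classify this
cleanly.

## Numerical conventions and degenerate inputs

* Medians over even counts: arithmetic mean of the central pair.
* Constant responses in ANOVA: F = 0, p = 1; a perfect fit with zero
  residual reports p = 0.
* p-value ties in FDR: stable sort on input order for reproducible q's.
* PCA/OPLS sign convention: largest-magnitude loading element positive.
* All-zero injections, missing blank/QC injections, empty variable sets,
  single-class fits and out-of-range parameters raise descriptive errors
  rather than propagating NaNs.
* Problem sizes in the test suite are scaled to the study's geometry
  (18 samples; 500-2,000 features for property simulations, ~600 for the
  end-to-end fixture), which keeps the full suite and the acceptance
  script to a few seconds while preserving the p >> n regime the methods
  operate in.

## Known limitations

* Only two-class (and pooled two-class) discrimination; the three-system
  comparison is emulated one-vs-rest.
* No mixed models or plot nesting — plots are treated as independent
  replicates, as in the source workflow.
* The exact component-selection and CV-grouping rules of the commercial
  software are unpublished; the delta-Q2 rule and blocked folds here are
  documented stand-ins, so published component counts are not expected to
  reproduce exactly.
* Exact ROC p-values are enumeration-only; no large-sample approximation.
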