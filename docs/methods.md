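# Methods

## Data model

A study is a tidy table of (sample_id, group, time_months, element,
concentration) with strictly positive concentrations in arbitrary units.
Animals are sacrificed at their time point, so each sample_id belongs to
exactly one (group, time) cell and there are no repeated measures across
time; every cross-time comparison treats times as independent samples. The
reference design has three groups (control, disease model, treated disease
model), six replicates per cell, 15 elements, and time points 2–12 months
with the treated group starting at 4 months (102 animals). Comparisons
involving the treated group are restricted to shared time points.

## Quality control

**Dixon's Q (r10).** Q = (gap of the suspect extreme to its nearest
neighbour) / (range). Both extremes are tested and the larger Q wins; the
suspect is replaced by the mean of the remaining replicates when Q exceeds
the two-tailed α = 0.05 critical value (n = 3…10: 0.970, 0.829, 0.710,
0.625, 0.568, 0.526, 0.493, 0.466 — the classical table, stored as data).
The screen is single-pass: Dixon's Q is defined for one suspect value and
n = 6 leaves no room for iterative cascades. An all-equal cell has zero
range and is returned untouched. Replacement keeps the cell size intact for
the rank statistics downstream; it slightly shrinks within-cell variance,
which is acceptable at a ~1–5% replacement rate.

**Normality screen.** A KS-type composite test with mean and sd estimated
from the sample, using the Lilliefors calibration
(`statsmodels.stats.diagnostic.lilliefors`, table p-values). A plain KS test
against the plug-in normal is exposed behind `estimated_params=False` for
comparison; it is anti-conservative and not used by the pipeline. The screen
is reported, not gating: the group tests are rank-based regardless.

## Differential elements

Two-sample Wilcoxon rank-sum, two-sided; exact by enumeration when both
samples have ≤ 8 observations and the pooled data are tie-free, otherwise
midranks with the tie-corrected normal approximation (both via
`scipy.stats.mannwhitneyu`). An element is a DCE at a time point when
p < α = 0.05, uncorrected — the analysis is deliberately per-test, with a
Benjamini–Hochberg option available but off by default. Direction is the
sign of the median difference (medians, not means, for consistency with the
rank test). Note the granularity at n = 6: the attainable two-sided p-values
jump from 0.041 to 0.065, so the realized type-I rate is ≈ 4.1%, and full
separation of the two samples gives p = 2/924 ≈ 0.0022.

The supporting "group × time" analysis is a two-way fixed-effects ANOVA
(group, time, interaction; statsmodels OLS, type-II sums of squares) on the
shared time points. Because the design is cross-sectional (animals are
sacrificed), a repeated-measures treatment of time is not applicable; this
is a declared modelling decision, not an oversight.

## Correlation networks and thresholds

Within each (group, time) cell, the Spearman correlation (midranks for
ties) is computed for all element pairs. Significance thresholds come from
the tie-free permutation null:

* one inner run = `inner_reps` (default 1000) draws of ρ between two
  independent random permutations of 1..n, reduced to the empirical
  (1 − α) quantile with linear interpolation between order statistics;
* `outer_reps` (default 1000) inner runs give the point estimate (their
  mean) and a replication half-width (half the central-95% spread).

Two deliberate conventions: (1) the quantile is taken on the **signed**
null — the one-sided 0.95 quantile at n = 6 lies between the null atoms
0.714 and 0.771 and interpolation lands near 0.749; the absolute-value
quantile would land near 0.83–0.89 instead. Significance is then applied as
|SCC| > τ so that strong negative edges are also called; the per-edge null
exceedance of the absolute rule is therefore ≈ 2α by construction, while the
signed exceedance is the calibrated α. (2) Linear interpolation is what
makes non-atom values attainable at all; the null at n = 6 has only 21
distinct atoms. The ΔSCC threshold uses the same protocol with each inner
draw being the difference of two independent null SCCs (τ ≈ 1.05 at n = 6,
consistent with an independent 10⁶-draw quantile). For the ΔSCC statistic
the outer-replication half-width of the 95th-percentile estimator at
1000 inner draws is ≈ 0.085. Thresholds can be overridden numerically (e.g.
pinning τ_SCC = 0.749) for exact replication of a published analysis.

`exact_null_scc_tail` enumerates all n! permutations (n ≤ 8) and returns
P(ρ ≥ q) exactly; it brackets and validates the simulated quantile (at
n = 6: P(ρ ≥ 0.771) = 37/720 ≈ 0.051, P(ρ ≥ 0.829) = 21/720 ≈ 0.029).

DCC scan: for each pair and shared time point, Δ = SCC(group1) −
SCC(group2), significant when |Δ| > τ_DCC; antisymmetric under group swap.
Shared DCCs match on (pair, time) across two comparisons; a shared DCC is
*reversed* when the two Δs have strictly opposite signs (product < 0) — a
zero Δ on either side is not a reversal. Group-specific edges use the
any-time rule: a pair is specific to a group when significant at ≥ 1 of its
time points and at none in any other group; per-time edge tables are also
emitted so a matched-time definition can be applied downstream. A constant
element vector within a cell (possible in degenerate data) yields an
undefined correlation, recorded as NaN and never significant.

## Clustering and classification

Element profiles (element × all-samples matrix) are row z-scored (sample
sd, ddof = 1); constant rows become zeros and are flagged. Agglomerative
clustering uses 1 − ρ distance (Spearman by default, for consistency with
the network statistics; Pearson behind a flag) with average linkage by
default; elements are processed in canonical panel order, making the
dendrogram independent of incidental input order. The dendrogram exports to
Newick with merge-height branch lengths.

Classification pools samples across time points (time is dropped from the
features) and separates two groups from the 15 concentrations per animal.
The default model is a shallow decision tree (max depth 3, min leaf 3 —
~60 samples leave no room for deeper fits); Gaussian naive Bayes and a
random forest (200 trees, depth 3) are untuned baselines. Accuracy is
stratified 5-fold cross-validation; importances are impurity-based for
trees/forests and permutation-based for naive Bayes, both deterministic
under the seed.

## Synthetic data

The generator draws each (group, time) cell from a log-normal Gaussian
copula: latent z ~ N(0, R), concentration = cell_mean · exp(σ·z). Planted
Spearman targets ρ_s convert to latent Pearson correlations via the exact
copula identity r = 2 sin(πρ_s/6); rank correlations survive the monotone
exp map, so targets are attained in population. R must be positive
definite; an infeasible plant fails loudly naming the cell (no silent
nearest-PD repair, which would not honour the targets). After
exponentiation, each observation independently becomes a gross outlier
(× outlier_multiplier) with probability outlier_rate — a multiplicative
single-observation event matching the single-suspect assumption of the
Dixon screen.

Defaults emulate the reference study: σ = 0.2 per element (~20% CV, typical
for elemental quantification of tissue replicates), baseline means ordered
like mammalian brain tissue (Ca/Mg hundreds of units, Fe/Zn tens, ultratrace
elements hundredths), outlier rate 1% at 5×. Planted structure: Fe and Zn
elevated 3 log-sd in the disease group from 8 months; Se elevated 3 log-sd
in the treated group throughout, with Fe/Zn at control level (treatment
reversal); conserved correlated blocks {Zn, Cu}, {Fe, V}, {Pb, Cd, Bi}
(ρ_s = 0.8–0.85) in every cell; an Se–Ca correlation only in the treated
group; and an Fe–Mn reversal at 4 months with the treated/disease/control
correlations set to published-scale values (0.90 / −0.60 / −0.32). The
3 log-sd shift magnitude is chosen so rank tests at n = 6 have high power;
with a fully separated shift the exact Wilcoxon p bottoms out at 0.0022.

What the generator does **not** emulate: instrument noise physics, isotope
interferences, digestion recovery, batch effects, or biological covariance
beyond the planted pairs. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the assumed sampling
model — not that any particular biological finding would replicate.

## Numerical and design notes

* All randomness flows from one top-level seed through named substreams
  (`stage_seed`), so stages re-run standalone reproduce their bundle parts;
  outputs carry seed and threshold provenance in their headers.
* The pipeline default for threshold estimation uses outer_reps = 200
  (point-estimate sd ≈ 0.002, ample for edge calling); the full 1000 × 1000
  protocol is used where the critical values themselves are the result.
* Monte-Carlo test scenarios use sample sizes and replicate counts chosen
  to keep each property's false-failure probability low while the whole
  suite stays fast (tens of seconds): e.g. 10–20 seeds for majority
  properties, 1000 panels for the type-I calibration.
* Quantile estimation is `numpy.quantile` with the default linear
  interpolation; ties in measured data use midranks while the null
  simulation is tie-free (continuous-data assumption).
* Known limitations: mean replacement understates within-cell variance;
  the DCE scan is uncorrected across 90–105 tests by design; the
  any-time group-specific rule is sensitive to the number of time points
  examined (more cells, more chances for a stray significant edge); the
  copula identity is exact for the latent model but empirical Spearman at
  n = 6 is a noisy estimate of the planted target.
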