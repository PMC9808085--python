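# Methods

This note documents the statistical model behind `omiqc`, the assumptions of
the synthetic-cohort generator, the numerical conventions, and the design
choices that were genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Data model and preprocessing

Quantitation tables are features × samples with NaN as the explicit missing
marker and a stage tag that may only advance along
`raw → transformed → imputed → scaled`.

**Detection-limit filtering.** A raw cell qualifies when its value exceeds
10× the feature's LOD *or* is at or above its LLOQ (the disjunction matters
for targeted panels where only one of the two is calibrated). A feature is
retained iff its qualifying fraction is *strictly* greater than `min_frac`
(default 0.66 — "more than 66%" read literally). Features without limits fall
back to a completeness rule (non-missing fraction > `min_frac`). The rule is
evaluated per matrix as given; when plasma and serum should be filtered
separately, split the matrix first. The operation is idempotent.

**Variance stabilization.** Exact affine maximum-likelihood calibration of a
vsn-type model is deliberately not reimplemented; the downstream contract is
only that values be approximately homoskedastic. Instead: (1) per-sample
scale factors are medians of ratios to a geometric-mean reference profile
(computed over features complete in every sample, with a NaN-aware fallback);
(2) a generalized log, glog₂(x; c) = log₂((x + √(x² + c²))/2), with a single
dataset-level offset c set to the 5th percentile of the scaled non-missing
values. The transform is monotone within each sample (rank-preserving) and
reduces the SD-vs-mean dependence by at least 5× on multiplicative+additive
noise (tested). At c = 0 it reduces to log₂.

**Left-censored imputation (MinDet).** Each missing cell takes the
q-quantile (default q = 0.01) of the *observed* values of its sample, using
linear interpolation between order statistics (numpy default, identical to
R's type-7 `quantile`, the convention the established left-censored
imputation implementations use). Deterministic; a sample with no observed
values is an error naming the sample.

**Duplicate injections** are averaged per sample before analysis
(`average_duplicates`).

## 2. Stability statistics

**Moderated linear models** (`fit_linear_ebayes`). Per-feature OLS against a
shared full-rank design; residual variances s²_g (d = n − p df) are shrunk
toward a global prior via s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d). The prior
(d₀, s₀²) is moment-matched on log s²_g through digamma/trigamma equations
(trigamma inverted by Newton iteration); when the observed log-variances show
no excess spread over the χ² sampling noise, d₀ = ∞ and every posterior
variance equals the common value, so the moderated t coincides with the
ordinary t statistic. Single-column factors get moderated t on d₀ + d df
(capped at 10⁶ for numerics); multi-column factors (e.g. *individual*) get a
moderated F. Setting `prior_df=0` disables moderation and recovers ordinary
per-feature OLS exactly (used as an oracle in tests).

**Design encoding.** Time is numeric hours — degradation accumulates with
sitting time and a slope test matches that mechanism; the contrast entry
point covers the categorical 8 h-vs-0 h view. Temperature is categorical with
4 °C as reference; individuals are categorical with the lowest id as
reference. Serum designs reject temperature terms (single level by design).

**Mixed models** (`fit_mixed_stability`). Per feature, REML with the fixed
terms of the design and a random intercept per individual. A fit is singular
when the estimated random-effect variance is below 10⁻⁸× the residual
variance or the optimizer fails; the feature is then refit as fixed-effects
ANOVA with the same terms and flagged `anova_fallback`. Note that under a
*true* zero individual variance REML lands exactly on the boundary only in a
(large) majority of features — small positive estimates are a property of
REML, not a bug. Wald t/F statistics use residual df n − p: Satterthwaite
approximations would be preferable and are the convention in the reference
mixed-model tooling, but no such approximation is available in the Python
mixed-model stack, and at the balanced designs used here (n = 48 plasma
samples, p = 4) the difference is immaterial for slope tests.

**FDR.** Benjamini–Hochberg step-up, adjusted per factor and per analysis;
missing p-values are excluded from m and reinserted. The implementation is
checked against a brute-force step-up oracle and against
`statsmodels.stats.multitest` on random vectors.

## 3. Signatures

A handling-condition quality signature is the k = 20 features with smallest
*raw* p in the 8 h-vs-0 h moderated contrast for that condition (raw rather
than adjusted p: BH is monotone within one contrast so the ranking is
identical, and raw p avoids ties at capped values). Ties break by larger |t|,
then lexicographic feature id — derivation is fully deterministic. Weights
are the moderated t-values; positive weight = feature increases under
degradation.

The bundled contamination panels (erythrocyte, platelet with unit weights;
coagulation with signed weights: PPBP/THBS1/PF4 +1, F13A1/F13B and fibrinogen
chains −1) are representative marker sets from the plasma-proteome QC
literature — they are data, not algorithm, and can be replaced wholesale via
the TSV signature format (`signature, feature_id, weight`).

## 4. Enrichment scoring

Samples are compared on per-feature z-scores across the cohort (ddof = 1;
constant features become zeros with a warning). The raw signature activity is
the weighted mean Σwᵢxᵢ/Σ|wᵢ| over signature members measured in the panel
(minimum overlap 3 — smaller overlaps give noise-dominated scores). The null
for a sample permutes that sample's values across the *full measured
universe* (default n_perm = 1000), keeping the weights attached to the
signature's features, and NES = (raw − null mean)/null SD. Scores are
reported signed; restricting attention to positive scores is a display
choice.

Conventions and properties (all tested): NES is invariant to positive
rescaling of the weights; flipping all weight signs flips raw score and NES;
the sampled null converges to the exhaustive enumeration over member-value
assignments on small universes; per-sample RNG streams are keyed by a CRC of
the sample id, so results are deterministic given the seed *and* invariant to
column order; a degenerate null (SD 0, e.g. universe = uniform-weight
signature) yields a missing NES with a warning. `delta_vs_reference` reports
NES relative to designated reference samples, since the score is relative to
the cohort by construction and cannot quantify absolute degradation.

## 5. Synthetic cohort generator

Per feature g and sample s (individual i, time t, temperature τ):

log₂ y_gs = μ_g + a_gi + 1[g affected]·δ_g·t·m_g(τ) + ε_gs,
a_gi ~ N(0, σ²_ind), ε ~ N(0, σ²_noise), reported raw as 2^(log₂y).

Defaults encode the reference study design: 6 individuals; 497 metabolites
and 572 proteins; times 0/2/4/8 h; plasma at 4 °C and RT, serum at RT only;
centrifugation carried in metadata with zero effect (no significant
centrifugation differences are expected at 2,000–4,000 × g). Baselines
μ_g ~ N(10, 2²) log₂ units. σ_ind is 1.0 for metabolites and 0.3 for
proteins, making individual effects dominate the metabolome far more than
the proteome. σ_noise = 0.25.

**Affected features.** round(frac × n) features per layer are time-sensitive
(10% of metabolites, 3% of proteins), with |δ| ~ U(0.05, 0.5) log₂/h and
random sign. Plasma and serum degrade *independently drawn* affected subsets
of the same size: the two blood fractions differ chemically (coagulation
happens only in serum), and with a shared subset the serum and plasma/RT
signatures would be statistically indistinguishable.

**Temperature specificity.** Each plasma-affected feature is dominantly
sensitive at one temperature: full slope there, slope/`multiplier` at the
other. 70% of affected metabolites are RT-dominant, 70% of affected proteins
are 4 °C-dominant, producing the layer-level asymmetry (metabolome less
stable at RT, proteome less stable at 4 °C). The default multiplier is 10:
the underlying degradation chemistries — hemolysis on ice, enzymatic
conversion at RT — are largely exclusive to their condition, so
cross-condition leakage is minor. This specificity is what makes
condition-resolved signatures identifiable from 6 individuals at all; at
weak specificity (multiplier ≲ 4) features sensitive to the *other*
temperature enter a condition's top-20 and the condition-diagonal score
pattern is no longer identifiable at this sample size.

**Censoring.** Per-feature detection limits are the `lod_quantile` (default
0.05) quantile of that feature's own marginal distribution — detection limits
are analyte-specific; values below are set missing. The generator can export
a consistent LOD/LLOQ table (LLOQ at the threshold, LOD at a tenth of it).

**Contamination spike-ins.** `inject_contamination` shifts the log₂ values of
signature features in scheduled samples by strength × w/max|w| (raw-scale
values are multiplied by 2^shift); schedules are per sample id and recorded
in the ground truth.

**What the generator does not emulate:** ionization suppression, batch drift,
lipid-class-specific chemistry, systematic plasma-vs-serum baseline offsets,
or correlated feature blocks (pathways). Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
performance on any particular real cohort.

## 6. Problem sizes and conventions of the verification runs

The acceptance checks use: 1,000 random p-vectors for the BH oracle; 10⁵
permutations against the exhaustive 5-choose-2 null; 500 exchangeable samples
× 300 features with a random 20-feature signature for NES calibration
(expected mean ≈ 0, SD ≈ 1); a 500-metabolite cohort at |δ| ∈ [0.1, 0.5] log₂/h
for mixed-model power and top-20 recovery; full-size cohorts (497/572
features) for the condition-diagonal and contamination-monotonicity checks
with n_perm = 500; and a compact 60/50-feature pipeline run for byte-level
determinism. The power analysis is run with temperature modulation disabled
(multiplier 1) so the injected per-hour slope *is* the time effect being
recovered; with modulation active, the time main effect equals δ only at the
reference temperature and power would conflate slope recovery with the
temperature split, which the condition-diagonal check assesses separately.

## 7. Known limitations

- Mixed-model p-values use residual df rather than Satterthwaite; anti-
  conservative for severely unbalanced designs (not the case here).
- The glog approximation is not a maximum-likelihood vsn fit; arrays with
  strong affine (non-multiplicative) distortions may stabilize imperfectly.
- NES values are cohort-relative; cross-cohort comparison requires shared
  reference samples.
- The bundled contamination panels are representative, not exhaustive;
  site-specific panels should replace them via `load_signatures`.
- MinDet imputation deflates variance for heavily censored features, as any
  deterministic single-value imputation does.
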