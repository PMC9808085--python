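# omiqc

Pre-analytical quality control for combined plasma/serum **metabolomics and
proteomics**: feature-stability modelling across sample-handling conditions,
derivation of degradation signatures, and a permutation-normalized enrichment
score (NES) that rates the quality and blood-cell contamination of individual
samples.

## The problem

Blood samples that sit on the bench before freezing change: erythrocytes lyse
(releasing CAT, CA2, BLVRB, PRDX2, ALDOA into plasma), platelets degranulate,
enzymes keep converting metabolites (hypoxanthine and lactate accumulate), and
serum carries coagulation-driven shifts (PPBP and THBS1 up, F13A1 down) by
construction. Sitting **time** and holding **temperature** are the dominant
pre-analytical factors, and they pull the metabolome and the proteome in
opposite directions: metabolites are least stable at room temperature,
proteins at 4 °C. For clinical omics, where handling cannot be perfectly
standardized across sites, an objective per-sample quality score is needed.
`omiqc` provides that score, plus everything required to derive and validate
it on data with known ground truth.

## What it computes

**Stability models.** For each feature *g* on variance-stabilized data, either

- a moderated linear model: ordinary least squares per feature with
  empirical-Bayes shrinkage of residual variances,
  s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), with (d₀, s₀²) moment-matched on
  log s²_g, giving moderated t/F statistics on d₀ + d degrees of freedom; or
- a linear mixed model: fixed effects *time* (numeric hours), *temperature*,
  *time×temperature* and a random intercept per *individual* (REML), with an
  automatic fixed-effects ANOVA fallback when the random-effect variance is
  estimated at the boundary (singular fit).

P-values are Benjamini–Hochberg adjusted per factor.

**Signatures.** A handling-condition signature is the top-20 features by
p-value of the 8 h-vs-0 h contrast under that condition, weighted by the
moderated t-value. Bundled erythrocyte / platelet / coagulation marker panels
score contamination; all panels are plain TSV and user-replaceable.

**Scoring.** Per-feature z-scores across the cohort give each sample a
profile x; a signature S with weights w scores

    score(x, S) = Σ_{i∈S} wᵢxᵢ / Σ_{i∈S} |wᵢ|

and the NES expresses this score in standard deviations of an empirical null
obtained by permuting the sample's values across the measured feature
universe. NES ≈ 0 means average quality relative to the cohort; the score is
relative, so including a reference sample of known quality is recommended
(`delta_vs_reference`).

**Synthetic cohorts.** Because such studies rarely deposit raw tables, the
package ships a generator that emulates the reference design — 6 individuals
× {plasma at 4 °C/RT, serum at RT} × sitting times 0/2/4/8 h — with dominant
individual random effects, time/temperature degradation on a minority of
features (10% of metabolites, 3% of proteins), detection-limit censoring and
contamination spike-ins, returning the ground truth alongside the data.

## Worked example

```python
import omiqc as oq

params = oq.SimulationParams(seed=7)
metab, prot, metadata, truth = oq.generate_cohort(params)

limits = oq.DetectionLimits(truth.detection_limits("metabolites"))
filtered, report = oq.filter_low_abundance(metab, limits)
imputed = oq.impute_min_det(oq.glog_transform(filtered))

res = oq.fit_linear_ebayes(imputed, oq.build_design(metadata, oq.PLASMA_LIMMA))
print(oq.count_significant(res, "individual"))       # 495 (of 497)

contrast = oq.fit_timepoint_contrast(imputed, metadata, "plasma", temperature="RT")
sig = oq.derive_quality_signature(contrast, "metabolome_plasma_RT_8h", k=20)
scores = oq.nes_scores(oq.scale_per_feature(imputed), [sig], n_perm=1000, seed=7)
grouped = oq.group_average(scores, metadata)
print(grouped.sort_values("mean_nes", ascending=False).head(4).to_string(index=False))
```

```
              signature matrix temperature  time_h  mean_nes  n
metabolome_plasma_RT_8h plasma          RT     8.0  6.483235  6
metabolome_plasma_RT_8h plasma          RT     4.0  3.054905  6
metabolome_plasma_RT_8h plasma          RT     2.0  1.070088  6
metabolome_plasma_RT_8h plasma          4C     8.0 -0.421117  6
```

The plasma/RT/8 h signature scores highest exactly in the plasma/RT/8 h
condition group (6.5 null SDs above average), rises monotonically with
sitting time within the RT arm, and stays near zero at 4 °C — individual
random effects (SD 1.0 log₂ units) dominate the raw data, yet the signature
isolates the handling effect.

The same analysis is available from the shell:

```sh
omiqc run --seed 7 --out results/          # full five-stage pipeline
omiqc simulate --seed 7 --out cohort/
omiqc preprocess --matrix cohort/metabolome_raw.tsv \
    --limits cohort/limits_metabolome.tsv --out prep/
omiqc stability --matrix prep/imputed.tsv --samples cohort/samples.tsv \
    --matrix-type plasma --mode mixed --out stability.tsv
omiqc score --matrix prep/imputed.tsv --samples cohort/samples.tsv \
    --signatures sigs.tsv --n-perm 1000 --seed 7 --out scores.tsv
```

All interchange formats are plain TSV (matrices carry a `# stage:` comment
line and a `feature_id` column); ground truth is JSON.

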