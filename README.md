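# plastmeta

Meta-analytic machinery for quantifying how plastic residues (macro- to
nanoplastics) affect soil microbial community parameters — biomass,
α-/β-diversity, community structure, and functionality — across published
control-vs-treatment experiments.

The package is aimed at soil ecologists and meta-analysts who have a tidy
observation table (one row per control/plastic comparison with group
means, SDs, replicate counts, and moderators) and want the full synthesis
pipeline: effect sizes, pooled estimates, moderator analyses, dose–response
thresholds, variable importance, and publication-bias screens — plus a
synthetic-data generator with planted truths so every stage is testable.

## The statistics

**Effect sizes.** Each comparison yields a log response ratio

    lnRR = ln(x̄_t / x̄_c),   v = s_t²/(n_t x̄_t²) + s_c²/(n_c x̄_c²)

where (x̄, s, n) are the group mean, SD, and replicate count of treatment
and control. Missing SDs are imputed as (mean CV of complete groups for
that parameter) × (reported mean) and flagged. From digitized ordination
plots (first two axes), β-diversity and community-structure ratios are

    lnRRb = ln(D̄_t / D̄_c),   lnRRs = ln(D̄_b / (D̄_c + D̄_t))

with D̄ the mean pairwise Euclidean distances within treatment, within
control, and between groups.

**Pooling.** Random-effects pooling with weights w_i = 1/(v_i + τ²); τ²
by REML (default) or DerSimonian–Laird. An effect is significant when the
95% CI excludes zero. Categorical moderators are tested with the
between-group heterogeneity Qm = Q_total − ΣQ_within, χ² with
(levels − 1) df; levels with ≤ 5 observations are excluded.

**Dose–response.** For lnRR against plastic amount (g/kg), particle size
(μm), or incubation time (days), the cascade fits OLS, weighted
meta-regression, and a penalized-spline GAM; the GAM wins only when its
AIC undercuts the linear model's by ≥ 2. When the nonlinear model is
suitable, the broken-stick model

    Y = β0 + β1·X + β2·(X − c)₊ + ε

estimates the threshold c where the slope changes (Muggeo-style iterative
linearization, grid-search oracle as fallback, Davies pretest for the
slope change), and the zero crossing of the fitted response gives the dose
or size at which the effect changes sign.

**Importance and bias.** Moderators are ranked by random-forest
permutation importance (%IncMSE with response-permutation p-values),
boosted-tree relative influence (normalized to 100), and a
weight-proportional bootstrapped forest. Per parameter, Egger's regression
tests funnel asymmetry and Rosenthal's fail-safe N counts the null studies
needed to erase a significant pooled effect.

## Worked example

```bash
plastmeta run-all --out results_demo --seed 1
```

generates a synthetic meta-dataset (48 studies × 15 comparisons, planted
effects and a 40 g/kg broken-stick amount–functionality response), then
writes `forest.tsv`, `subgroups.tsv`, `dose_models.tsv`, `importance.tsv`,
`bias.tsv`, and `report.json`. The forest table starts:

```
parameter         k    mean     ci_low   ci_high  tau2    significant
biomass           97  -0.0662  -0.1106  -0.0219   0.0387  True
functionality    358   0.0649   0.0411   0.0888   0.0421  True
soc               37  -0.0704  -0.1400  -0.0008   0.0364  True
shannon           67   0.0111  -0.0365   0.0586   0.0289  False
```

Read: on this synthetic dataset microbial biomass declines by ~6.6% under
plastic addition (CI excludes zero), pooled functionality rises by ~6.7%,
soil organic carbon declines, and the Shannon index does not move — each
lnRR ≈ proportional change for small effects, and each row is re-derivable
by calling `estimate_tau2` + `pool` on that parameter's effect sizes.

The same machinery ingests a real deposited observation table via
`--dataset table.csv` with a YAML column map (`--schema`) when the file's
column names differ from the canonical ones.

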