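# Methods

## Epistasis model

The interaction statistic works on the natural-log scale: a multiplicative
null for the four genotype phenotype means (WT0 · TH3 = CM1 · CP2) becomes
additivity of log-means, and the departure from it is the linear contrast
`E = (μ_WT0 + μ_TH3) − (μ_CM1 + μ_CP2)`. The observation model is

    log y_ij = μ_g(i) + b_j + ε_ij,   b_j ~ N(0, σ_b²),  ε_ij ~ N(0, σ_e²),

with one random intercept per experiment (batch), capturing counter drift
between blood-count runs performed on different dates. Assumptions:
lognormal counts (equivalently, normal residuals after the log transform),
a shared residual variance across genotypes, and batch effects independent
of genotype. Strain and age columns are carried in the data model but
excluded from the default fit; they can be added as fixed covariates when a
dataset warrants it.

Numerical choices:

- **Fitting.** Variance components by REML (statsmodels `MixedLM`), the
  standard choice for small-sample mixed models. With a single experiment,
  or when batch adjustment is switched off, the fit reduces analytically to
  per-genotype means with a pooled residual variance. A batch variance
  estimated at the boundary (0) is reported with a warning, not an error —
  the fit is then numerically the fixed-effects fit.
- **Interval.** `SE = √(cᵀVc)` with `c = (+1, −1, −1, +1)` over the
  covariance `V` of the fitted means. The CI uses a t quantile with
  between-within residual degrees of freedom `N − 4 − (n_experiments − 1)`
  by default; `interval="z"` gives the normal-quantile interval. The choice
  is calibration-driven: in a 4000-replicate simulation at the default
  study size (15/group, 5 batches) the t interval covered the true
  interaction 94.95% of the time at the nominal 95%, while the z interval
  covered 94.6% — the z interval ignores the uncertainty of the residual
  variance estimate (~52 df here) and undercovers accordingly, more so for
  smaller cohorts.
- **Log base.** Natural log everywhere, recorded in output metadata.
  Changing base rescales `E` and its CI by a constant without affecting the
  sign or z-statistic, so published interaction magnitudes are only
  comparable given the base.
- **Degenerate data.** Zero-variance groups give SE = 0 and a CI collapsed
  to the point estimate; the sign class then follows the point estimate's
  sign. Values ≤ 0 are rejected by the log transform with the offending
  animal named; an explicit offset flag (off by default) can shift counts
  first.
- **Multiplicity.** The per-cell-type panel deliberately applies no
  multiple-comparison adjustment — each cell type is an independent
  question; the ANOVA/Tukey screen is the only adjusted output.

## Blood-count simulator

`simulate_blood_counts` inverts the estimator's model exactly: group
log-means are built as baseline + single-mutant deltas, with the triple-het
mean `baseline + δ_CM1 + δ_CP2 + true_E`, so the planted `true_E` is by
construction the contrast being estimated. Counts are continuous lognormal
draws — no discretization, since automated counters report quasi-continuous
K/µL values. Genotypes are allocated to experiments evenly by default
(remainder round-robin), with an `unbalanced` mode that assigns batches at
random, because real multi-experiment cohorts are rarely stated to be
balanced. Defaults (15/group, 5 experiments, σ_b = 0.1, σ_e = 0.2 on the
log scale) reflect a realistic multi-batch mouse CBC study: a residual
log-SD of 0.2 corresponds to a ~20% coefficient of variation, typical for
platelet and lymphocyte counts, with batch drift half that size. Because no
per-genotype raw means are available to copy, baselines (e.g. ~1000 K/µL
platelets) are plausibility choices, not reproductions of any published
axis; published interaction magnitudes are therefore used only as *planted
truths* for recovery tests, never as reproduction targets.

What the simulator deliberately does not model: strain or age effects
(generated as inert columns), genotype-dependent variances, count
discreteness, censoring at detection limits, and litter structure. Passing
the coverage and recovery tests therefore shows the estimator is correct
*under its stated assumptions*, not that real cohorts satisfy them.

## Expression simulator

`simulate_expression` emulates a two-genotype (WT vs KIX-mutant) ×
two-treatment (control vs c-Myb overexpression) array experiment on the
log2 scale. Disjoint gene classes are planted: activated (+2 log2 units
under treatment by default), repressed (−2), absent (pinned 1.5 log2 units
below the presence floor), and null. Within each regulated class a
configurable fraction (default 0.7, matching the order observed in KIX
studies) is KIX-sensitive: its treatment effect is attenuated to exactly
zero in the mutant genotype, the others respond equally in both genotypes.
Per-gene baselines spread around 7.0 (SD 1.5) log2 units; regulated-gene
baselines are clipped upward so that a planted gene can never fall below
the presence floor in any condition — noiseless recovery tests must be able
to demand exact truth recovery. The abundance of undetected genes is its
own knob, `frac_absent` (default 0.1). Replicate noise is i.i.d.
N(0, σ²) on log2 signals (default σ = 0.25, a typical inter-replicate SD
for averaged array probes); real array data additionally have
intensity-dependent variance, probe effects and correlated replicates,
which are out of scope.

## Gene-set classification

Detection calls of the original platform (present/marginal/absent) cannot
be re-derived from signal matrices, so presence is a per-condition
mean-signal floor, default 3.4 log2 units ("twice background"), inclusive.
All fold-change thresholds are inclusive (≥ 2-fold induced, ≤ 0.5-fold
repressed, ≥ 1.5-fold KIX-sensitivity), reading "at least" literally; this
makes activated/repressed disjoint by construction and keeps the
KIX-sensitive sets subsets of their parents. Ratios are differences of
averaged log2 signals (the scale the figures use); a stricter
per-replicate mode (`classify_myb_response_replicates`) requires every
treated replicate to clear the threshold, since "induced in both
replicates" is a defensible alternative reading. Probe→gene collapsing
keeps the probe with the highest mean signal (ties lexicographic). The
optional p-value filter is an unadjusted equal-variance two-sample t-test
on replicate log2 signals at 0.05.

## Enrichment analysis

The GSEA implementation follows the classic two-class weighted-KS
procedure. Signal-to-noise `(m_A − m_B)/(s_A + s_B)` floors each class SD
at `0.2·|class mean|` (absolute floor 0.2 when the mean is zero), so
near-constant genes score 0 instead of exploding. Ranking ties break by
stable original gene order. The running sum adds `|r_i|^p / Σ_hits |r_j|^p`
per hit (defaults: weight p = 1; an equal-weight fallback covers the
all-zero-metric corner) and subtracts `1/(N − N_hits)` per miss; ES is the
signed maximum deviation, and the sum returns to zero at the end by
construction. Defaults `n_permutations = 1000`, `min_size = 15`,
`max_size = 500`, phenotype permutation. With few samples per class the
distinct label assignments are enumerated exhaustively when their count is
below `n_permutations` (e.g. C(8,4) = 70 for a 4 vs 4 design), which makes
the permutation p exact; otherwise label shuffles are sampled with the
recorded seed. Nominal p is the same-signed tail of the permutation ES
distribution; NES divides ES by the mean same-signed permutation ES; FDR q
compares the observed NES against the pooled normalized null over all
analysed sets, and FWER p against the per-permutation most extreme
normalized ES. An estimated p of 0 is reported as 0.0 with the resolution
floor `1/n_permutations` alongside. FDR/FWER behaviour depends on the
composition of the whole set collection, so only the procedure — not any
particular published q value — is checkable.

## Test and calibration problem sizes

The statistical checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted tolerances: 1000 replicates for CI coverage
and null centering (binomial SE ≈ 0.7 percentage points at 95%), 500
replicates for recovery of a planted interaction of 0.41 at n = 16/group
(SE of the mean ≈ 0.005), 200 null datasets × 500 permutations for the
p-value uniformity KS test, 100 random instances for each brute-force
oracle comparison, and 1000 null ANOVA simulations for the type-I error
check. `scripts/acceptance.py` reruns the coverage/centering pair
end-to-end from a single seed.

## Known limitations

- The mixed model assumes batch effects shared across genotypes within an
  experiment; confounded designs (a genotype concentrated in one batch)
  inflate the contrast SE and are not specially diagnosed beyond the
  boundary-variance warning.
- The between-within df formula is exact for balanced designs; for strongly
  unbalanced batch allocations a Satterthwaite-type approximation would be
  more accurate and is not implemented.
- Gene-level presence is an approximation to platform detection calls; with
  a different background level the floor must be re-specified per panel.
- gene_set-mode permutation significance ignores inter-gene correlation and
  is anti-conservative on correlated expression data; phenotype mode is the
  default for that reason.
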