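# Methods

## Preprocessing

Counts are normalized to counts-per-million: every sample column is scaled
so it sums to 10⁶. No between-sample normalization beyond total-count
scaling is applied (no TMM or median-of-ratios size factors), and values are
not log-transformed — every statistic operates on the CPM scale directly.
Genes are then filtered on the mean CPM across *all* samples of the loaded
matrix (healthy and patient groups alike): genes with mean < 10 are
removed, genes exactly at the threshold kept. Filtering happens after
normalization and the surviving columns are deliberately not re-scaled, so
group means stay comparable across genes. When an a-priori gene set is
supplied it is intersected with the filtered matrix (matrix gene order
wins); unmatched identifiers are reported but not fatal.

## Per-gene statistic

All group comparisons use Student's pooled-variance two-sample *t* with
df = n₁ + n₂ − 2 and two-sided p values. Pooling (rather than Welch) is a
structural choice: the analytic null for the disruption index and the
degrees of freedom of the subset-vs-background comparison only hold with
additive df. Genes with zero pooled variance and equal means score t = 0,
p = 1; zero pooled variance with unequal means leaves *t* undefined — such
genes are flagged degenerate and excluded from every index numerator *and*
denominator, with the count reported. Raw p values are reported (the indices
consume |t|, never p); a Benjamini–Hochberg column is available for display
only.

## Restorative index

Δt = |t|(H~P_b) − |t|(H~P_a) per gene, always differencing absolute *t*
values. I_DD is the mean Δt; E and T are the positive and negative sums over
the *full* denominator N, so I_DD = E + T holds to machine precision, with
Δt = 0 genes counted in N but in neither sum. The one-sample test of
I_DD = 0 and the (1 − α) CI use the *t* distribution with df = N − 1 and the
empirical SE of the Δt values. Two experiments are compared on CI overlap:
an experiment wins if its CI lower bound clears the other's point estimate,
or its point estimate clears the other's CI upper bound; comparisons across
different gene universes are flagged, not refused. The distance-based
Δ_D = |MeanH−MeanP_b| − |MeanH−MeanP_a| is carried per gene for
interpretation but feeds no index, since it ignores sampling error.

The one-sample test treats the N per-gene Δt values as independent. They
are not perfectly so — all genes share the 60 samples through the CPM scale
factors — but the shared-factor correlation vanishes as the gene count
grows; the simulations below quantify the residual inflation.

## Disruption index and its analytic null

The disruption efficacy is the mean per-gene |t| between the after and
before groups; transcriptomic toxicity is the identical computation on
normal-tissue samples. The null expectation of a single |t| is the mean of
the folded central *t*,

E(|t| | ν) = 2√ν Γ((ν+1)/2) / (√π (ν−1) Γ(ν/2)),  ν > 1,

implemented through log-gamma (stable to ν ≈ 10⁶, where it approaches the
half-normal mean √(2/π)); a direct quadrature of ∫t·f(t|ν)dt / ∫f(t|ν)dt
over (0, ∞) is exposed and agrees to 1e−8. The significance test is a
one-sample *t* of the M per-gene |t| values against E(|t| | ν) with
SE = sd(|t|)/√M and df = M − 1. |t| is right-skewed, so the test leans on
the CLT across genes; at M = 500 its simulated type-I error is already
within Monte-Carlo noise of the nominal 5% (checked in the suite over 1,000
replicates).

The toxicity aggregate is defined both as the mean (comparable across gene
universes and to the efficacy index) and as the literal sum of |t| values.
The two differ only by the factor M; the report carries both and the mean is
the default, because a sum is not comparable between matrices with
different gene counts. A designated gene panel is scored by the same index
on the sub-matrix, and compared against the full gene universe with a
pooled two-sample *t* between the two |t| lists, subset overlap retained
(df = n_panel + n_all − 2); a disjoint-background variant is just a matter
of passing the complementary list.

## Dose–response models

The dose–mortality curve is a binomial GLM with logit link fitted by IRLS
(statsmodels), dead cells out of counted cells per dose row, intercept
always included. Convergence is declared by statsmodels' deviance criterion
(tolerance 1e−12, 100 iterations max); apparent separation — absurd
standard errors (> 10⁴) on finite estimates — is reported through
`converged=False` plus a message instead of an exception, so model sweeps
continue past pathological candidates. An independent check in the test
suite maximizes the binomial log-likelihood directly (grid + Nelder–Mead)
and agrees to 1e−4 in the coefficients.

Expression-covariate screening fits every subset of the candidate main
effects plus every combination of pairwise interactions among included
mains, ranks by AIC (ties by BIC, then by parameter count) and reports
likelihood-ratio tests of all nested pairs. The screen defaults to the
*propensity scale* — each row's observed mortality fraction as one
binomial-family observation — rather than the grouped counts. This is a
deliberate weighting decision: with thousands of cells per row the grouped
likelihood resolves mortality differences of a fraction of a percent, so
biologically negligible covariate effects become highly significant and
AIC inflates models; treating the row (the dose condition) as the unit of
replication asks the right question of a nine-row design. The dose model
itself stays on grouped counts, where every counted cell genuinely is an
observation. Both scales are available everywhere via `grouped=`.

Covariates enter untransformed; predictions are the inverse logit of the
linear predictor.

## Simulators

Counts are negative-binomial (gamma–Poisson), the standard overdispersed
model for RNA-seq: mean μ, size r, variance μ + μ²/r, with r = 10 as a
moderate biological-replicate dispersion. Baseline means are log-uniform
over [1, 10⁴], spanning the observed four orders of magnitude between
lowly expressed genes and housekeeping-scale genes. Effects are
multiplicative: affected/perturbed genes draw a log2 fold change from
N(0, sd). The restorative generator defaults to the 20/20/20 cohort design
and interpolates the drug effect on the log scale — P_a means are
baseline·effect^(1−ρ) — so ρ = 1 restores the healthy mean exactly and
ρ = 0 makes P_a exchangeable with P_b. The disruptive generator defaults to
the 3-vs-3 cell-line design; a designated panel (the first k genes) has its
log fold changes multiplied by a boost factor. The dose generator draws
n_dead ~ Binomial(n_cell, expit(a + b·dose)) with defaults
(a, b) = (−3.3827, 0.0130) and doses 0–500 in steps of 50; optional
covariates add *AG2*, linear in dose with noise (sd 60 over a 100–2000
range), and *AG1*, uniform noise on a similar scale. Every generator
returns a truth table (affected flags, fold changes, true means or
propensities) so recovery tests never re-derive truth.

What the simulators do *not* emulate: gene–gene correlation (co-expression
modules), library-size imbalance beyond total-count scaling, batch effects,
sample-level heterogeneity (e.g. tumor lineage mixtures), or count
zero-inflation. Passing tests therefore demonstrate correctness of the
statistics under an idealized independent-gene NB world, not robustness to
those real-data features.

## Numerical and design choices

- Rankings break ties by gene identifier (stable mergesort), so outputs are
  deterministic.
- CI and tests are two-sided throughout.
- The Δt sign convention stores signed *t* per comparison but differences
  only |t| values; the sign of the underlying *t* never enters an index.
- Degenerate genes (zero pooled variance, unequal means) are excluded from
  numerators and denominators alike and counted in reports and logs.
- `expected_abs_t` refuses ν ≤ 1, where the mean of |t| diverges.
- Problem sizes in the test suite: null-calibration and power claims use
  200–1,000 seeded replicates at 300–3,000 genes, the scale at which the
  shared-normalization correlation noted above is negligible while the
  suite stays quick; the full-size defaults (15,570 genes) are exercised
  structurally rather than in replicate loops.
- The boosted-panel power check uses a moderate base effect (log2 sd 0.5)
  because |t| saturates in an NB world: once a fold change dwarfs the
  within-group noise, t ≈ √n/CV regardless of further boosting, so a 3×
  target-panel effect is only detectable as such before saturation.

## Known limitations

- The indices treat genes symmetrically; no weighting by biological
  relevance beyond the optional a-priori gene set.
- The one-sample tests across genes ignore residual inter-gene dependence;
  at small gene counts (≲ 1,000) the restorative null test is mildly
  anticonservative (see above).
- Disruption "efficacy" rewards any perturbation, including directions that
  do not kill cells; the dose–mortality models are the complementary,
  outcome-anchored view.
- Only the logit link is provided for mortality models; no EC50
  interpolation beyond the fitted curve.
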