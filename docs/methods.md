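# Methods

This note documents the statistical model behind `mircluster`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should
know about.

## Preprocessing

**Un-amplified rule.** A qPCR reaction is treated as un-amplified when
its CT is *strictly greater* than the cutoff (default 50 cycles, the
panel's maximum; configurable because most instruments stop at 40).
Un-amplified cells are missing everywhere downstream; nothing is imputed.

**Global-mean −∆CT.** For sample *s* and amplified miRNA *m*,

    dct[s, m] = mean(CT[s, amplified miRNAs]) − CT[s, m]

so higher −∆CT means higher expression relative to the sample's global
level. The mean is taken over *amplified* miRNAs only — un-amplified
reactions have no CT to average. Consequences tested exactly: every
sample's non-missing −∆CT values average to zero, and adding a constant
to all CTs of one sample (a plate offset) leaves −∆CT unchanged. Samples
with fewer than two amplified miRNAs are dropped with a warning.

**Pipeline order.** Normalization runs before the detection filter: the
global mean includes miRNAs the filter later removes. After filtering,
per-sample means of the *retained* columns are therefore no longer
exactly zero; renormalizing after filtering is available but not the
default.

**Detection filter.** A miRNA is kept only if detected in at least
`min_detected` samples (default 30, the 30-of-42 rule; a fraction mode
covers other cohort sizes). The filter is idempotent and preserves column
order.

**Hemolysis QC.** Red-cell lysis releases miR-451a into plasma; the gap
∆CT = CT(miR-23a-3p) − CT(miR-451a) flags contamination, with > 7 cycles
flagged and 5–7 logged as borderline (the convention of the standard
plasma-miRNA QC workflow; all three knobs configurable). Samples are
flagged, never dropped automatically. If either marker is un-amplified
the verdict is "indeterminate". Simulated cohorts do not contain the
marker miRNAs, so the pipeline skips this stage on them with a warning.

## Cluster assignment

Loci on one chromosome are chained whenever the gap from the previous
interval's end to the next start is ≤ 10 kb (overlap counts as gap 0) —
single-linkage chaining, verified against a brute-force union-find oracle
on random annotation sets. Chains of one miRNA are "unclustered" and
excluded from cluster-level statistics. Raising the gap threshold can
only merge clusters (monotone coarsening, property-tested).

Named families (miR-17/92, with paralog loci at 13q31.3 and Xq26.2) are
pooled across chromosomes through an explicit two-column mapping file and
take precedence over genomic chaining; cytoband names (14q32 → c14mc,
19q13.41 → c19mc) are resolved through a user-supplied span table so the
package embeds no genome build. A cluster overlapping two labelled spans
is an error, not a guess.

## Correlation structure

Pearson correlations use pairwise-complete observations; entries with
fewer than `min_pairs` (default 10) complete pairs are left missing.
Matrices are ordered cluster-by-cluster, members in genomic order.

**Jennrich test.** The χ² statistic for equality of two correlation
matrices from independent samples (formula in the README). The group
sample sizes used are the nominal group counts (21/21 in the matched
design), with the minimum pairwise count logged as a caveat. Inputs must
be positive definite; matrices with eigenvalues below 1e-8 are repaired
by eigenvalue clipping to the nearest positive-definite correlation
matrix and the repair is recorded in the output. This matters in
practice: a 33-member cluster estimated from 21 samples is always rank
deficient, so its within-cluster Jennrich result is only indicative and
is flagged as repaired. Calibration under the null (p = 4, n = 60 per
group, 2000 replicates) puts the empirical type-I error at α = 0.05
within [0.03, 0.08].

**Coefficient-set ANOVA.** Within-cluster regions contribute the
k(k−1)/2 upper-triangle coefficients, between-cluster regions the kA·kB
block. The two groups' sets are compared by one-way ANOVA on raw r
(Fisher-z offered as an option); for two groups F is identically the
squared pooled-variance t, which the suite asserts to 1e-9. The
coefficients within a set are statistically dependent (they share
samples), so the nominal df overstate the information content — this is
the method as practised, reproduced deliberately, and a reason the
Jennrich test is reported alongside. No multiple-testing correction is
applied across the six region comparisons (a Bonferroni column is
emitted for transparency).

## Factor analysis

**Minres EFA.** Loadings minimize the squared off-diagonal residuals of
the correlation matrix: for uniquenesses ψ the reduced matrix R − diag(ψ)
is eigendecomposed and the top-k scaled eigenvectors are the loadings; ψ
is optimized by L-BFGS-B (bounds [0.001, 1], start at 1 − squared
multiple correlation). No normality assumption is made by the fit; the
BIC used to compare dimensions comes from the ML discrepancy evaluated at
the minres solution with the Bartlett correction — a pragmatic hybrid,
used only for model comparison, never as a test.

**Rotation.** Oblimin (γ = 0, oblique) via statsmodels'
`rotate_factors`; the factor correlation matrix Φ = TᵀT is reported.
Sign indeterminacy is fixed by flipping each factor so its
largest-magnitude loading is positive, making runs bit-reproducible.

**Dimension choice.** Horn's parallel analysis (mean simulated eigenvalue
threshold by default, quantile optional; simulated datasets are seeded)
suggests k; the BIC over {k−1, k, k+1} may override it when strictly
lower. The decision trail is logged and stored in the manifest.

**Cluster scores.** The per-sample factor variables used in outcome
models are simple row means of the cluster members' −∆CT over non-missing
values — robust to sporadically undetected miRNAs, linear in the data,
and invariant to member order. No Bartlett/Thurstone factor-score
estimator is used.

## Outcome models

One model per cluster and outcome: `outcome ~ score + BMI + gravida +
history_PTB + fetal_sex` with a random intercept per matched pair
(REML). Binary covariates are 0/1; gravida is an integer count. CIs are
the normal approximation (estimate ± 1.96·SE) matching the z column of
the report schema. The PTB label itself can be modelled with
`family="logistic"`, implemented with statsmodels' variational Bayes
binomial mixed model (no frequentist binomial GLMM exists in the stack);
perfect separation on the score raises a warning. Zero-variance
covariates are dropped with a warning rather than crashing the design.

**Boundary fits.** With 21 pairs the estimated pair variance often hits
the zero boundary, where the mixed model reduces analytically to OLS but
the boundary Hessian can produce badly miscalibrated standard errors
(observed: SEs up to 3× too small at a degenerate REML point all
optimizers agree on). When the fitted pair variance is ≤ 1e-3 of the
residual variance the model therefore reports the exact OLS inference
instead. With this rule, parameter recovery at the design's scale (true
effect 0.8 weeks per unit score, 21 pairs, 200 replicates) gives mean
estimate 0.83 and 95% CI coverage 0.915. If every optimizer fails
outright the model degrades to OLS and flags the row (`degraded`).

The per-miRNA t-test defaults to pooled-variance Student's t (Welch by
flag); outcome correlations are unadjusted Pearson r with 0.05/0.01
flags plus Benjamini–Hochberg q-values in an extra column. The term-only
regression adds gestational age and birth weight as covariates on the
term subset to ask whether a cluster–outcome association is independent
of pregnancy duration and infant size.

## The synthetic cohort

The generator emulates a matched case-control plasma panel study: 21
term/PTB pairs, 58 miRNAs in three clusters (33 on chr14, 15 on chr19,
and 10 miR-17/92 members split 6 on chr13 / 4 on chrX), spacing well
inside the 10 kb chaining rule so annotation → assignment is exact.

Per sample, a latent factor per cluster is drawn from a multivariate
normal with the group's factor correlation matrix; −∆CT is
loading × factor + noise with per-miRNA loadings ~ N(0.8, 0.05²) and
noise sd 0.4, so the one-factor within-cluster correlation limit is
λ²/(λ²+σ²) ≈ 0.8 (verified at large n). Group differences enter two
ways, mirroring the two kinds of finding separately: between-cluster
coupling in the latent correlations (c14↔c19 −0.3 at term vs −0.7 in
PTB; c14↔17/92 +0.2 vs +0.4; c19↔17/92 −0.2 in both) and within-cluster
loading attenuation (PTB scales c14mc loadings by 0.75 and c19mc by
1.1). CT = per-miRNA baseline (N(42, 4²)) − dct, censored above 50 —
light, realistic missingness concentrated in high-CT miRNAs, enough to
exercise the detection filter.

Gestational age is 37.5 + Σc βc·factor_c + N(0, 0.9²) weeks with default
β = (+0.8, −0.6, 0) for (c14mc, c19mc, miR-17/92); the noise sd is
calibrated so the cohort-wide gestational-age sd is ≈ 1.6 weeks. (An
alternative `outcome_on="score"` mode generates the outcome from the
observable row-mean score, used by the parameter-recovery experiments so
the true coefficient is exactly on the scale the model estimates.) Birth
weight is linear in gestational age (160 g/week around 2850 g, sd 250);
head circumference is linear in gestational age plus a c19mc-factor term.
The PTB label is the 37-week threshold; samples are rejection-sampled
until each group reaches 21, then paired in order — matching covariates
(BMI, gravida, history, fetal sex) are drawn from cohort-realistic
distributions but have no causal effect, as matching made them
uninformative by design in the emulated study.

**What the generator does not emulate:** qPCR amplification curves,
plate/batch effects, hemolysis chemistry (QC fixtures are constructed
directly as CT patterns), inter-miRNA noise correlation beyond the
factor structure, and real miRBase coordinates. A green structural test
therefore establishes that the statistics recover the latent model —
not that real plasma data behave like the latent model.

## Known limitations and honest caveats

- **Compositional centering.** Global-mean −∆CT normalization subtracts a
  per-sample mean that is itself a weighted mix of the cluster factors.
  With 33 of 58 panel members in one cluster this has real consequences,
  measured on the default synthetic world: (i) parallel analysis on the
  centered data suggests 2 factors, merging the two anticorrelated
  imprinted clusters into one bipolar factor (on the latent scale it
  correctly suggests 3 with clean cluster-aligned loadings); (ii) the
  between-cluster term/PTB contrast is compressed (detection power at
  n = 21+21 drops from 0.91 on the latent scale to ≈ 0.83 after
  centering); (iii) the within-c14mc contrast can even invert in sign.
  Structural-recovery tests therefore run on the latent scale, and
  results on globally normalized panels dominated by one large cluster
  should be interpreted with this artifact in mind.
- Between-cluster ANOVA on dependent coefficient sets is
  anti-conservative; it is retained as the field's practice, with the
  Jennrich test as the principled companion.
- Jennrich results on clusters larger than the sample count rest on a
  positive-definiteness repair and are flagged; treat them as
  descriptive.
- The logistic mixed model is variational Bayes; its posterior sd is an
  approximation to a frequentist SE.
- Detection-filtered cohorts vary slightly in retained miRNA count
  across simulation replicates, as in real panels.
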