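# Methods

`pleioscan` implements a pipeline for deciding whether QTL shared between
traits reflect pleiotropy (one causal variant moving several traits) or
linkage (distinct causal variants in LD, each moving one trait).  The
stages mirror a dairy-cattle mapping study design: single-trait
mixed-model GWAS on de-regressed proofs (DRP), conditional lead-SNP
discovery, QTL-region definition, multi-trait chi-square meta-analysis of
summary statistics, LD-score-regression genetic correlations, and
bivariate mixed-model confirmation with an explicit decision rule.

## Single-trait association (`assoc`)

Variant QC removes monomorphic variants, variants with MAF below 1%, and
variants failing a 1-df chi-square goodness-of-fit test for Hardy-Weinberg
proportions at p < 1e-6 (the conventional filters for imputed sequence
panels).

The GRM is the average of per-variant standardized cross-products,
GRM(j,k) = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i)),
the form used by GCTA.  Kinship for the scan is built leave-one-
chromosome-out (LOCO): the tested chromosome contributes no variants to
the GRM, because fitting a SNP as a fixed effect while it also sits
inside the polygenic covariance double-counts it and costs power.  All
LOCO GRMs are produced in one pass (full cross-product minus each
chromosome's contribution) and their eigendecompositions are cached, so
the per-trait cost after the first trait is only the REML profile and the
scan itself.

The null model y = mu + g + e with g ~ N(0, sigma_g^2 K) is fit by REML
on the eigendecomposition of K, profiling out the total variance and
optimizing the heritability on [0, 0.999] by bounded scalar search —
components are non-negative by construction.  The SE of h2 comes from the
observed information (numerical second derivative at the optimum).

The scan is two-step mixed-model association (MLMA): variance components
stay fixed at the null fit and each SNP is tested by GLS.  Two SE
conventions are supported.  The default re-estimates the residual scale
per SNP, so with an identity GRM and zero genetic variance the output is
*exactly* ordinary least squares (the oracle used in the tests).  The
alternative (`rescale_residual=False`) keeps the covariance fixed at the
null fit, which makes the t statistic exactly invariant to covariates
orthogonal to the tested SNP; the two conventions differ by an O(1/n)
factor at n in the thousands.  p-values use the standard normal reference
(appropriate for cohorts of thousands); a Student-t reference is a switch
for small samples.  `neglog10p` is computed in log space so extreme
signals (-log10 p in the hundreds) survive float underflow.

Conditional discovery iterates per chromosome: take the most significant
SNP below the Bonferroni threshold (ties broken by smaller position),
append its dosage as a covariate, rescan; stop when nothing passes, abort
with a diagnostic after 20 rounds.  Variance components are not refit
between rounds by default (a config switch refits them on lead-adjusted
phenotypes).  SNPs with r^2 > 0.999 against the covariates are skipped.

## QTL regions (`regions`)

A region is anchored on a lead SNP with -log10(p) above the genome-wide
threshold.  Boundaries are the furthest left/right variants whose
-log10(p) is no less than 3 units below the lead's (inclusive); each
boundary is then clipped at 0.25 Mb from the lead, so a region spans at
most 500,001 bp (1-based inclusive).  The search runs before the clip.
Overlapping regions — from the same trait or different traits — are
reported, never merged.  A brute-force re-scan over all variants is kept
as the test oracle.

Leads discovered only in conditional rounds can fall below the marginal
threshold (their signal is masked until a neighbour is conditioned on);
the pipeline logs and skips them at the region stage, since the region
definition requires a marginally significant anchor.

## Multi-trait meta-analysis (`metamulti`)

For variant i with per-trait signed t statistics t_i, the statistic is
chi2_MT,i = t_i' V^-1 t_i with degrees of freedom equal to the number of
traits.  V is the Pearson correlation of signed t across variants,
restricted to variants with |t| < 2 for every trait so that large QTL do
not inflate it.  That truncation attenuates the correlation of a null
bivariate-normal pair (0.5 shrinks to ~0.42 at a cutoff of 2), so the
estimate is passed through the inverse of the truncated-bivariate-normal
correlation map (tabulated by Gauss-Legendre quadrature).  V is then
shrunk toward the identity with the smallest lambda in {0, 0.01, ...}
that brings the condition number under 1e6.  Meta lead SNPs come from
greedy distance clumping (take the most significant variant under the
threshold, mask +/- 1 Mb, repeat); no conditional re-analysis is defined
for the meta statistic.

## LD-score regression (`ldsc`)

The LD score of a variant is the sum over a +/- 1 Mb physical window
(self term included) of bias-adjusted squared correlations,
r2_adj = r2 - (1 - r2)/(n - 2); an isolated variant scores exactly 1.
SNP heritability comes from a weighted regression of z^2 on the LD score
(free intercept), h2 = slope * M / n-bar with M the number of regression
variants; genetic covariance from regressing z1 z2; and
rg = cov / sqrt(h2_1 h2_2).  SEs are delete-a-block jackknives over 20
contiguous variant blocks, taken over the full rg ratio.  Deliberate
divergences from the reference human-genetics implementation, chosen for
synthetic panels without a genetic map: a physical rather than 1-cM
window, and single-pass 1/max(l, 1) weights without the second-step
intercept re-weighting.  No sample-overlap correction is attempted; the
intercept is reported for inspection.  rg estimates outside [-1.25, 1.25]
are clamped and flagged; non-positive heritability makes rg undefined
(flagged, not fabricated).

## Bivariate model and decision rule (`bivar`)

Per lead SNP m the model stacks two traits:
y = [mu1 1 + beta1 m; mu2 1 + beta2 m] + u + e with u ~ N(0, G (x) A) and
e ~ N(0, diag(se1^2, se2^2) (x) I).  A is the genomic GRM — the synthetic
universe has no pedigree, and the GRM preserves the model's covariance
structure.  One eigendecomposition of A decouples the data into n
independent 2-vectors with covariance s_i G + diag(se1^2, se2^2), making
every REML iteration O(n); the decomposition is shared across the many
lead-SNP fits on the same cohort.

The fit is average-information REML.  Because the optimum frequently sits
on the boundary of the parameter space (|genetic correlation| -> 1 at
small n), each iteration evaluates several candidates and keeps the best:
the AI step on the variance-component scale (step-halved inside the PSD
cone), the same step taken on an unconstrained working scale (Cholesky
factor of G, log residual variances, with the transformation curvature
included so it is a true Newton step), an EM-REML step (monotone and
interior by construction), and an extrapolation along the previous move
to accelerate boundary ridges.  Convergence requires that no candidate
improves the restricted log-likelihood by 1e-8.  The accepted trajectory
is non-decreasing by construction; tests verify the optimum against
derivative-free maximization of the same restricted likelihood over the
same constrained space.  Fits with A indistinguishable from identity are
flagged as confounded (polygenic and residual components merge); a
genetic correlation pinned at +/- 0.999 raises a boundary flag.

Fixed effects are GLS at the converged components; each allele-
substitution effect is tested by a Wald statistic against a standard
normal.  A lead SNP is called *pleiotropic* when at least one trait is
genome-wide significant and the other passes the pairwise threshold
alpha / (T_total x L), with T_total the number of traits in the study and
L the number of unique lead SNPs; *single-trait* when only the genome-wide
condition holds; *not-significant* otherwise.

The two-GRM variance partition fits y = mu + g_lead + g_background + e by
the same AI-REML machinery on full matrices: one GRM from the lead SNPs
only, one from all variants outside a window around each lead.  The
window is read as lead +/- 1.25 Mb (total width 2.5 Mb); a +/- 2.5 Mb
option exists because the intended half-width is genuinely ambiguous.
The reported fraction v_lead / (v_lead + v_background + v_residual)
mirrors the V(lead SNP)/V(DRP) summary of such studies; its SE comes from
the inverse average-information matrix by the delta method.

## Synthetic cohorts (`simdata`)

Genotypes are built per LD block from simulated haplotypes: the first
variant of a block is drawn at the block allele frequency, each later
variant copies its left neighbour with probability sqrt(r2) and redraws
otherwise, and haplotypes are paired into diploids.  All variants in a
block share one allele frequency (drawn per block from `maf_range`),
which makes any target r2 attainable and keeps the marginal frequency
exactly stationary; across blocks haplotypes are independent, so expected
between-block r2 is zero.  The generator does not attempt coalescent
realism: no recombination maps, no allele-frequency/LD coupling, no
imputation error.  Passing tests therefore demonstrate correctness of the
estimators under block-structured LD, not robustness to every feature of
real sequence data.

Phenotypes are y_t = sum_k beta_kt x_k + u_t + e_t.  The polygenic term
draws per-variant effects on standardized doses jointly across traits
from the specified genetic covariance; each trait's polygenic column is
rescaled so its realized variance equals the specification exactly (LD
between background variants would otherwise inflate it), which preserves
the trait-trait correlations.  Residuals are independent Gaussians.  This
emulates high-reliability DRP pseudo-phenotypes; a helper converts a DRP
reliability r2 into the implied noise variance (default 0.9 — the
reliability of the real proofs is not published, so it is a free knob).
Causal loci are declared as pleiotropic (one variant, >= 2 traits),
linked pairs (two variants in one block, each one trait, achieved r2
reported back), or single-trait; invariants are enforced at construction.
A master seed spawns independent per-stage streams, and identical seeds
give bit-identical cohorts.

## Benchmark battery (`experiments`) and problem sizes

The battery in `pleioscan.experiments` is the package's evidence that the
stages behave as claimed; `scripts/acceptance.py` re-runs it from scratch.
Problem sizes are the package's choices for a single-CPU run of a few
minutes:

- **Null calibration**: 3 pure-noise traits with residual correlation
  0.5, n = 2000, 10,000 unlinked variants, LOCO mixed-model scans.  V is
  estimated without the |t| < 2 restriction here: under a global null
  every variant is null, and the restriction only adds estimator noise
  that a 10,000-variant KS test can detect.  chi2_MT is compared with
  chi2(3) by KS; single-trait type-I error is measured at p < 0.05.
- **Power ordering**: 200 pleiotropic variants (10 cohorts x 20), equal
  effects on 3 traits (1% of variance each), residual correlation 0.5,
  n = 2000, plain least-squares scans (no polygenic background is
  simulated, so a mixed model has nothing to absorb).  The multi-trait
  detection rate at the Bonferroni threshold is compared with the best
  single-trait scan's rate.  The reference is the best individual trait
  scan, not a per-variant min-p over traits — the latter is a different
  combined test and provably beats the chi-square under this effect
  pattern.
- **rg recovery**: one panel (n = 1500, 3200 variants in blocks of r2 0,
  0.3, 0.6, 0.9), 50 replicates of shared causal effects with rg = 0.78
  and h2 = 0.5; coverage of the truth within 2 jackknife SEs.  The rg
  ratio is heavy-tailed at desk scale, so observed coverage sits near,
  not comfortably above, the nominal level.
- **Partition recovery**: n = 800, five lead SNPs jointly explaining 25%
  of variance, background 25% outside +/- 1.25 Mb exclusion windows, 25
  replicates, coverage within 2 delta-method SEs.
- **Discrimination**: n = 800 with per-variant effects scaled to preserve
  the non-centrality of a ~3000-sample cohort with 1%-variance QTL
  (3.75% at this n); 60 replicates per scenario; linked pairs at r2 ~ 0.3;
  polygenic background h2 = 0.3; genome-wide threshold for the scanned
  panel and the pairwise threshold of a 4-trait, 106-lead study.  The
  verdict-rate gap between the pleiotropic and linked scenarios is the
  package's core discrimination measure.

## Numerical choices and degenerate inputs

- p-values are floored at 1e-300 to stay in (0, 1]; ranking of extreme
  signals uses `neglog10p` computed from log survival functions.
- REML convergence: |delta restricted log-likelihood| < 1e-8 (bivariate),
  200-iteration cap with the trajectory carried in the error.
- Monomorphic variants: always removed by QC, skipped by the GRM, scored
  l = 1 by the LD-score code.
- Duplicate variant positions are rejected at region definition (boundary
  ties would otherwise be ambiguous).
- Identity-GRM fits flag non-identifiability instead of failing.
- Shrinkage of V and the [-1.25, 1.25] rg clamp are reporting safeguards;
  both are flagged in the returned objects.

## Known limitations

- The simulator's LD is blockwise-stationary with a single frequency per
  block; real sequence data couple frequency and LD and have long-range
  structure the tests do not probe.
- LDSC here is the minimal estimator (single-pass weights, physical
  window, free intercept); absolute h2 estimates at desk scale are noisy,
  and only ratio quantities (rg) are benchmarked.
- The bivariate model handles exactly two traits and complete cases, and
  the Wald tests assume large-n normality of the effect estimates.
- Multi-trait meta lead SNPs come from distance clumping; no conditional
  multi-trait analysis is defined.
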