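# Methods

## The estimator

A GWAS over k LD-pruned (approximately independent) SNPs reports, for SNP
i, a z-statistic `z_i = beta_i / se_i`.  We model `z_i ~ N(delta_i, 1)`,
where `delta_i = beta_true_i / se_i` is the standardised true effect, and
treat the `delta_i` as draws from an arbitrary, unspecified prior.  The
observed statistics of the top SNPs overstate their true effects (winner's
curse), so summing naively converted `z_i^2` overestimates heritability.

Tweedie's formula gives the posterior mean of the true effect using only
the *marginal* density f of the observed z:

    E[delta | z] = z + f'(z) / f(z).

No assumption about the prior on delta is needed; everything rests on
estimating f and f' well.  With `delta_hat_i = E[delta | z_i]`, the
variance explained by SNP i of a continuous trait follows the ANOVA
identity for simple regression,

    Vg_i = delta_hat_i^2 / (n - 2 + delta_hat_i^2),

and total SNP-based heritability is `Vg = sum_i Vg_i`.  For binary traits
the corrected log-odds `delta_hat_i * se_i` is mapped to the
liability scale via a probit approximation,
`tau_1 = beta * K(1-K) / phi(Phi^-1(1-K))` with prevalence K, standardised
by the allele-count SD `sqrt(2*MAF*(1-MAF))`, and squared; the liability
variance is taken as 1.  The conversion is validated by a
liability-threshold forward simulation (recovery within 20% at
Vg = 0.01, K = 0.1, n = 50,000) rather than by a formula claim.

A conditional variant `E[delta | z, H1] = E[delta | z] / (1 - fdr(z))`,
with the local false discovery rate `fdr(z) = pi0 * f0(z) / f(z)`,
converts the conditional effect and weights each SNP by `1 - fdr`.  It is
exposed but not the default: it inherits the sampling noise of per-SNP
fdr estimates, and the unconditional estimator is the one whose operating
characteristics the simulation study documents.

## Density estimation

f and f' are estimated by a Gaussian-kernel KDE with an *analytic*
derivative (never finite differences).  Above 5,000 points the sample is
linearly binned onto a uniform 2^14-point grid spanning the data padded
by 4 bandwidths, convolved (FFT) with the kernel and its derivative, and
interpolated linearly at the observed z; below that, exact O(n^2)
summation is used.  Binned and exact evaluation agree to ~1e-3 relative.
Queries outside the grid fall back to the exact kernel sum.  f is floored
at 1e-12 before division so far-tail z cannot produce unbounded
corrections; floored evaluations are counted and logged.

Bandwidth rules:

* `silverman` (default): `0.9 * min(sd, IQR/1.34) * n^(-1/5)`.
* `sheather_jones`: the Botev fixed-point (DCT) formulation of
  Sheather-Jones plug-in selection.
* `deriv_reference`: `sigma_robust * (0.8/n)^(1/7)`, the normal-reference
  bandwidth that minimises the asymptotic MISE of the *derivative*
  estimate -- about 1.9x Silverman at n = 1e5.
* `fixed`: user-supplied.

The choice matters and is genuinely open: the correction consumes
`f'/f`, whose noise shrinks like `1/(n h^3)`, so a derivative-optimised
(wider) bandwidth tracks the closed-form correction more tightly and
collapses pure-null panels harder (mean |corrected| ~0.04 vs ~0.08 under
Silverman at n = 1e5).  Silverman remains the default because the
package's simulation benchmarks -- the variability of the total-Vg
estimate and the resampling SEs it is designed to quantify -- are driven
by exactly that correction noise, and the wider bandwidth suppresses it
several-fold, which understates the SEs relative to the documented
operating characteristics.  The rule in force is recorded in every run
manifest.

pi0 for the local fdr defaults to central matching at zero,
`pi0 = min(1, f(0)/phi(0))`, with a fixed-pi0 override; the null is the
theoretical N(0,1) or, optionally, a normal matched to the sample's
median and IQR.  No spline-based (Poisson-regression) density or
empirical-null mean/variance machinery is included.

## Standard errors

Five SNP-level resampling schemes, each re-running the full pipeline
(density refit included) per replicate:

* delete-1 jackknife, `se = sqrt((k-1)/k * sum_i (theta_i - theta_bar)^2)`;
  by default m = 200 leave-one-out indices are subsampled and the same
  plug-in applied (exact mode available) -- enumerating 1e5 refits buys
  little, as the subsampled and exact SEs agree closely;
* delete-d jackknife, d = k/5 by default, m = 200 random deletion sets,
  `se = sqrt((k-d)/(d m) * sum_v (theta_Sv - theta_bar)^2)`; preferred for
  non-smooth statistics;
* parametric bootstrap (`paraboot`): `z* ~ N(delta_hat, 1)`;
* `fdrboot1` / `fdrboot2`: each SNP is resampled from `N(mean, 1)` with
  probability `1 - fdr` (mean = observed z, resp. corrected delta_hat)
  and from N(0,1) otherwise; fdr values come from the original fit, and
  membership is redrawn per SNP per replicate; bootstrap SEs use the
  sample SD with denominator B-1.

Replicates run on deterministic child streams of the method seed
(mixture-membership and noise draws on separate streams, so `fdrboot2`
with fdr = 0 reproduces `paraboot` bit-for-bit).

## Confidence intervals

Standard normal-approximation CIs use the delete-d SE (one uncorrected,
three corrected by the bootstrap bias `mean(theta*) - theta_hat`, one per
bootstrap flavour); percentile CIs use each bootstrap's replicate
quantiles (type-7 linear interpolation), uncorrected and reflected about
the estimate (`2*theta_hat - q`).  Union CIs take the min lower / max
upper bound within the standard family, within the percentile family, and
across both.  Bounds are not clipped to [0,1] by default (clipping is a
presentation flag): the documented coverage behaviour belongs to the
unclipped intervals.

## Synthetic data

`simulate_panel` emulates a quantitative-trait GWAS: k = 100,000
independent SNPs, 0.5% non-null; per-SNP variances for the non-null SNPs
are Gamma(shape 0.5, scale 1) draws rescaled so the true total is hit
exactly; `delta_i = +/- sqrt(vg_i (n-2)/(1-vg_i))` with random signs;
`z_i = delta_i + N(0,1)`.  The gamma shape is configurable (0.5 chosen
once as a realistically long-tailed architecture: a few SNPs of large
effect over a polygenic background; the mean estimate moves by <8% for
shapes between 0.2 and 5).  What this does *not* emulate: residual LD
between SNPs, per-SNP sample-size heterogeneity, population
stratification, binary traits, or selection of top SNPs -- passing
simulation benchmarks therefore says nothing about robustness to LD
mismatch or confounding in real summary files, only about the estimator's
sampling behaviour under independence.

Study drivers report the mean estimate and its empirical SD ("true" SE,
100 outer replicates by default), per-method SE bias/variance/RMSE
(population-variance convention, so `rmse^2 = bias^2 + variance` exactly),
and union-CI coverage.  Desk-scale coverage runs use a proportionally
shrunk panel (k and the Vg target scaled together, preserving per-SNP
signal strength).

## Numerical and design notes

* Panel-level n: with a per-SNP n column, the median is used and a >10%
  spread triggers a warning; the conversion formulas use one n.
* Duplicate SNP ids: first occurrence wins; non-finite rows are dropped
  with logged counts.
* Tweedie overshoot is not clamped; only the density floor guards the
  division.
* All report files embed a hash of the effective configuration; a fixed
  seed reproduces every number bit-for-bit.
* Known limitations: no LD modelling (input must be pruned; block
  resampling is out of scope), no partitioned heritability, no BCa or
  studentised intervals, and small-sample (n < ~5000 or k < ~1e4)
  behaviour of both the estimate and its SEs is undocumented here and
  should be treated with caution.
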