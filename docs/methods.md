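# Methods

This note documents the models, conventions, and design choices behind the
package, in the spirit of a statistical-software methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

The generator is the package's study system: it plants, in a fully known
way, every association the downstream analysis is designed to detect.  All
randomness flows through named substreams of one seed, so a
`(config, seed)` pair reproduces a cohort bit for bit.

**Covariates.** Age ~ N(120, 9.6) months (median 120, IQR ≈ 13); sex,
race, ethnicity as Bernoulli indicators (0.52/0.67/0.20); six-level income
and caregiver-education ordinals cut from latents sharing a socioeconomic
factor (loading 0.8 each), which makes their rank correlation positive by
construction; BMI ~ N(18.5, 3) truncated at 12; family size 2 + Poisson(2);
five-level family-togetherness ordinal; site uniform over `n_sites`;
motion-censored fraction uniform on [0, 0.10] (runs above 10% censoring are
treated as already excluded).

**Ordinal beliefs.** Each of 7 religious and 3 family-values items is a
five-level cut of a latent normal
λ_R·factor + λ_inc·z(income) + λ_edu·z(education) + unique noise, with
λ_R = 0.6 and λ_inc = λ_edu = −0.15 by default (lower SES → stronger
beliefs).  Religious items share a religiosity factor; family items share a
second factor correlated 0.4 with it, so the two belief types are positively
associated.  Service attendance (0–4) and importance (1–4) load 0.75 on the
religiosity factor.  Cut points are fixed normal quantiles chosen to give
skewed, realistic response margins; with all loadings zero the level
proportions reduce to the cut-point design.

**Topology effect.** Each subject carries a true within-network correlation
for one targeted (network, hemisphere):
ρ_s = ρ_within − Δ·(belief−1)/4 + η_s, η_s ~ N(0, σ_ρ), with
Δ = d_target·σ_ρ.  Cohen's d between belief levels 5 and 1 on the *latent*
property is therefore exactly `belief_topology_d`.  The measured property
(median within-network connectivity from finite time series) adds
estimation noise, which attenuates the empirical d by the factor
σ_ρ/√(σ_ρ² + σ_err²); at the defaults (σ_ρ = 0.06, T = 200) the
acceptance script measures ≈ 0.21–0.26 for a planted 0.3 — inside the
0.2–0.4 band the analysis targets.  Defaults: 100 parcels in 8 named
networks per hemisphere, ρ_within = 0.35, ρ_between = 0.10.

**Signals.** Zero-mean Gaussian with an equicorrelated block covariance
(unit diagonal), sampled via Cholesky after a positive-definiteness check;
an over-large decrement raises a generation error rather than silently
clipping structure away.  Subjects get `n_runs_per_subject` runs; the last
run receives an additive *common* component shared by all parcels, emulating
a global artifact that inflates pairwise correlations.  Selecting the run
with the lowest median connectivity therefore avoids the contaminated run,
which makes run selection non-trivial and mirrors how motion inflates
connectivity in real recordings.

**Scores.** On the standardized scale,
y = c′·z_b + b·z_m + m·(z_b·z_m)⊥ + γ_inc·z_inc + ε, mapped to the task
scale as 97 + 14.08·y (median ≈ 97, IQR ≈ 19).  The belief×mediator product
is residualized against the main effects before scaling: belief levels are
skewed, so the raw product correlates with them and would bias the planted
main effects; after orthogonalization the planted coefficients are exact
*partial* standardized effects, which is what the path models estimate.
With `noise_sd = None` the residual SD is set so Var(y) = 1, making planted
betas exact population standardized coefficients (long-run ±2·SE coverage
of all three path coefficients is 95–97%).  A second score with no belief
effect serves as a negative control.  Defaults: a = −0.15, b = +0.15,
c′ = −0.10, moderation −0.08 (f² ≈ 0.01, inside the "small" band).

**Matrix mode vs time-series mode.** Matrix mode emits the standardized
mediator directly (a·z_b + √(1−a²)·ε), which makes statistics-only
calibration experiments fast; time-series mode routes the belief effect
through the block covariance so the full connectivity→metric path is
exercised.  Statistical calibration uses matrix mode; the topology-effect
recovery uses time-series mode.

## Connectivity

* **Peak cross-correlation.** For each pair, ρ(τ) is the Pearson
  correlation of the overlapping segments (mean-centered and renormalized
  per lag); the stored value is the signed ρ at the τ ∈ [−L, L] maximizing
  |ρ|, tie-broken toward the smallest |τ| and negative before positive.
  Default L = 5 samples; L = 0 reduces exactly to the Pearson matrix.  Note
  that maximizing over lags right-shifts the null distribution (the maximum
  of ~2L+1 noisy correlations), which makes the population threshold more
  conservative at short run lengths.
* **Mutual information.** Plug-in estimate (nats) from an equal-width
  16-bin 2-D histogram — deterministic and oracle-checkable; it carries the
  usual small positive bias for independent signals.
* **Thresholding.** Per-subject outlier level q_s = median + 1.5·IQR of the
  upper-triangle values; the population threshold is the normal-theory upper
  95% confidence bound mean(q) + 1.96·sd(q)/√n (a percentile-bootstrap
  variant is available).  Signed values below threshold — including all
  negative correlations — are zeroed; a flag switches to thresholding |v|.

## Graph metrics

Conventions follow the common brain-connectivity toolboxes: efficiency on
1/weight path lengths (unreachable pairs contribute 0; binary view uses hop
counts); clustering and degree on the binary view by default (weighted
geometric-mean variant behind a flag); spectral metrics (natural
connectivity via log-sum-exp of eigenvalues, λ_max, eigenvector centrality
scaled to unit maximum) on the weighted adjacency.  Modularity is the
weighted Newman–Girvan Q, optimized by exhaustive partition search for
graphs with ≤ 8 nodes (guaranteed optimum at oracle scale) and by seeded
Louvain above.  Small-worldness uses 20 degree-preserving rewired nulls by
default (10 in the demo pipeline), is computed on the binary view, and is
restricted to the largest connected component with a flag when the graph is
disconnected.  Undefined quantities (empty scopes, edgeless graphs, no
connected triples) are NaN, never silent zeros.  Median connectivity is
computed on the *raw* (pre-threshold) values to avoid threshold-induced
zero inflation; a thresholded variant sits behind a flag.

## Inference layer

Continuous outcome and predictors are z-scored before fitting (binary and
dummy terms untouched), so coefficients are standardized betas; rescaling
any continuous column leaves betas and p-values unchanged.  Missing rows
are dropped listwise and `n_used` reported; rank-deficient designs raise an
error naming the aliased columns.  All paths share one covariate set (age,
sex, race, ethnicity, income, BMI, togetherness, family size, plus the
propensity-style site term); models touching a network property add the
motion-censored fraction.  The indirect effect is a·b with a from Path B
and b from the full model (Path D); classification is *partial* when both
the Sobel test and the direct path are significant at α = 0.05, *full* when
only the indirect is.  FDR families group the primary-predictor p-values of
one belief item's path models (BH for the independence assumption, BY for
dependence).  Site adjustment fits a multinomial logistic model of site
membership on demographics and appends each subject's own-site predicted
probability as a covariate (an inverse-probability-weight variant was
considered and left out as the covariate form is the simpler default).
Moderation codes belief levels 2–5 as dummies against level 1, with
property×dummy interactions; the simple slope at level ℓ is
β_prop + β_int(ℓ) with a delta-method SE, the overall interaction is an
F-test of all interaction terms, and levels observed fewer than 10 times
are flagged rather than dropped.  Split-sample validation draws seeded
75/25 splits, fits on the training split on the raw outcome scale, and
reports per-repeat CV(RMSE) = RMSE/|mean observed test outcome| (a
range-normalized variant exists behind a flag); a near-zero normalizer
yields a per-repeat NaN with a count, not a crash.

## Problem sizes and numerical choices

Calibration experiments use 200 all-null replicate cohorts of n = 500,
power/recovery over 50–100 seeds at n = 2000, and topology-effect recovery
on time-series cohorts of n = 2000 (100 parcels, T = 200, 2 runs), which
keeps the whole suite and acceptance script in the minutes range on one
CPU.  The demo pipeline uses 40 parcels, T = 150, n = 120–300.  Eigenvalue
computations use symmetric dense solvers; the exhaustive modularity bound
(8 nodes, Bell(8) = 4140 partitions) keeps exact search affordable;
percentage rounding is decimal half-up to two places, matching how cohort
tables are printed.

## What the synthetic cohort does and does not show

The generator reproduces the *statistical* structure the analysis assumes —
ordinal skew, SES gradients, block-structured connectivity, small planted
effects, artifact-contaminated runs — but not scanner physics,
hemodynamics, spatial atlas geometry, autocorrelated BOLD noise, or
motion's spatially heterogeneous signature.  Passing tests therefore
demonstrate that the pipeline recovers known structure with calibrated
error rates under its own assumptions; they do not validate those
assumptions against real recordings, and effect estimates on real data
would additionally be attenuated by preprocessing and measurement choices
upstream of this pipeline.  The secondary latent-variable (structural
equation) analysis of the source study is out of scope.
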