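# fcmediation

Multiscale topology of resting-state functional brain networks, and
mediation/moderation of ordinal-belief effects on cognitive task scores — a
tested, reusable reimplementation of a connectome-survey analysis pipeline,
exercised end to end on a synthetic cohort generator.

## The problem

Large developmental-cohort studies relate a caregiver-reported ordinal
exposure (here, strength of belief on a 1–5 scale, "not at all" … "completely")
to (i) the topological organization of a child's resting-state functional
brain networks and (ii) cognitive task scores, asking whether the
brain-network effect *mediates* or *moderates* the belief–cognition
relationship.  The pipeline covers every step after parcellation:

1. **Connectivity** — per subject/run, pairwise association between parcel
   BOLD signals by peak lagged cross-correlation (signed value at the lag
   τ ∈ [−L, L] maximizing |ρ(τ)|; L = 0 recovers Pearson) or plug-in
   histogram mutual information.  The analysis run is the one with the
   lowest overall median connectivity.  A population threshold — the upper
   95% confidence bound of the per-subject outlier level
   q_s = median + 1.5·IQR, i.e. mean(q) + 1.96·sd(q)/√n — converts
   connectivity into nonnegative weighted adjacency matrices.
2. **Graph metrics**, at whole-brain, per-(network, hemisphere), and node
   scale: global efficiency E = ⟨1/d(i,j)⟩, transitivity, weighted
   Newman–Girvan modularity Q, small-worldness
   σ = (C/C_rand)/(L/L_rand) against Maslov–Sneppen degree-preserving
   nulls, natural connectivity ln((1/N)Σ e^{λ_k}) (robustness), largest
   adjacency eigenvalue λ_max (stability), eigenvector centrality, degree,
   local clustering, and within/outside-network median connectivity.
3. **Inference** — covariate-adjusted standardized OLS for the mediation
   diagram (Path A: belief→score; B: belief→property; C: property→score;
   D: full model), Sobel test z = ab/√(b²se_a² + a²se_b²) of the indirect
   effect, ordinal moderation with level dummies (reference "not at all"),
   simple slopes and f² = (R²_full − R²_reduced)/(1 − R²_full), Cohen's d
   with df-weighted pooled SD, Benjamini–Hochberg / Benjamini–Yekutieli FDR,
   propensity-style site adjustment, and 75/25 split-sample validation
   (100 repeats) scored by CV(RMSE) = RMSE/|mean observed outcome|.

Because the source cohort data are access-restricted, the package ships a
**synthetic cohort generator** that plants exactly the statistical structure
the analysis assumes — SES-dependent ordinal beliefs (latent-normal
cut-point model), belief-modulated block-covariance parcel signals, and
scores with direct (c′), indirect (a·b) and moderated belief effects — so
every stage is testable and calibrated without any download.

## Worked example

```bash
python analysis/04_mediation_moderation.py --seed 0
```

fits the path models on an n = 2000 synthetic cohort with planted effects
a = −0.15, b = +0.15, c′ = −0.10 and negative moderation, and prints:

```
path                     term     beta     se      p  p_fdr
   A                belief_r2  -0.0921 0.0227 0.0001 0.0001
   B                belief_r2  -0.1308 0.0228 0.0000 0.0000
   C  net__..__median_conn_in   0.1787 0.0218 0.0000    NaN
   D                belief_r2  -0.0693 0.0225 0.0021 0.0021
indirect a*b = -0.0222; Sobel z = -4.61, p = 4e-06; classification: partial
moderation: interaction p = 4.3e-08, f^2 = 0.0204
```

Reading: stronger belief predicts a lower network property (Path B,
β = −0.13) and lower scores directly (Path D, β = −0.07); the property
predicts scores positively (Path C, β = +0.18), so the belief effect on
cognition is *partially mediated* through network topology (Sobel p < 0.05
with the direct path still significant), and the property→score slope
flattens at high belief levels (negative moderation, small f²).  The other
drivers follow the same pattern: `01` cohort margins,
`02` connectivity/threshold, `03` topology contrasts (Cohen's d for the
targeted network's properties, level 5 vs level 1), `05` split-sample
CV(RMSE).  A single command runs everything end to end:

```bash
fcmediation pipeline --seed 1 --out runs/demo
```

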