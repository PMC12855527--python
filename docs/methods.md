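# Methods

## Data model and conversions

The corpus is a flat table, one row per effect size: an SMD comparing an
atypical CYP metaboliser group against normal metabolisers, its sampling
variance, the study it came from, and moderator labels (proximal/distal
outcome class, drug, drug class, enzyme, metaboliser phenotype, continent).
CSV is the canonical format (UTF-8, header row, empty string = missing).
Outcome labels are normalised case-insensitively and must resolve to
proximal/distal — they drive the primary model, so an unmappable label
rejects the row rather than guessing.  Phenotype labels that cannot be
mapped become "unknown"; such rows stay in the corpus but are excluded from
the phenotype-interaction analysis.  Exact duplicate effects are flagged in
the provenance but retained, since a legitimate study can report the same
numeric comparison twice.

Conversions to the SMD scale follow a fixed order of preference — group
means/SDs, median+IQR, odds ratio, t statistic — because later paths carry
more approximation error:

* means/SDs: Cohen's d with the pooled (df-weighted) SD; sampling variance
  `v = N/(n1 n2) + d²/(2N)`.  The Hedges small-sample factor
  `J = 1 − 3/(4 df − 1)` is available behind a flag but off by default (the
  plain d convention).
* median+IQR: Wan recovery, `mean = (q1 + med + q3)/3`,
  `sd = IQR / (2 Φ⁻¹((0.75n − 0.125)/(n + 0.25)))`.  Only the median+IQR
  scenario is implemented; min/max variants are out of scope.  The SD bias
  of this recovery is relative (≈3% at group n = 50, shrinking with n), which
  bounds the SMD round-trip error in the tests.
* odds ratio: the logistic-distribution conversion `d = ln(OR)·√3/π`, with
  the variance mapped by the squared factor; exactly invertible.
* t statistic: `d = t·√(1/n1 + 1/n2)` with the same variance formula.

Records whose variance cannot be derived (no variance, no group sizes) are
rejected at ingestion: every downstream weight needs a variance.  Extreme
effects are filtered with an inclusive boundary — |SMD| ≥ 5 is removed, the
strict interior kept.

## The CHE model and its estimation

The working model is described in the README.  Two details matter for
faithfulness:

* the "random slope for the outcome moderator with unstructured covariance"
  is realised as outcome-class-specific study random effects
  (τ²_prox, τ²_dist, correlation ρ_τ): this is the only structure that
  yields separate between-study variances per class, which is how results
  are reported.  ρ_τ is estimated but has no external reference value.
* the sampling covariance V is imputed blockwise with constant within-study
  correlation ρ (default 0.6; sensitivity grid {0.2, 0.4, 0.6, 0.8} run by
  the pipeline).  Subgroup sensitivity fits use the simplified nested
  structure (single study-intercept τ² plus σ²) and the same ρ.

REML estimation log-parameterises variance components and
atanh-parameterises ρ_τ, then maximises the restricted log-likelihood with
L-BFGS-B (ftol 1e−12; up to three jittered restarts).  The likelihood
factorises over study blocks; blocks of equal size are stacked and evaluated
with batched Cholesky factorisations, which keeps a 200-study fit under a
second.  Components can be pinned (`fix_components`), which yields the
closed-form GLS/fixed-effect special cases used as oracles, and profile
likelihood traces (each grid point re-optimises the remaining components).
A profile whose log-likelihood range over its grid is below 0.1 is flagged
non-identifiable — the single-effect-per-study degenerate case produces
exactly this flat τ²/σ² ridge.

The absolute-SMD response uses the raw sampling variance unchanged (no
folded-normal correction).  The intercept model's reference level is
proximal, so its second coefficient is distal − proximal.  Prediction
intervals are `estimate ± crit · √(SE² + τ²_class + σ²)` with a normal
critical value by default (t on request), never truncated at zero even for
an absolute response.

## Robust inference

CR2 adjustment matrices are `A_j = U_j (U_j G_j U_j)^{−1/2} U_j` with
`U_j = C_j^{1/2}` (symmetric PSD square roots, eigenvalues floored at 1e−10
of the largest) and `G_j = C_j − X_j M X_j'` the working-model residual
covariance; this makes each cluster's adjusted residual cross-product
unbiased for its true covariance when the working model is right, and
reduces exactly to HC2 on singleton clusters with identity weights.
Satterthwaite degrees of freedom for a contrast w use the covariance of the
per-cluster score contributions under the working model:
`df = (Σ_j t_jj)² / Σ_jk t_jk²` with
`t_jk = p_j'(C_j δ_jk − X_j M X_k') p_k`, `p_j = A_j W_j X_j M w` — the
standard bias-reduced-linearisation df, not a clusters-minus-p rule.

Holm families follow the reporting layout: the six pairwise phenotype
comparisons within each outcome class form one family per class (m = 6),
and the four proximal-vs-distal comparisons (one per phenotype) a third
family (m = 4).

## Bias diagnostics

Funnel exports plot the signed SMD against 1/√N; the formal small-study test
adds 1/√N as a moderator to the same CHE model used for the primary analysis
and tests its coefficient with CR2 robust inference.  A response switch runs
the test on signed SMDs instead.  Null calibration and power against planted
small-study inflation (effects shifted by c/√N) are verified by simulation
in the acceptance tests.

## Power planning

Exact noncentral-t power: df = 2n − 2, noncentrality d√(n/2), two-sided
α = 0.05 by default.  Sample sizes solve the continuous power equation by
bracketed root finding and round **up** — "required to attain" a power floor.
One reference value is worth noting: at d = 0.278 the continuous root is
204.08, so the solver returns 205; matching a published 204 for that effect
size requires an unrounded input slightly below 0.278.  The retrospective
audit computes, per outcome class, the share of corpus effects whose
per-group n (= N/2) yields power below 80% at the class's pooled effect.

## Winner's-curse shrinkage

Observed z-scores are modelled as `z = μ + ε`, `ε ~ N(0,1)`, with the true
signal-to-noise ratio μ drawn from a zero-mean normal mixture.  The mixture
is fitted to the z marginal (component variances `s_k² + 1`, floored at 1)
by EM with a deterministic initialisation: component SDs {0.5, 1.5, 4}
scaled by the sample SD of z, equal weights, three components by default;
collapsed components trigger a refit with one fewer.  Posterior means are
conjugate: `E[μ|z] = Σ w̃_k(z) · z s_k²/(s_k² + 1)` with
`w̃_k(z) ∝ w_k N(z; 0, s_k²+1)`.  The exaggeration ratio is `z / E[μ|z]`
(≥ 1 for any zero-mean mixture prior); the class summary is the unweighted
mean ratio over the class's observed nonzero z-scores.  z-scores are
computed from signed SMDs — shrinking a folded quantity is ill-defined — so
shrinkage analyses should use signed corpora.  The supplementary formulae
behind the published shrinkage means are not public, so every choice
(component count, initialisation, averaging) is configuration-exposed and
the published means are treated only as a qualitative ordering check.

## Synthetic corpus generator

Defaults encode the literature's shape: 184 studies; effects per study
1 + Poisson(10.4) (mean ≈ 11.4, matching ~2,100 effects from 184 studies);
56% proximal effects; class means 0.481/0.278 on the absolute-SMD scale;
τ² 0.062/0.017 with ρ_τ = 0.5 (the study-level correlation between a
study's proximal and distal deviations has no published value; 0.5 encodes
that a study's two outcome families share design and population); σ² =
0.164; sampling correlation 0.6; total N log-uniform on [20, 400] (split
evenly between groups); phenotype mix 25.5/48.2/6.7/19.6% over
poor/intermediate/rapid/ultrarapid; drug/enzyme/continent labels drawn at
study level with literature-like frequencies.

Generation per study: correlated class deviations (b_prox, b_dist) from the
2×2 covariance T; per effect a class label, an effect-level deviation, a
sample size, and a sampling variance computed from the SMD variance formula
**at the local truth** θ_i; within-study sampling errors drawn jointly with
correlation ρ.  Recording the variance at the local truth (rather than at
the observed draw) keeps the weights independent of the noise; the small
residual dependence of v on the study's random effects still biases the
weighted mean down by ~2–4%, which is inherent to SMD weighting and stays
within the 10% recovery tolerance.  Per-study seed sequences derived from
the single config seed make corpora reproducible and append-stable.

The generator draws the model's response directly on the absolute scale, so
generated "smd" values are already the absolute-SMD response (occasionally
negative, as the normal working model implies).  Fitting generator output
therefore uses the identity (`signed_smd`) response; re-applying the
absolute-value transform would fold the negative tail and bias estimates
upward.  A `signed` flag attaches random signs for funnel and shrinkage
testing.  What the generator does **not** emulate: publication selection,
heterogeneous outcome measurement error, non-normal effect distributions,
and real genotype→phenotype structure — so passing recovery tests shows the
estimator is correct under its own assumptions, not that those assumptions
hold in the real literature.

## Problem sizes used in the test suite

Parameter recovery uses 100 replicate corpora of 200 studies; Wald type-I
calibration 2,000 null replicates of 30 studies (~3 effects each); Egger
calibration 1,000 null replicates and 200 planted-bias replicates.  These
sizes give Monte-Carlo standard errors comfortably inside the acceptance
bands while keeping the whole suite to a few minutes on one CPU.

## Known limitations

* The CHE fit offers REML only (no ML, no Bayesian estimation).
* Only CR2 among the small-sample cluster-robust corrections; no
  permutation tests.
* No trim-and-fill, selection models or p-curve for publication bias.
* Power planning covers equal-allocation two-sample t-tests only.
* Shrinkage returns point posterior means, not full posteriors.
* ρ_τ is weakly identified in small corpora and can sit on the ±1 boundary;
  the fixed effects are insensitive to this (the ρ-sensitivity grid and
  profile traces are the intended diagnostics).
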