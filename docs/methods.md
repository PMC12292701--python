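# Methods

## Screening model

Every method in this package is a *marginal* screen: given a predictor array
`X ∈ R^{d×n×p}` (d platforms, n samples, p features) and a response
`Y ∈ R^{n×q}`, it computes one dependence score `ω_j` per feature from the
`n × d` block `X_j` and the full response, ranks features by descending
score, and keeps the top `s = ⌊n / ln n⌋`.  No joint model is fitted;
collinearity between features is irrelevant by construction, and the
approach scales linearly in p.  Ranking ties are broken by ascending feature
index so that results are reproducible across runs and platforms (success
rates are tie-sensitive in principle).  The multi-method "consensus" is the
plain intersection of each method's top-s set, reported in feature-index
order.

## Dependence measures

**Distance correlation (DC-SIS).**  The empirical (V-statistic) version:
pairwise Euclidean distance matrices are double-centered
(`A_kl = a_kl − ā_k· − ā_·l + ā_··`) and
`dCor² = mean(A∘B) / sqrt(mean(A∘A)·mean(B∘B))`, all means over the full
n×n grid.  We return the nonnegative square root, and 0 when either block
is constant.  The production kernel never materialises `A`: double-centering
is an orthogonal projection, so `mean(A∘B) = mean(a∘B)` when `B` is already
centered, and `mean(A∘A) = mean(a²) − 2·mean(rowmeans(a)²) + grandmean(a)²`.
A compiled (numba) loop exploits the symmetry of `a`; a vectorised
Gram-matrix fallback gives identical results without numba.  Both paths are
tested to 1e-10 against a literal-transcription brute-force oracle.

**Projection correlation (PC-Screen).**  `sup |Corr(uᵀX, vᵀY)|` over unit
vectors, approximated by maximising over K sampled directions per side
(default K = 100, drawn uniformly on the unit sphere from a caller-supplied
seed).  A univariate side has only the directions ±1, which leave the
absolute correlation unchanged, so it is handled exactly without sampling;
with both sides univariate the score is exactly `|Pearson r|`.  Degenerate
projections (zero variance along a direction) contribute 0.  The sampled
maximum is a lower bound on the true supremum that improves with K; K = 100
keeps the K²·n correlation sweep affordable at p = 2000 while staying
within ~0.02 of a dense grid in 2-D experiments.  Because the direction
scheme is a design choice, projection-correlation results carry wider
Monte-Carlo bands than the other two screens.

**Wasserstein dependence (WD-Screen).**  The coefficient

`D1 = (Σ√λ_X + Σ√λ_Y − Σ√λ_joint) / (Σ√λ_X + Σ√λ_Y − Σ_{j≤dx∨q}√(λ_{j,X}+λ_{j,Y}))`

with eigenvalues sorted descending and the shorter marginal list zero-padded
for the denominator pairing.  It measures how far the joint covariance
spectrum falls short of the uncoupled (block-diagonal) one, normalised by
the maximally-coupled extreme; it is 0 exactly when the sample
cross-covariance vanishes and is invariant to common rescaling of the data,
so the covariance divisor is immaterial — we use `n − 1`.  Sample
covariances are PSD only up to roundoff, so eigenvalues below
`1e-12 × λ_max` are clamped to zero before square roots, and the result is
clamped to [0, 1].  A degenerate denominator (both blocks constant) yields
0 with a warning.  In the univariate equal-variance case `D1` is a strictly
increasing function of `|Pearson r|`, so WD-Screen and SIS produce identical
rankings there — the explanation for their identical success rates in the
skewed-predictor benchmark, where feature variances are equal in
distribution.

**Univariate baselines.**  SIS (`|Pearson r|`), SIRS (`|Pearson|` against
average-ranked response), RRCS (|Kendall τ-b|), DC-RoSIS (distance
correlation against the ranked response).  All signed statistics are
returned in absolute value: screening ranks by dependence strength and
response signs are arbitrary.  These baselines require `d = q = 1` and
refuse multi-platform input with an explicit capability error.

Measures receive raw, unstandardized data — real mRNA input is typically
already z-scored, and no standardization step is part of the method.  Data
harmonisation (missing values, matching) happens upstream in `omics_io`;
the measures themselves reject non-finite input.

## Benchmark studies

Four generative scenarios, defaults n = 200, p = 2000, cutoff
`s = ⌊200/ln 200⌋ = 37`, 200 replicates:

1. Predictors multivariate normal, AR(1) covariance `σ_ij = 0.5^|i−j|`
   (generated by the exact recursion `X_j = 0.5·X_{j−1} + √0.75·Z_j`);
   response `y = β₁X₁ + β₂X₂ + β₃X₁₂ + β₄X₁₃ + ε`, `β ~ U(2,5)`,
   `ε ~ N(0,1)`.
2. Predictors i.i.d. power(5) (density `5x⁴` on (0,1), drawn as `U^{1/5}`),
   the same response with weaker `β ~ U(1,2)`.
3. Three platforms — Pareto(shape 10, mode 1) and two power(5) — each with
   AR(1) dependence realised by a Gaussian copula (latent AR(1) normals
   mapped through Φ and the marginal quantile function), stacked to
   `3 × n × p`.  The response is 10-dimensional: components 1–3 load
   linearly (coefficients `U(1,2)`) on features 2, 3, 101, 102, the source
   platform of each loading redrawn uniformly per component; components
   4–10 are pure power(5) noise.
4. As study 3 but each active component is
   `β₁·X[id₁,2]·X[id₂,3] + β₂·X[id₃,101]·X[id₄,102] + ε` — the truths carry
   almost no marginal signal and must be caught through the interaction.

Conventions worth stating because the construction is genuinely open:

- "Multivariate Pareto/power with shared covariance Σ" is realised as a
  Gaussian copula whose latent correlation is the AR(1) matrix; this keeps
  the marginals exact and targets the dependence on the latent (hence rank)
  scale.
- The platform indices `id₁..₄` are redrawn independently for each active
  response component and each replicate; the coefficient vector β is drawn
  once per replicate and shared by the three active components; each
  component has its own N(0,1) noise vector.
- Replicate r derives all randomness from `base_seed + r`, and every
  measure scores the same replicate data — a paired comparison, and
  bit-reproducible for a fixed base seed.

Reported criteria per measure: `Ps` (per-truth probability of ranking within
s), `Pa` (probability that all four truths rank within s; always
`≤ min Ps`), and the distribution of the minimum model size
`S = max` truth rank.

**Problem sizes.**  The test suite and `scripts/acceptance.py` run study 1
at 50 replicates and studies 2–4 at the full 200 (success-rate tolerances
are Monte-Carlo bands of ±0.08–0.15; 200 replicates put the binomial
standard error of a Pa near 0.5 at ≈0.035).

## Multiomics pipeline

Readers accept the cBioPortal tab-delimited dialect (header row of sample
IDs after a `Hugo_Symbol` and optional `Entrez_Gene_Id` column).  CNA
platforms must contain only the codes {−2,−1,0,1,2}; violations are hard
errors naming the gene and sample.  Duplicate gene symbols keep the first
occurrence.  Harmonisation intersects genes across platforms and samples
across platforms and the clinical table (samples without TMB are dropped,
since the response is mandatory), removes genes with any missing value on
any platform, and orders genes and samples lexicographically — the source
ordering is not reproducible, determinism is.  CNA codes enter the screens
as numeric scores −2..2; the distance-, projection- and covariance-based
measures handle the discrete and continuous channels together in one block.
Methylation input is assumed gene-level; probe-to-gene collapsing is out of
scope.

The fixture generator emulates this dialect offline: discrete CNA codes
(mostly neutral), mRNA partially driven by copy number then z-scored per
gene, beta-distributed methylation mildly anti-correlated with expression
for signal genes, and a TMB response that is linear in signal-gene mRNA
with an additional CNA effect (`|β| ~ U(1.5, 2.5)` with random sign, CNA
effect `β/2`, unit noise, floor at 0.01).  At 200 samples × 500 genes this
puts each signal gene's marginal correlation near 0.4 — strong enough that
a correctly wired pipeline recovers all signal genes in the three-method
consensus, weak enough that a broken ranking or harmonisation step fails
visibly.  What the fixtures do *not* emulate: real LD-like correlation among
null genes, platform batch effects, heavy-tailed TMB, or missingness
patterns; passing the recovery test therefore validates the pipeline's
wiring and the screens' relative behaviour, not field performance on TCGA
data, and the published TCGA gene lists are not reproducible without the
original download.

## Numerical conventions and edge cases

- Covariance divisor `n − 1`; eigenvalue clamp `1e-12 × λ_max`; scores
  clamped to [0, 1].
- Constant blocks: correlation-type measures warn and return 0; distance
  correlation returns 0 silently (its variance factor vanishes).
- Ranks of tied response values: average ranks (deterministic).
- `screen` streams features in chunks (default 512), so memory is
  proportional to `chunk × n²`, not to p; p ≈ 20,000 at n ≈ 200 fits
  comfortably on a laptop.
- `cutoff_size(n)` requires n ≥ 3 (the formula degenerates below).

## Known limitations

- The sampled-direction projection correlation underestimates the supremum;
  results depend (mildly) on K and the direction seed.
- The Gaussian-copula reading of "shared covariance structure" is one of
  several defensible constructions for non-Gaussian platform marginals.
- `D1` is covariance-based and therefore blind to dependence with zero
  linear correlation (e.g. a pure quadratic link); in the benchmark's
  interaction study it succeeds because the products of positive-valued
  platform variables retain linear correlation with their factors.
- No FDR control, iterative/conditional screening, or second-stage model
  fitting: the deliverable is the ranked lists and consensus set.
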