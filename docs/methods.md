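# Methods

## Model

`latentgrm` decomposes the covariance of k phenotypes measured on n
unrelated individuals into latent genomic (A) and residual (E) factor
structures.  With trait-major stacking y = vec(Y), the implied covariance
is

```
ΣV = C_G ⊗ G + C_I ⊗ I + C_X ⊗ G^½
C_G = ΛA ΦA ΛAᵀ,   C_I = ΛE ΦE ΛEᵀ,   C_X = M + Mᵀ,   M = ΛE Φcov ΛAᵀ
```

`G` is the genetic relationship matrix; each latent factor's variance is
fixed to one (unit diagonals of ΦA and ΦE), so loadings are on the
trait-SD scale when traits are standardised.  Model families differ only
in the free-parameter masks of ΛA and ΛE:

* **cholesky** — both sides k×k lower-triangular; the saturated baseline.
* **ip** — nA (nE) common factors plus a diagonal block of trait-specific
  AS (ES) factors.
* **ipc / cip** — IP on one side, Cholesky on the other.
* **bifactor_a / bifactor_e** — one general factor loading on every trait
  plus group factors, used to test the independence of identified factors.

### Gene–environment correlation

rGE parameters live in the common-factor block of Φcov; specific factors
never correlate across the A/E divide.  The cross-kernel choice is the
one substantive modelling decision in the package.  Treating the joint
factor-score vector as Gaussian — genetic scores gf ~ N(0, G), residual
scores eh ~ N(0, I), per-individual correlation r between a pair — forces
Cov(gf, eh) = r·G^½, hence the `C_X ⊗ G^½` term.  Two consequences:

* Each trait pair's covariance follows `a·d + e + 2c·√d` across the GRM
  eigenvalue spectrum d.  The three basis functions {d, 1, √d} are
  linearly independent, which is what identifies the A / E / Cov(A,E)
  split.  Folding the cross term into the G and I kernels instead (the
  `"mean"` convention, cross kernel (G+I)/2) leaves positive rGE nearly
  unidentified whenever the residual loading vector is roughly
  proportional to the genomic one, because the cross term is then
  absorbed by the factor variances; we keep that convention available as
  a toggle, together with a `"literal"` convention that assigns M to the
  G kernel and Mᵀ to the I kernel without symmetrisation (that form is
  asymmetric for G ≠ I and `implied_sigma` raises rather than silently
  symmetrising).  All conventions coincide for G = I or rGE = 0 and
  share the per-trait decomposition `V = a + e + 2c`.
* The variance decomposition reported by `standardize` /
  `decompose_variance_rge` treats kernel diagonals as 1 (GRM and G^½
  diagonals are ≈1 for outbred samples): `snp_h2 = a/V`, `e2 = e/V`,
  signed share `2c/V`, and the combined g-related `(a+c)/V` and
  e-related `(e+c)/V` shares, which sum to one.

### Identification conventions

The likelihood is invariant to flipping all loadings of a common factor
(with the matching rGE row/column) and to the sign of any specific
loading or Cholesky column.  The reported representative keeps Cholesky
diagonals and specific loadings non-negative and each common factor's
largest-magnitude loading positive.  Correlation-type parameters (factor
correlations, rGE) are optimised through a tanh bijection onto (−1, 1).

## Likelihood evaluation and optimisation

* **Rotated path** (complete data): with G = U D Uᵀ, the rows of Ỹ = UᵀY
  are independent, ỹi ~ N(0, di·C_G + C_I + √di·C_X); cost O(nk³) per
  evaluation, batched over eigenvalues.
* **Direct path** (missing data): the Gaussian density of the observed
  subvector of vec(Y), obtained by subsetting the dense nk×nk ΣV —
  full-information ML by marginalisation.  Cost O((n_obs)³); practical up
  to a few hundred individuals with k ≈ 6, which is why the replicate
  suites use complete data and the rotated path.

Scores are analytic on both paths: with Wi = Σi⁻¹ − qiqiᵀ (qi = Σi⁻¹ỹi),
the gradient reduces to inner products of S_G = Σ diWi, S_I = Σ Wi and
S_H = Σ √diWi with the coefficient-matrix derivatives, which are linear
in the loadings.  The analytic gradient is verified against central
finite differences in the test suite; it makes a 42-parameter k=6
Cholesky fit at n=2000 take about a second, where numerical gradients
(84 evaluations each) would be two orders of magnitude slower.

Optimisation is multi-start L-BFGS-B on the mean log-likelihood per
observation (gradient tolerance 1e-6 on that scale), default 5 restarts
with multiplicative N(1, 0.1²) start perturbations from moment-based
starting values (the sample covariance split evenly between A and E and
projected onto the structure).  The rGE likelihood is bimodal in the
sign of each correlation, so rGE-enabled fits additionally seed every
±0.5 sign combination of the rGE entries; in the stepwise pipeline the
rGE model is warm-started from the independence-IP optimum.

Standard errors come from the observed information — central finite
differences of the analytic score at the optimum — inverted on the raw
scale and delta-transformed; correlation SEs include the tanh Jacobian.
Parameters pinned at a box bound (e.g. a specific loading at zero) are
excluded from the positive-definiteness check of the information matrix
and flagged, not boundary-corrected.  `FitResult` distinguishes
`optimum_reached` (optimiser success + small projected gradient) from
`identified` (interior information PD): a saturated Cholesky whose
implied ΣA is sample-rank-deficient legitimately reaches an optimum on a
parameterisation continuum, while a fit with G = I is flagged
unidentified because A and E are then indistinguishable.

Degenerate inputs: a covariance that is not PD at some θ evaluates to
−∞ and the line search backtracks; an exactly-collinear covariate design
is reported with the offending columns; a trait whose step-1 residuals
are numerically zero (perfect covariate fit) is treated as exact ties
rather than rank-transforming rounding noise.

## Phenotype preparation

Traits are aligned so higher scores mean more difficulties (reverse
coding by negation; rank-equivalent to any max−x scheme).  The transform
is: OLS residualisation on the covariates; rank-based inverse-normal
transform of the residuals (Blom offset (r−3/8)/(n+¼), average ranks for
ties); second residualisation on the same covariates so the rank step
cannot re-introduce covariate effects.  Missing entries are never
imputed.  Heavily tied questionnaire scores yield tied normal scores.

## Model-building pipeline

1. Fit the saturated Cholesky.
2. Predict the latent genomic structure from the Cholesky-derived genetic
   correlation matrix: Kaiser count (eigenvalues > 1, primary) and an
   automated Cattell scree test (elbow at maximum acceleration of the
   eigenvalue sequence; factor count = elbow − 1).  When the two
   disagree both candidates are fitted and compared by AIC.  ML
   exploratory factor analysis (statsmodels) with promax rotation frees
   loadings with |rotated loading| ≥ 0.3; traits left unassigned keep
   their specific factor.
3. Fit the IPC hybrid; predict the residual structure from its implied
   residual correlation (PCA) and covariance (EFA) matrices; fit the IP.
4. Bifactor variants (general + identified group factors) check factor
   independence by AIC.
5. Extend the best IP with one rGE per structurally matched factor pair
   (pairs matched greedily by Jaccard overlap of loading patterns; a
   full Φcov block is available by configuration), warm-started from the
   IP optimum.  Evidence for rGE requires better fit (AIC or LRT
   p < 0.05) *and* every rGE Wald interval excluding zero.
6. Constrain specific genomic loadings with |estimate| < 0.05 to zero
   and refit.
7. Final model: best AIC among converged, admissible (SRMR ≤ 0.08)
   non-bifactor models.

SRMR uses the lower triangle including the diagonal, residuals
standardised by sample SDs; the model-implied per-individual covariance
takes kernel diagonals as one (C_G + C_I + C_X).  AIC = −2LL + 2Np;
BIC = −2LL + Np·ln(N_ind) with the number of *individuals*, not the
number of non-missing observations — the convention that reproduces the
published fit tables exactly.  LRT p-values are plain χ² upper tails,
except the univariate h²=0 boundary test, which uses the 50:50 χ²₀/χ²₁
mixture.  Phenotypic (split-half) models report CFI/TLI/RMSEA/SRMR with
χ² = (n−1)·F_ML against the independence baseline.

The split-half phenotypic analysis assigns rows to halves alternately
within per-row-missingness strata (seeded shuffle within each stratum),
runs EFA with PCA factor-count prediction on half 1, and on half 2 fits
a correlated-factor CFA of the implied simple structure plus an
uncorrelated variant that keeps thresholded cross-loadings.

## Synthetic data

Genotypes are i.i.d. Binomial(2, p) dosages with per-marker MAF uniform
on (0.05, 0.5) — unrelated individuals by construction, no LD, no
population structure or relatedness above the pruning cutoff.  Phenotypes
are drawn from the exact model law through the factorised square root of
ΣV given by the GRM eigendecomposition (per-eigenvector k×k Cholesky
draws mapped back by U); missingness is masked completely at random.
Passing tests therefore validate the estimator under its own assumptions;
they say nothing about LD structure, assortment, stratification or
informative missingness in real cohorts.

The six-trait preset (`alspac_like_scenario`) encodes two genomic and two
structurally matching residual factors (cognitive/language and social
domains) with sparse loadings, rGE = +0.89 and −0.62, ~18% missingness by
default, and per-trait specific loadings solved so every trait has unit
variance; two specific genomic loadings sit below the 0.05 constraint
threshold by design.  Published point estimates are used where the text
prints them; the remaining loadings are assumed values, kept below the
0.3 "negligible cross-loading" level and chosen non-proportional between
the A and E sides so that the preset's Fisher information for rGE matches
the published standard-error regime (≈0.17–0.18 at the cohort size,
≈0.33 at n = 2000).  The scenario file records which values are
published and which are synthetic placeholders.

## Validation problem sizes

The replicate suites run at desk scale, chosen to finish on one CPU:
parameter recovery at n = 2000 with 5000 markers and 20 replicate
phenotype draws over one shared GRM (inference conditions on the observed
GRM, as GREML does); LRT size under a zero-rGE truth at n = 500, k = 4,
200 replicates; saturated-model SRMR at n = 2000, k = 3; univariate
SNP-h² at n = 4000 with 40,000 markers — the marker count sets the GRM
eigenvalue dispersion and was chosen so univariate standard errors land
in the population-cohort regime (≈0.06–0.07).

Known limitations at these sizes: the ML estimate of a near-boundary
positive rGE is downward-biased (truth 0.89; replicate mean ≈0.6–0.7 at
n = 2000, ≈0.7 at n = 4000, with correct signs in ≥90% of draws) because
the likelihood is bimodal and some draws' global optimum lies near zero —
a finite-sample property of the estimator, not an optimisation failure
(truth-started refits reach the same optima).  Negative rGE, protected by
the non-negativity of specific variances, is recovered essentially
unbiased.  The data-driven pipeline's 0.3 EFA freeing threshold drops
true sub-threshold cross-loadings, which can make the saturated-residual
IPC the overall AIC winner on preset draws even though, within the IP
branch, the rGE model beats the independence IP.
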