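# Methods

## The evaluation model

The package scores genotypes for long-term heat tolerance from a paired
chamber trial: every index is measured under control (CK) and heat stress
(HS) with replicates. Replicates are averaged per genotype × index ×
condition *before* any ratio is formed (ratio-of-means; stabler than
mean-of-ratios when control replicates are noisy, and standard practice for
this evaluation method). The heat-resistance coefficient of index *j* in
genotype *g* is the dimensionless ratio

    h[g, j] = HS mean / CK mean.

h is stored on the ratio scale (1.0 = unchanged), not ×100. The choice is
inconsequential for everything downstream of standardisation — the z-scoring
absorbs any positive affine map of a column — but it keeps reported
regression coefficients on a scale where predicted H values land in [0, 1]
for ordinary genotypes.

The composite score is the classical fuzzy membership-function evaluation:

1. **Standardise** each h column (mean 0, sd 1, ddof = 1). Constant columns
   are rejected by name; at least 3 genotypes are required.
2. **PCA on the correlation matrix** (equivalently, covariance of the
   z-scores). The indices have wildly different native units, so the
   correlation matrix is the only defensible choice; it also matches the
   defaults of the legacy statistical packages this method is usually run
   in. Eigenvalues sum to the number of indices; component *i*'s variance
   proportion is Pi = λi / Σλ.
3. **Retention**: the smallest m with cumulative proportion ≥ 0.80
   (configurable), or an explicit component-count override. An override
   beyond the numerical rank of the correlation matrix is an error.
4. **Orientation**: the membership step is not sign-invariant, and an
   eigenvector's sign is arbitrary, so each component is deterministically
   flipped to make its loading on a configured *anchor index* non-negative.
   The default anchor is chlorophyll-a retention ("Chl a"), a benefit trait:
   genotypes that keep their chlorophyll under stress are the tolerant ones,
   so the oriented first component increases with tolerance. If the anchor
   loading is zero within 1e-10 (or the anchor is absent), the
   largest-magnitude loading is made positive instead.
5. **Membership values**: per retained component, genotype scores
   X (= z-matrix × unit-norm eigenvector) are min–max normalised,
   Ui = (Xi − Xmin)/(Xmax − Xmin). Exact ties share the endpoint values.
   Scores are *not* eigenvalue-scaled; membership normalisation makes H
   invariant to that per-component scaling, which a test asserts.
6. **Weights and H**: Wi = Pi / Σ(retained Pi), so Σ Wi = 1, and
   H[g] = Σ Ui[g]·Wi. H ∈ [0, 1]; a genotype attaining every per-component
   maximum scores exactly 1.

Two structural consequences are load-bearing and tested: H is invariant to
any increasing affine transform of any single coefficient column, and in the
rank-1 limit (every column an affine function of one latent factor) PC1
captures all variance and H is strictly monotone in that factor.

## Validation, grouping, index selection

- **H vs HII**: Pearson correlation with the two-sided t-test. The injury
  index HII = Σ(i·Ni)/(4N)×100 summarises 5-grade damage counts; the
  printed formula for this index is parenthesis-ambiguous in much of the
  literature, and it is read here so that the all-class-4 population scores
  100, the universal convention. A non-negative H–HII correlation produces a
  prominent warning, not a failure — the user may have mislabelled a hazard
  trait.
- **Grouping**: agglomerative clustering of the scalar H values (squared
  Euclidean distance, average linkage — again the legacy-package default),
  dendrogram cut at `n_groups` (default 3), groups renumbered by descending
  mean H so Group I is always the strongly resistant set. On 1-D data
  average linkage yields contiguous groups in sorted order; a test asserts
  this and checks agreement with an exhaustive optimal within-group-SS
  partition on well-separated instances.
- **Stepwise selection**: forward entry of the candidate with the smallest
  partial-F p-value if ≤ alpha_enter (default 0.05), then backward removal
  of any included predictor with p ≥ alpha_remove (default 0.10), iterated
  to a fixed point, with three guards: steps that would leave fewer than 2
  residual degrees of freedom are refused; candidates with tolerance
  (1 − R² against the included set) below 1e-8 are skipped and recorded;
  and exact p-value ties break lexicographically by index label so results
  are platform-independent and column-order-invariant. If nothing enters,
  an intercept-only model is returned with an `empty_model` flag. The final
  fit reports raw-scale coefficients plus beta-standardised ones, with
  R² checked against an independent residual-sum recomputation and the
  overall F from the closed form (R²/k)/((1−R²)/(n−k−1)); an exact fit
  (R² = 1) reports F = ∞, p = 0.

## The synthetic trial generator

The generator emulates a 10-genotype paired-chamber screen: a latent
tolerance θ_g ~ Uniform(0, 1) per genotype; per index a linear response on
the ratio scale, E[h_j(θ)] = a_j + b_j·θ, constrained positive on [0, 1];
CK replicates ~ Normal(μ_j, (cv·μ_j)²) and HS replicates
~ Normal(μ_j·h_j(θ), (cv·μ_j·h_j(θ))²), both truncated at zero by clipping
(at the default cv = 0.05 the clip essentially never fires; for large cv it
biases means upward and a log-normal model would be preferable); per-seedling
injury grades ~ Binomial(4, clamp(1 − θ + Normal(0, 0.05), 0, 1)), so
E[HII] = (1 − θ)·100 when grade noise is off.

Defaults — the simulated study conditions — are 10 genotypes, 3 replicates,
30 seedlings, cv 0.05, and six indices with field-plausible control means:
four benefit traits (Chl a retention a=0.3/b=0.7, CAT induction 1.0/1.5,
SOD 1.05/0.85, germination 0.35/0.6) and two hazard traits (hypocotyl
elongation 2.2/−1.0, soluble-sugar accumulation 2.8/−1.4). The latent model
is single-factor and linear — the weakest structure under which the
composite method is consistent; multi-factor structure can be injected via
`index_specs` but is not the default.

Reproducibility: θ, each index, and the injury grades draw from separate
child streams derived by hashing (seed, stream tag, index label), so adding
an index never perturbs existing columns, and identical configs give
byte-identical trials.

What passing synthetic tests shows — and does not: the generator has exact
single-factor structure, Gaussian replicate noise, no missing data, no
genotype × index interactions and no measurement drift. Recovery of θ here
demonstrates internal consistency of the scoring chain, not field validity
of any particular index panel.

## Numerical choices and sizes

- Eigen-decomposition via `numpy.linalg.eigh` on the symmetric correlation
  matrix; eigenvalues clipped at 0 and sorted descending; rank counted at a
  relative 1e-10 threshold.
- Degenerate-column detection uses a relative floor (sd ≤ (mean|x|+1)·1e-12)
  so a column constant up to rounding is treated as constant.
- Spearman recovery returns exactly ±1 for exactly (anti-)monotone rank
  vectors rather than round-tripping through floating-point covariance.
- Test/acceptance problem sizes: 100 simulation seeds for the stochastic
  medians, 1000 replicates for the null false-entry calibration, panels of
  10 and 30 genotypes — large enough for stable medians on a single CPU,
  small enough to keep the whole suite under a minute of simulation time.

## Known limitations

- Complete-case only: any genotype × index missing a condition is a hard
  error; there is no imputation.
- No factor rotation, no robust/sparse PCA, no regularised selection; the
  method implemented is deliberately the classical one.
- With ~10 genotypes the min–max membership step is sensitive to the extreme
  genotypes; the 30-genotype simulations show the expected stabilisation.
- Group membership from 1-D clustering is reported with its linkage record,
  but no bootstrap stability assessment is offered.
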