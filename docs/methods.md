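# Methods

This note records the statistical model behind each component, the
numerical conventions chosen where the literature is not unanimous, what
the synthetic data generator does and does not emulate, and the known
limitations. It documents decisions; every empirical number it mentions is
computed by the test suite or `scripts/acceptance.py`, not asserted here.

## Summary-statistic model

All computation is on the summary level. Instrument *j* carries
γ̂ⱼ ~ N(γⱼ, σ²_Xⱼ) for the exposure (per-SD units of a variance-1,
rank-normalized trait) and Γ̂ⱼ ~ N(Γⱼ, σ²_Yⱼ) for the outcome (log-odds
for a binary trait). A valid instrument satisfies Γⱼ = θγⱼ; horizontal
pleiotropy adds a direct effect αⱼ.

## Instrument selection and harmonization

* Filters: association p < 5×10⁻⁸, MAF ≥ 0.01 (MAF = min(EAF, 1−EAF)),
  duplicate variant ids dropped entirely (multiallelic proxy), palindromic
  allele pairs ({A,T}, {C,G}) dropped, and a genomic exclusion window for
  the extended HLA region given as chr6:25,000,000–34,000,000, interpreted
  as a closed 1-based interval. Every dropped record is attributed to
  exactly one filter (the first it fails, in the order p-value, MAF,
  multiallelic, palindromic, region) so the audit counts partition the
  input.
* Clumping is greedy by p-value (ties broken lexicographically by variant
  id, making output deterministic): the index SNP removes all SNPs on the
  same chromosome within the window (default 10,000 kb between `pos`
  values) with r² ≥ 0.01 against it. LD comes from a user-supplied
  precomputed matrix; the package never computes LD from genotypes.
* Harmonization aligns the outcome onto the exposure's effect allele:
  swapped alleles negate the outcome beta and reflect its frequency;
  complement-pair (strand-flip) matches are treated as matches because
  palindromic SNPs — the only ambiguous case — are excluded upstream.
  Frequency-based palindrome inference is deliberately not implemented;
  the exclusion-based strategy is simpler and loses little at these
  instrument counts.

## Estimators

* **Wald ratio**: θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE σ_Yⱼ/|γ̂ⱼ|. Exposure-side
  uncertainty is ignored, the dominant convention (NOME); this is a
  documented limitation, mitigated in practice by F ≫ 10 instruments.
* **IVW**: weights 1/σ²_Yⱼ; the multiplicative random-effects SE is the
  fixed-effect SE times √φ, φ = Q/(J−1), *not* floored at 1 (a pure
  multiplicative error model). P-values are normal.
* **MR-Egger**: SNPs are oriented so γ̂ⱼ ≥ 0, then weighted least squares
  with intercept. φ = RSS/(J−2) is floored at 1 here, and p-values use the
  t distribution with J−2 df — honest at the 3-SNP minimum. The floor/no-
  floor asymmetry between Egger and IVW reproduces the most widespread
  implementations and is stated explicitly because conventions differ.
* **Weighted median**: inverse-variance weights on the ratio scale;
  interpolated weighted percentile at s = 0.5 with sⱼ = (Σ_{k≤j}w_k −
  wⱼ/2)/Σw. SE from a seeded parametric bootstrap (default 1,000 draws)
  resampling γ̂ and Γ̂ from normals with their SEs.
* **Weighted mode**: Gaussian KDE of the ratios with the modified
  Silverman bandwidth 0.9·min(sd, mad/0.6745)·J^(−1/5) times a
  `bandwidth_factor` (default 1, the NOME setting); argmax on a grid at
  resolution h/10 padded by 3h, ties toward the smaller θ. The grid spans
  the ratios carrying the central 99.8% of weight, capped at 200,001
  points: a near-zero-weight wild ratio (tiny γ̂ denominator) would
  otherwise inflate the grid without being able to host the maximum.
* **Cochran's Q** about any fitted slope, df J−1 (J−2 for Egger
  residuals).

## Pleiotropy residual scan

Leave-one-out IVW slopes are computed in closed form from running sums, so
observed and simulated residual sums share one definition and the
simulation loop is fully vectorized. Empirical p-values use the add-one
convention (1+k)/(N+1). Outliers are flagged at p < 0.05/J (Bonferroni);
because the smallest attainable empirical p is 1/(N+1), the outlier test
needs N > J/0.05 − 1 simulations to be able to flag anything (e.g. > 3,679
for 184 SNPs); the default of 1,000 suits panels up to ~50 SNPs and is
exposed in config. The distortion test compares
(θ_raw − θ_corrected)/θ_corrected against removal of equally many SNPs at
random. SNPs are canonically sorted by variant id internally so all
outputs are invariant to input order.

## Directionality

Variant–trait r² uses the t-to-r conversion r² = t²/(t² + n − 2). For the
binary outcome the same formula is applied to the logistic-scale statistic
with total n (cases + controls) — an approximation; the liability-scale
conversion is a possible extension, and the retained SNP set may differ
marginally from what an exact method would keep. The Steiger test compares
Fisher-z-transformed correlations with variance 1/(n−3) per side,
two-sided. Filtering keeps SNPs with r²_exposure > r²_outcome (ties are
not retained) and Steiger p < 0.01.

## Pooling, multivariable MR, mediation

* Fixed-effects inverse-variance pooling; no genomic control, no
  heterogeneity filter. SNPs present in a subset of datasets are pooled
  over that subset and flagged (`N_DATASETS`, `DATASET_MASK` columns)
  rather than dropped, keeping instrument counts stable.
* MVMR is weighted least squares of Γ̂ on the J×K exposure-effect matrix,
  no intercept, φ = RSS/(J−K) floored at 1. The instrument panel is the
  union of the exposures' instruments restricted to SNPs present in all
  datasets, with the first exposure's alleles defining the reference
  orientation.
* Mediation: indirect = β₁β₂; the CI is the percentile interval of
  exp(β₁*β₂*) over independent normal draws of the two stage estimates
  (default 10,000, seeded). Independence is justified because the stages
  come from non-overlapping regressions. Proportion mediated is the signed
  ratio indirect/total; a zero total effect flags the proportion undefined
  rather than raising. The optional outlier-exclusion step before stage 2
  mirrors the practice of removing pleiotropic SNPs flagged on the
  univariable mediator→outcome set.

## Significance policy

Three tiers: p < 0.017 (0.05/3, Bonferroni across three co-primary outcome
datasets) is significant, 0.017 ≤ p < 0.05 nominal, else null. A p-value
exactly on a boundary falls in the weaker category.

## Synthetic data

Defaults are the study conditions the package is tested under: 184
instruments, total PVE 4% (hit exactly by rescaling), true θ = ln(0.916),
exposure GWAS n = 417,580, pooled case-control outcome GWAS n = 808,000
with case fraction 0.085, MAF ~ U(0.05, 0.5). SEs follow the large-sample
forms σ_X = (2·maf(1−maf)·n)^(−1/2) for a variance-1 trait and
σ_Y = (2·maf(1−maf)·n·φ(1−φ))^(−1/2) on the log-odds scale with φ the case
fraction — generation stays entirely on the summary level.

Per-SNP variance shares are shifted-exponential with three boosted loci
(the `longtail` profile), spanning instrument strengths F ≈ 30–2,500 at
default scale, the shape of large biomarker GWAS instrument sets where a
few major genes dominate; an `even` profile without boosts is available.
Pleiotropy is drawn per exposure-increasing allele (so a nonzero mean is
genuinely directional), optionally correlated with instrument strength
through `rho_inside` (InSIDE violation). Planted pathologies: outliers
(offset in units of σ_Y) and reverse-causal SNPs, the latter with a strong
outcome association and a configurable exposure "echo" (genome-wide
significant by default — a realistic trap for directionality filtering;
near-null for reverse-workflow experiments).

What the generator does **not** emulate: LD between instruments (an
explicit block LD matrix exists only to exercise clumping), sample overlap
between exposure and outcome GWAS, winner's-curse selection of
instruments, assortative mating or population stratification, and
liability-scale subtleties of the binary trait. Passing tests therefore
demonstrate correctness of the estimators and filters under the stated
generative model, not robustness to those real-data complications.

### Regimes used by the checks

Problem sizes were chosen so Monte-Carlo error is small against each
asserted bound: estimator recovery and Egger type-I use the full default
conditions (500 and 300–500 replicates); the outlier scan uses 50-SNP
panels with 1,100 simulations (so the Bonferroni floor is attainable) over
100 seeded runs; directionality uses 100-SNP panels with 10 planted
reverse SNPs. The median-robustness check sets 40% of instruments invalid
with mean direct effect 0.08 — gross pleiotropy, direct effects an order
of magnitude above the causal path. This is deliberate: with a
migraine-scale outcome GWAS the per-SNP ratio noise is large (per-SNP
outcome z ≈ 0.3), so the median's finite-sample bias under milder
contamination is a fixed fraction of the valid-cluster spread and its
breakdown-resistance only becomes visible against contamination well clear
of that noise floor.

## Known limitations

* First-order Wald SEs understate uncertainty for weak instruments.
* The binary-trait Steiger approximation can misrank SNPs near the
  direction boundary.
* The sample-overlap bias formula (bias ≈ overlap·confounded/F̄) is a
  first-order reconstruction validated by one-sample simulation only.
* The mediation bootstrap assumes independent normal stage estimates; a
  correlated resampling scheme could give narrower intervals.
* Conditional F statistics for MVMR and multivariable outlier scanning are
  out of scope.
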