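# Methods

## Model and tests

The package tests a variance component in the linear mixed model

    y = β₀1 + Xβ + Gγ + ε,   γⱼ ~ N(0, τ wⱼ²),   ε ~ N(0, σ² Iₙ),

where G holds minor-allele dosages of the m rare variants in the tested
set and wⱼ is the Beta(1, 25) density at variant j's MAF, rescaled so
max wⱼ = 1. The scaling is applied per tested set, after the rare-variant
filter; this changes the *scale* of λ = τ/σ² between sets (flagged in the
output) but not the tests, and keeps the profile likelihood numerically
well behaved. Squared weights enter the random-effect covariance
(var γⱼ = τwⱼ²), so the marginal covariance is σ²·V_λ with
V_λ = I + λ·GWG′, W = diag(wⱼ²).

The kernel formulation replaces Gγ by an n-vector h ~ N(0, τK); for the
weighted linear kernel K = GWG′ the two marginal models are identical, so
`LRT.M`/`LRT.K` (and `ReLRT.M`/`ReLRT.K`) differ only in how the spectrum
is computed (m×m cross-product versus n×n kernel eigendecomposition). The
equivalence is asserted to 1e-6 in the tests. IBS, Gaussian and polynomial
kernels are available behind the same interface but are flagged
experimental: only the weighted linear kernel participates in the
validated equivalences, and non-linear kernels change the null model being
tested.

### Observed statistics

The profile log-likelihoods in λ (up to λ-free constants) are

    ℓ_ML(λ)   = −(n/2)·log r′V_λ⁻¹r − ½ log|V_λ|
    ℓ_REML(λ) = −((n−p−1)/2)·log r′V_λ⁻¹r − ½ log|V_λ| − ½ log|X̃′V_λ⁻¹X̃|

with r the GLS residual at λ and X̃ = [1, X]. Both are maximised over
λ ∈ [0, ∞) on the grid {0} ∪ 81 log-spaced points in [1e-4, 1e4] followed
by golden-section refinement to relative tolerance 1e-4 in log λ;
LRTₙ = max(0, 2[sup ℓ − ℓ(0)]). λ̂ = 0 exactly when the statistic is 0.
The statistic is computed from the data-dependent likelihood (not by
plugging data into the spectral form), and every evaluation is validated
against a dense-matrix oracle in the tests. Implementation note: V_λ⁻¹
quadratic forms use the eigendecomposition of GWG′ (through its m×m
cross-product when genotypes are available), making each λ evaluation
O(K·p) after an O(nm·min(n,m)) precomputation.

### Exact simulated null

Both statistics satisfy a finite-sample distributional identity driven
only by the eigenvalues ξⱼ of W^½G′GW^½ (resp. K) and μⱼ of W^½G′P₀GW^½
(resp. K^½P₀K^½), with P₀ the residual projector off [1, X]. With uⱼ iid
standard normal and p₁ = p + 1,

    N(λ) = Σⱼ [λμⱼ/(1+λμⱼ)]uⱼ²,  D(λ) = Σⱼ uⱼ²/(1+λμⱼ) + Σ_{j>K} uⱼ²
    LRT   ≝ sup_λ { n·log(1+N/D) − Σⱼ log(1+λξⱼ) }
    ReLRT ≝ sup_λ { (n−p₁)·log(1+N/D) − Σⱼ log(1+λμⱼ) }

Each null draw evaluates the sup over the *same* λ grid used for the
observed statistic (plus a vectorised golden-section refinement), so the
maximisation bias of observed and null statistics cancels and the
simulated null is exact for the statistic as implemented. The trailing
n−p₁−K normals enter only through their sum of squares and are drawn as a
single χ² variate. p = (#{null ≥ observed} + 1)/(n_sims + 1); the default
n_sims is 10,000 per set (p-value floor ≈ 1e-4) and the study harness
lowers it to 2,000 (floor 5e-4, adequate for α ≥ 0.01).

Numerical choices: eigenvalues below 1e-10 × ξ_max are truncated (they
contribute only log(1+λ·noise)); the μ spectrum of the kernel route uses
P₀KP₀, which shares nonzero eigenvalues with K^½P₀K^½ without forming a
matrix square root; sorted-order μⱼ ≤ ξⱼ is enforced (Poincaré
separation), clipping only float noise. A degenerate spectrum (no genetic
variation) yields a "not testable" record rather than an error.

The asymptotic ½χ²₀+½χ²₁ mixture p-value is provided only as a
cross-check utility (`chibar_pvalue`): the exact null has *more* than half
its mass at zero and thinner upper tails than χ²₁ — for a single-variant
set roughly 0.69/0.70 at n = 150–400, verified against brute-force
profile-ML fits on fresh null data — which is precisely why the mixture
is conservative and never the default.

### Score-test comparators

Burden, SKAT and SKAT-O are the unified statistic Q(ρ) = r′GW^½R_ρW^½G′r
with r = P₀y and R_ρ = (1−ρ)I + ρJ; R_ρ^½ is computed in closed form from
the exchangeable structure. Under H₀, Q(ρ) ~ Σcⱼχ²₁ with cⱼ the
eigenvalues of σ̂₀²A′P₀A, A = GW^½R_ρ^½ and σ̂₀² = r′r/(n−p−1). Tail
probabilities invert the characteristic function (Imhof's integral; the
oscillatory tail is handled by QUADPACK's sin/cos-weighted rules, the head
by plain adaptive quadrature; absolute error target 1e-6, verified to
~1e-10 against closed forms), falling back to the Liu four-moment match if
the quadrature misbehaves. The Liu approximation is used as the common
currency inside SKAT-O's minimum-p statistic; it agrees with inversion to
within ~15% relative for p ≳ 0.01 and drifts conservative in the far tail.
SKAT-O's overall p-value is a Monte-Carlo tail probability of min-p over
the ρ grid {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} (squared-decile
convention; the grid is a package convention, surfaced in the config)
under Gaussian null residuals, with the same Liu p-values applied to
observed and simulated statistics — simpler than the analytic
one-dimensional integration and exact in the Monte-Carlo limit.

## Synthetic data

The generator emulates a coalescent sequencing-study design with two
backends.

The default `genealogical` backend simulates a neutral coalescent for n
diploids over a 100 kb region (Nₑ = 10⁴, μ = 1.5e-8, r = 1e-8 per bp per
generation), takes a random contiguous 30% subregion and extracts a
contiguous run of `m_target` polymorphic variants with realised MAF in
(0, 0.01). These canonical human-scale parameters imply
E[S] = 4NₑμL·H_{2n−1} ≈ 418/435/449 segregating sites at n = 300/400/500,
of which ~30% fall in the subregion and ~⅓ are rare — matching the
~41/47/51 usable rare variants per set that the study design anchors on
(the harness defaults `variants_per_n = {300: 41, 400: 47, 500: 51}`).
Crucially, the variants share a genealogy and therefore realistic LD;
without LD, opposite-sign causal effects cannot cancel through correlated
genotypes, and the power *loss* of SKAT and the (Re)LRT under sign-mixed
effects — a central comparison of the study — degenerates to zero. The
alternative `pool` backend (truncated power-law site-frequency spectrum,
density ∝ maf⁻¹ on (5e-4, 0.01), independent sites on a haplotype pool,
individuals as random haplotype pairs) is retained exactly for that
reason: it isolates LD effects and supports spectrum-level analytic
checks, but is not the study default.

Phenotypes: x₁ ~ N(0,1), x₂ ~ Bernoulli(0.5);
y = 0.5x₁ + 0.5x₂ [+ Σ γᶜgᶜ] + ε with ε ~ N(0, 1). The covariate
coefficients and noise SD are package defaults (all tests adjust for X, so
type-I error is invariant to them). Causal variants are
round(0.3·m) of the rare variants; |γ| = 0.3·|log₁₀MAF| (1.2 at MAF 10⁻⁴,
0.6 at 10⁻²); a configurable fraction (0/30/50%) of causal effects is
negated.

What passing tests do *not* show about real data: the simulator has a
single panmictic population (no structure or admixture), no genotyping
error or missingness, exactly Gaussian residuals, and LD only at the
within-100kb scale; calibration and power on real sequencing data can
differ accordingly.

## Study harness

Type-I cells use 2,000 replicates, power cells 1,000 (defaults; any
reported cell requires ≥ 100). Genotypes are regenerated per replicate
(configurable to a fixed panel), so Monte-Carlo error includes genotype
variability. All requested methods run on the same simulated data —
common random numbers make power *differences* much less noisy than the
powers. Seeding derives one `SeedSequence(root, spawn_key=(study, n,
scenario, replicate))` stream per replicate, so reruns are byte-identical
and parallel execution (joblib) matches serial exactly. Rejection is
p ≤ α (the simulated-null p-values are discrete). The acceptance script
runs three single-method cells at 2,000 × 2,000 scale; the in-suite power
study uses 300 replicates per cell across the three sample sizes — chosen
as the package's default scaled-down study — which resolves the
burden-vs-SKAT-vs-(Re)LRT loss ordering while keeping the suite quick.

## External validation (access-restricted)

The GAW17 mini-exome benchmark (697 unrelated individuals, simulated
quantitative traits on real exome genotypes; e.g. genes *HIF3A*, *FLT1*,
*KDR* for trait Q1, with age/sex/smoking covariates) is the natural real
-data check for these methods, but its data-use agreement prevents
shipping it here. The generic CLI runs the identical analysis for users
who hold the data:

    rvlrt test --geno gaw17.vcf --format vcf --pheno traits.tsv \
          --pheno-col Q1 --covar-cols age,sex,smoke --sets genes.setid \
          --maf-max 0.01 --nsim 100000 --seed 1 --out gaw17.results.tsv

(`--nsim 1e5` keeps the simulated-null floor below the strong-gene
p-values expected there.)

## Known limitations

- Continuous phenotypes only; no binary-trait (logistic) variant of the
  tests, no related samples/kinship, and a single variance component.
- The SKAT-O p-value is Monte-Carlo (floor 1/(n_mc+1)), not the analytic
  integration; for exome-wide scans at strict thresholds raise `n_mc`.
- Liu fallback p-values are conservative below ~1e-3.
- Per-set max-scaling of weights means λ̂ is comparable across sets only
  up to the per-set scale factor; the raw weights are retained for users
  who need a common scale.
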