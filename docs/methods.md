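# Methods

## Model

The working model is the standard additive polygenic model
`y = Xβ + Zγ + ε` for a quantitative trait on N individuals, P SNPs coded
as allele counts {0, 1, 2}, and K confounders (always including an
intercept). The ridge estimator minimizes
`‖y − Xβ − Zγ‖² + λβᵀΛβ`; the confounder effects γ are deliberately
unpenalized, which is what the projector `M_Z = I − Z(ZᵀZ)⁻¹Zᵀ` implements.
Its closed form, `β̂ = (XᵀM_Z X + λΛ)⁻¹XᵀM_Z y`, exists for any λ > 0
regardless of P/N. The package never forms M_Z explicitly: it is applied
through a thin QR of Z at O(NK) per vector.

Three algebraic identities organize the code and the test suite:

1. **Woodbury/dual form.** `β̂ = Xᵀ(XXᵀ + λI)⁻¹y`, so out-of-sample
   prediction is `ŷ₂ = A21*(A* + λ_GRM I)⁻¹y` with the genetic relationship
   matrices `A = P⁻¹XXᵀ`, `A21 = P⁻¹X₂Xᵀ`, `λ_GRM = λ/P`, and projections
   `A* = M_Z A M_Z`, `A21* = M_Z₂ A21 M_Z`. The outcome vector enters
   unprojected: the component of y in col(Z) is annihilated by the M_Z
   factors already inside the GRMs (A* is zero on col(Z), `(A*+λI)⁻¹`
   maps col(Z) to itself, and A21*'s right factor M_Z kills it), so
   projecting y first changes nothing. This identity is verified
   numerically rather than assumed.
2. **Multi-λ evaluation.** With `A* = QΘQᵀ`, predictions for an entire grid
   are `Ŷ₂ = A21* Q [(θ_i + λ_ℓ)⁻¹] ∘ (Qᵀy ιᵀ)` — one O(N³)
   eigendecomposition, then O(N²L) arithmetic. When `N > P` the same trick
   runs on the P×P matrix `XᵀM_Z X`; `ridge_predict` switches branch at
   `N ≤ P`.
3. **Penalty-as-weighting.** Heteroskedastic penalties Λ are absorbed by
   scaling SNP columns with `Λ^{-1/2}` and running the homoskedastic
   machinery. Consequences used throughout: plain ridge on standardized
   data `X = GD` equals per-SNP penalties `Λ = D⁻²` on raw centered counts;
   frequency weighting generalizes this to `Λ = D^α` (α = 0: effect size
   independent of frequency; α = −2: rarer alleles carry larger effects);
   external GWAS t statistics give `λ_p = t_p⁻²`, i.e. SNP p is scaled by
   |t_p|, because squared t statistics estimate per-SNP effect variance up
   to a common factor. |t| below 1e−3 is floored at 1e−3 (with a counted
   warning) so penalties stay finite — the statistics are noisy estimates,
   not structural zeros.

Kernels replace the additive similarity `x_iᵀx_j` with richer ones:
`(c + a_ij)^d` elementwise on GRM entries spans d-way SNP products (the
homogeneous d = 2 kernel is exactly the Gram matrix of all P² ordered
pairwise products divided by P², a factor absorbed into λ), and
`exp(−‖x_i − x_j‖²/η)` spans all orders. Confounders are projected around
the kernel (`M_Z₂ K21 M_Z (M_Z K M_Z + λI)⁻¹y`), after the nonlinearity.
Kernel distances are computed on standardized genotypes; raw counts can be
passed instead if a frequency-weighted notion of distance is not wanted.

## Standardization conventions

* `empirical`: `D_p = sqrt((N−1)/Σ(g_ip − ḡ_p)²)`, so `x_pᵀx_p = N−1` and
  `trace(A) = N−1` exactly. The N−1 (rather than N) denominator is a
  deliberate choice matching the GCTA convention; nothing downstream
  depends on which is used as long as it is used consistently.
* `true_frequency`: `x_ip = (g_ip − 2f_p)/sqrt(2f_p(1−f_p))` with known
  allele frequencies — the simulator's convention, identical in training
  and test data.
* Out-of-sample data always reuses the training means and D; test-set
  statistics are never consulted.
* Missing genotypes are mean-imputed per SNP before standardization; the
  missingness mask is kept for reporting. Constant SNPs are an error, named
  by id.

## Penalty tuning

* **Grid**: 151 log-uniform values on [1e−6, 1e9] (10 per decade), on the
  raw scale; `λ_GRM = λ/P` conversions are explicit via `LambdaGrid`.
* **K-fold CV** (defaults K = 10, 10% final test split): the full-sample
  GRM is built once and each fold eigendecomposes a submatrix, giving the
  whole λ curve per fold. The CV criterion is the *pooled* R² (all fold
  predictions concatenated before correlating) rather than a per-fold
  average — more stable for small folds; the aggregation is otherwise a
  free choice and is documented as such. Ties break toward the smallest λ.
* **Nested CV**: S superfolds wrap plain CV; the spread of λ̂ and test R²
  across superfolds is the robustness readout.
* **Closed forms**: `λ = σ²_ε/σ²_β` (ridge = BLUP), and
  `λ = P(1/h² − 1)` from SNP heritability, i.e. `λ_GRM = 1/h² − 1`.

## Simulator

Per run: `f_p ~ U(0.05, 0.95)`, `g_ip ~ Binom(2, f_p)` (so only common,
mutually independent variants), true-frequency standardization, effects
`β_p ~ N(0, σ²_β)` on the first `C = max(1, round(f_C·P))` SNPs, Gaussian
noise. One genotype matrix of `⌊1.1·max(N)⌋ × max(P)` is drawn per run and
every (N, P) scenario is a leading submatrix of it; training is the first N
rows, testing the next ⌊1.1N⌋ − N.

The genetic score g and the noise ε are centered, ε is orthogonalized to g,
and both are rescaled so the *sample* variance ratio var(g)/var(y) equals
h² exactly (to machine precision) per cohort. This makes
heritability-dependent checks sharp instead of adding an O(N^{-1/2})
sampling wobble on top of every comparison. β and ε are drawn fresh per
(P, f_C, h²) cell from seeds spawned off the run seed — statistically
identical to rescaling one draw, and fully reproducible from
(seed, config) alone.

What the simulator does **not** emulate: linkage disequilibrium (SNPs are
independent, so ridge's main real-data advantage — handling correlated
markers — is absent and the measured RR-vs-RSR gap is conservative in that
respect, while the independence also means `XᵀX → NI` as N grows, where RR
and RSR converge); minor-allele-frequency-dependent effect sizes; rare
variants; non-Gaussian noise; binary traits. Passing tests therefore
certify the linear algebra and the stated generating process, not
real-cohort performance.

## The factorial study

Factors: N ∈ {200, 500, 1k, 2k, 5k, 10k, 20k}, P ∈ {100, …, 500k} (12
levels), f_C: 37 log-uniform levels on [0.001, 1] (the published grid
states the rule, not the individual values; the log-uniform endpoints are
implemented as stated), h² ∈ {0.05, …, 1.00}: 62,160 scenarios, 1,305,360
scenario×run combinations at R = 21. The execution order is
runs → (N, P) → one eigendecomposition → (f_C, h²) → all λ jointly, with
optional per-run checkpointing.

Accuracy is the squared sample correlation between score and outcome in
the test set (zero-variance scores define R² = 0). λ is tuned per cell by
maximizing the median over runs of R²_RR(λ), ties to the smallest λ.
Derived measures: `log(R²_RR/R²_RSR)` with records outside (−1, +1)
flagged as outliers, and `logit(R²_RSR/h²)` with records where
R²_RSR ≥ h² flagged as uninformative (the ≥ boundary case is included in
the exclusion; the boundary convention is ambiguous in the source
material and is fixed here once). The RSR baseline under confounders
projects X, X₂ and y by the respective M_Z before scoring so the
comparison with projected ridge is like-for-like.

**Problem sizes.** The graded/per-default configuration is desk-scale:
`SimConfig.smoke()` (N = P = 2,000, f_C = 1%, h² = 0.5, 21 runs, ≈1 min)
and `SimConfig.desk_scale()` (N ≤ 2,000, P ≤ 5,000). The full grid
(`SimConfig.table1()`) is available by configuration and requires hours
per run on a single CPU at N = 20,000, P = 500,000. The smoke cell is
chosen because N = P, h² = 0.5 is the regime where the RR-vs-RSR ordering
is sharpest, and because the expected accuracies there are nearly
scale-free in N at fixed N/P (≈ h²/(1 + P/(N·h²)) ≈ 0.17 for RSR), so the
scaled-down medians are directly comparable to full-scale ones.

## Meta-model

Responses `log_ratio` or `logit_rel` are regressed on the intercept plus
log N, log P, log C, log f_C, log h² and their distinct-factor products up
to three-way. `log C = log f_C + log P` exactly, so the design is rank
deficient by construction; fitting is minimum-norm least squares (fitted
values are basis-invariant) and BIC = `n·ln(RSS/n) + k·ln(n)` counts the
numerical rank as k. The published 35-column three-way design cannot be
reconstructed from its description (distinct-factor products give 25 + 1
columns); an `include_squares` option adds pure powers and the column
count is always reported rather than claimed to match. Mean-prediction
intervals use `x̂ᵀβ̂ ± t_{n−k} σ̂ sqrt(xᵀ(XᵀX)⁺x)`, valid for estimable
x; rows extrapolating more than 10× beyond the fitted factor range are
flagged. Back-transforms (exp, inverse logit) are applied to interval
endpoints, which is exact for monotone maps.

## Numerical choices

* GRMs are symmetrized (`(A+Aᵀ)/2`) before eigendecomposition; asymmetry
  beyond 1e−6 or NaNs are errors.
* Eigenvalues below `−1e−8·θ_max` are rejected (the GRM is PSD in exact
  arithmetic, so this indicates a malformed input); the remaining small
  negatives and values below `N·eps·θ_max` are clipped to exact zero, so
  a K-dimensional confounder projection visibly removes K dimensions.
* λ = 0 is allowed only on the explicit OLS path with a full-rank
  `XᵀM_Z X`; otherwise a singularity error points to λ > 0.
* `rsr_score` refuses visibly unstandardized input (unequal column norms
  beyond 1e−6 relative); the study pipeline uses the raw `XᵀX`-free sum
  directly since true-frequency standardization equalizes column norms
  only in expectation.
* R² ties and degenerate cases: zero-variance predictions give R² = 0;
  argmax ties resolve to the smallest λ (less shrinkage ambiguity is below
  noise either way, and the choice is deterministic).

## Known limitations

* No LD-aware simulation, no dosage (non-integer) input, no VCF parsing,
  no binary-trait (logistic) ridge, no standard errors on β̂.
* Variance components σ²_ε, σ²_β are accepted as inputs, not estimated
  (no REML/ML/EM).
* The kernel module stops at polynomial and Gaussian kernels;
  multi-kernel variance-component models are out of scope.
* `--threads` is advisory; BLAS threading is controlled by the
  environment.
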