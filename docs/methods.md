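# Methods

## Model

A genotype is a string of `l` sites over a shared alphabet of `α` alleles;
the full space of `n = α^l` genotypes forms a Hamming graph (edges between
genotypes differing at one site). Indices use a fixed big-endian
mixed-radix code (leftmost site most significant); this ordering is a pure
convention, declared once and used everywhere, including file output.

For a face (wild type, two single mutants, double mutant) the epistatic
coefficient `ε = (f_AB − f_aB) − (f_Ab − f_ab)` measures how much one
mutation's effect changes across the backgrounds defined by the other;
its sign depends on the labeling, `ε²` does not. The mean of `ε²` over all
`s = C(l,2) C(α,2)² α^(l−2)` faces is the quadratic form `ε̄²(f) = fᵀC f`.
Counting how often each ordered product `f(i)f(j)` appears across faces
gives distance-dependent coefficients `c(d)`:
`c(0) = l(l−1)(α−1)²/2`, `c(1) = −(l−1)(α−1)`, `c(2) = 1`, `c(d≥3) = 0`,
with `C(i,j) = c(d(i,j))/s`. Equivalently `2sC = L² − αL` where `L` is the
graph Laplacian; the package evaluates `Cf` matrix-free through two
Laplacian applications (each `O(l·n)` by tensor reshaping), and keeps
explicit face enumeration only as a test oracle.

The reconstruction solves `minimize fᵀCf subject to f_B = y`. Eliminating
the constraint yields the sparse SPD system `C_II f_I = −C_IB y`, which is
solvable exactly when the additive least-squares fit on `B` is unique; we
pre-check this by a rank test of the order-{0,1} eigenbasis restricted to
`B`, which is cheaper and gives a clearer error than a failed
factorization. Key consequences, all tested: the solution is the
boundary-value problem `(L² − αL) f̂ = 0` on `I`; at each unobserved
genotype `f̂(i)` equals the mean of the `p = C(l,2)(α−1)²` local additive
face predictions, i.e. `(M f̂)(i)` for the smoother `M = I − (s/p)C`, and
also `2d₁(i) − d₂(i)` in distance-class means; `f̂_I` is linear in `y`
with noise covariance `σ² C_II⁻¹ C_IB C_BI C_II⁻¹`.

## Numerical choices

* **Direct solver** (default): assemble sparse `C` once per space
  (`2sC = L² − αL` in sparse arithmetic; nonzeros only at distance ≤ 2),
  slice `C_II`, solve with SuperLU. **Iterative solver**: conjugate
  gradients on the matrix-free operator (relative tolerance 1e−8,
  iteration cap ~10√|I|), for spaces where assembling `C` is unwanted.
* **Iterative smoothing**: the fixed-point view (apply `M`, clamp the data
  back) is implemented with damped relaxation
  `f ← (1−ω) f + ω clamp(Mf)`. The undamped sweep is a Jacobi iteration
  whose matrix `M_II` has spectrum reaching `1 − k(k−1)α²/(2p) < −1` on
  high-order components, and demonstrably diverges (e.g. binary `l = 4` at
  50% coverage). The default `ω = (α−1)²/α²` maps the spectrum of the
  damped iteration into `[0, 1)`, since `(s/p)·λ_max(C) ≤ (α/(α−1))²`,
  guaranteeing convergence whenever the solution is unique; `damping=1`
  restores the plain sweep. Convergence is declared when the max change on
  `I` falls below `1e−9 ×` the data range.
* **Interaction eigenbasis**: per-site Helmert contrasts (constant column
  plus `α−1` orthonormal contrasts), tensor-multiplied over site subsets.
  Order-`k` columns are `L`-eigenvectors with eigenvalue `kα` and block
  dimension `C(l,k)(α−1)^k`. Any orthonormal choice spans the same
  eigenspaces, so tests compare projections/predictions, not raw
  coefficients.
* **Local maxima**: tie tolerance defaults to 0 (exact comparison), with
  strict and weak policies exposed; the crater model's `d = 3 / d = 4` tie
  is exact in real arithmetic but off by ulps in floating point, so
  tolerance 1e−12 is used when counting its plateau.
* **Size caps**: dense per-genotype vectors refuse spaces above 2²⁰
  genotypes (configurable per space); dense matrices above 2¹⁴.
* **Convex-combination reconstruction** (`regularized_reconstruction`):
  minimizes `(1−mix)·weighted-MSE_B + mix·ε̄²`, one sparse SPD solve;
  `mix = 1` dispatches to exact interpolation, and per-genotype noise
  variances enter as inverse-variance weights. The kernelized solver
  (complexity cubic in |B| instead of |I|) is not implemented; the direct
  and matrix-free routes cover the package's intended size range.

## Simulators

The generators are first-class, tested code and define the package's
benchmark conditions.

* **Crater model** (transcription-factor binding): fitness depends only on
  the Hamming distance `d` to a focal sequence,
  `f(d) = s_on/(1+e^{ε(d−ρ_on)}) − s_on/(1+e^{ε(d−ρ_off)})`, defaults
  `ε = 1, ρ_on = 6, ρ_off = 1, s_on = 1`, classically on binary sequences
  of length 16. The profile peaks equally at `d = 3` and `4`
  (`f = 0.8333712`), with `f(0) = 0.2664688`.
* **Other distance profiles**: Hamming ball (high value out to a threshold
  distance, then low), quadratic in distance, and sinusoidal. Their exact
  parameter values are package defaults (threshold `l/2`, unit curvature,
  period 4), declared rather than inherited from any external source.
* **Sparse interaction model**: a coefficient for every allelic
  combination on every site subset — `(α+1)^l` one-hot columns — with 90%
  of coefficients zeroed and survivors drawn standard normal. Zeroing is
  i.i.d. Bernoulli(0.9) by default (an exact-fraction variant is a flag).
  `f = Xθ` is evaluated by per-site tensor contraction, never by
  materializing the `α^l × (α+1)^l` design.
* **Noise** is i.i.d. Gaussian with user-chosen σ — the simplest model of
  assay noise; real assays have heteroscedastic, count-driven errors,
  which only the convex-combination reconstruction can honor (via
  per-genotype variances). **Sampling** draws a uniformly random training
  fraction; the `per_distance_class` scheme additionally forces at least
  one held-out genotype per distance class so distance profiles remain
  assessable everywhere.

Because all synthetic truths are smooth-by-construction (distance
profiles) or Gaussian-coefficient models, passing benchmarks shows the
machinery is correct and well-behaved, not that real landscapes will be
reconstructed with any particular accuracy: empirical data differ in
noise structure, missingness patterns correlated with phenotype, and
epistasis that need not resemble either family.

## Baselines and metrics

The additive model is ordinary least squares on the order-{0,1} basis.
L2-regularized pairwise/three-way regression fits
`f̂ = Φβ + Ψγ` (additive block unpenalized, `λ‖γ‖²` on the interaction
block) with `λ` chosen by 10-fold cross-validation over a 20-point
log₁₀-spaced grid spanning `[1e−4, 1e4] ×` the data's mean squared
deviation (the spacing is standard; the range is a package default).
Internally the additive block is concentrated out (Frisch–Waugh) and the
ridge path solved through one eigendecomposition of the residualized Gram
matrix per fold, so the whole grid costs one factorization. The L1
three-way model is a lasso on the one-hot design up to three-way terms
(duplicate intercept excluded, indicator columns unstandardized), fitted
with scikit-learn's coordinate descent and CV-chosen penalty.

Metrics: out-of-sample/in-sample/total R² (SST about the reference mean on
the evaluated set); out-of-sample ε̄² averaged over faces whose four
genotypes are all held out (mixed faces excluded — the face must be fully
out of sample to measure pure prediction smoothness); strict-policy local
maxima counts and their out-of-sample enrichment; percentile FDR (fraction
of out-of-sample genotypes predicted above the 95th percentile of the
data whose true value is below it); and a randomization test for the
additive R² of a genotype region against equal-size uniform subsets
(plain-fraction p-value, ties counted extreme; add-one correction by
flag).

## Evolutionary embedding

The weak-mutation chain moves between Hamming neighbors at rate
`(1/(α−1))·S/(1−e^{−S})` with `S = c·Δf`, i.e. proportional to the
classical fixation rate, with time scaled so the per-site mutation rate is
1. The conversion factor `c` is calibrated by bracketed root-finding so
the stationary mean phenotype (under `π ∝ e^{cf}`) equals the wild-type
phenotype; the stationary mean is strictly increasing in `c`, so the root
is unique. Numerical guards use the asymptotic forms of `S/(1−e^{−S})`
for `|S|` small or beyond ±500. Embedding coordinates are right
eigenvectors of `Q` for the eigenvalues nearest zero (excluding the
stationary mode), computed on the π-symmetrized generator, π-normalized,
sign-fixed, and scaled by `1/√|λ|` (diffusion coordinates, in units of
square-root expected neutral substitutions per site); raw eigenvectors are
a flag. Degenerate eigenvalues among or adjacent to the selected set
trigger a warning, since coordinates are then defined only up to rotation.

## Benchmark problem sizes

The packaged studies are sized for a single CPU: the crater reconstruction
uses binary sequences of length 12 (4096 genotypes, training fractions
1–90%, with per-distance-class held-out coverage), and the sparse
interaction fixture uses `l = 7, α = 4` (16,384 genotypes, 78,125
coefficients, 80% training, 3 replicates). On the sparse fixture the
interpolation clearly beats the L2 pairwise model in out-of-sample R² and
shows less held-out-face epistasis than the L2 three-way model on the
replicate mean; the L1 three-way lasso, whose order-≤3 basis cannot
express the fixture's higher-order ruggedness at all, attains a *lower*
held-out-face ε̄² than the interpolation on this fixture — an expected
property of a truth whose all-order ε̄² is large, and a reminder that
"least epistatic given the data" is relative to what the data demand, not
a guarantee of the smoothest possible predictor.

## Known limitations

* Dense per-genotype vectors cap practical spaces at ~10⁶ genotypes; the
  kernelized (observation-space) solver that would lift this is not
  implemented.
* Plain interpolation reproduces noisy observations exactly; use the
  smoother or the convex-combination reconstruction when measurement noise
  matters.
* Identifiability requires the additive design on `B` to have full rank —
  in particular every allele must be observed at every site.
* The simulators draw on two stylized landscape families; conclusions
  about empirical data require the user's own validation splits.
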