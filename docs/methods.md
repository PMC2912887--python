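# Methods

## The model

Given a nonnegative feature-by-sample matrix `X` (n × p; genes × arrays in
the expression setting), nonnegative matrix factorization seeks

    X ≈ W H,   W ∈ R^{n×r}_{≥0},  H ∈ R^{r×p}_{≥0},  r ≪ min(n, p),

so each sample (column of `X`) is a nonnegative combination of `r` basis
components — *metagenes* — with mixture coefficients given by the matching
column of `H`.  The fit quality is a loss `D(X, WH)`, either the halved
squared Frobenius norm `½‖X − WH‖²` or the generalized Kullback–Leibler
divergence `Σ [X log(X/Ŵ) − X + Ŵ]` (with `0·log 0 = 0`).  The internal
euclidean objective is halved (derivative-friendly); the *reported* residual
sum of squares (RSS) is the unhalved `Σ(X − Ŵ)²`, so `RSS = 2 × objective`.

Two model variants extend the plain product:

* **non-smooth NMF** interposes `S(θ) = (1−θ)I + (θ/r)·J` so the estimate is
  `W S H`; the smoothing leak between metagenes pressures `W` and `H`
  themselves to become sparse (θ ∈ [0,1]; default 0.5, the customary
  reference value);
* **offset NMF** adds a feature-wise constant vector: `W H + b·1ᵀ`,
  absorbing expression common to all samples.

## Algorithms

| method  | loss      | scheme |
|---------|-----------|--------|
| lee     | euclidean | multiplicative updates `H ← H∘(WᵀX)/(WᵀWH)`, `W ← W∘(XHᵀ)/(WHHᵀ)` |
| brunet  | KL        | multiplicative updates `H_au ← H_au·[Σ_i W_ia X_iu/(WH)_iu]/Σ_k W_ka` (and symmetric for W) |
| nsnmf   | KL        | brunet steps with `W S` in the H update and `S H` in the W update |
| offset  | KL        | brunet-style steps against `WH + b1ᵀ`; `b_i ← b_i·[Σ_u X_iu/est_iu]/p` |
| snmfr   | euclidean | alternating nonnegativity-constrained least squares (active set, per column) with an L1 penalty `β` on H columns and ridge `η` on W (defaults `β = 0.01`, `η = max(X)²`) |

Every division and logarithm argument carries an epsilon guard
`ε = 2⁻⁵²`, the standard stabilization keeping multiplicative updates
defined at exact zeros.

**Stopping criteria.** Three rules, applicable to any iterative scheme:
(1) a fixed iteration count; (2) *connectivity invariance* — stop once the
sample connectivity matrix of the current model is unchanged over a 40-
iteration window, assessed every 10 iterations (the window counts
iterations, not checks); (3) *stationarity* — stop when the relative
objective change between checks falls below `tol` (default 10⁻⁶).
Connectivity invariance is evaluated per run, on the current single run's
connectivity matrix.  Defaults: connectivity invariance with a 2000-
iteration cap for the multiplicative methods; stationarity with a 500-outer-
iteration cap for SNMF/R.  Rank surveys default to stationarity because it
behaves uniformly on structured and randomized data (connectivity never
stabilizes on noise, which would otherwise always exhaust the cap).

**Seeding.** `random` draws W, H i.i.d. uniform on `(0, max X]`; `nndsvd`
is the deterministic double-SVD construction (sign ambiguity fixed by making
the largest-magnitude entry of each left singular vector positive; optional
`dense_fill` replaces exact zeros by `mean(X)/100`, applied automatically
for KL methods, whose multiplicative updates cannot escape exact zeros);
`ica` takes the positive parts of a FastICA (negentropy contrast)
decomposition, flipping each component's sign so its positive parts carry
more mass before truncation, and falls back to `random` on non-convergence;
an explicit model or a bare numeric seed may also be supplied (the numeric
form seeds the random initialization).  Deterministic seeds make a fit fully
reproducible in a single run.

**Multi-run consensus.** `multifit` performs `nrun` independent fits with
per-run seeds spawned from a master seed via `SeedSequence(master).spawn(k)`
— run k's seed depends only on `(master, k)`, so serial and concurrent
execution give identical results.  The consensus matrix is the average of
the per-run sample connectivity matrices; the best fit minimizes the final
objective (ties → lowest run index).  Failed runs are excluded with a
warning.

## Quality measures

* `RSS` and explained variance `evar = 1 − RSS/ΣX²`.
* Hoyer sparseness `(√n − ‖x‖₁/‖x‖₂)/(√n − 1)`, averaged over columns of W
  and rows of H (the aggregation is a package choice; a whole-matrix
  aggregate would also be defensible).
* Purity `(1/p)·Σ_k max_l n_k^l` and normalized entropy
  `−(1/(p log₂ q))·Σ_k Σ_l n_k^l log₂(n_k^l/n_k)` against known classes.
* Cophenetic correlation of a consensus matrix: Pearson correlation between
  the induced distances `1 − C` and the cophenetic distances of their
  average-linkage hierarchical clustering.  `1 − C` is the distance used for
  the coefficient; euclidean/average-linkage ordering is used only for
  heatmap display.  All off-diagonal entries equal → the coefficient is
  undefined and reported as not available.

## Rank estimation

`survey` fits each candidate rank with `nrun` repeated runs (30–50 is
enough for a robust estimate) and records the cophenetic coefficient,
best-fit RSS/evar and the consensus matrix.  Selection heuristics:

* **first cophenetic decrease** — smallest surveyed r with
  `coph(r+1) < coph(r)` (strict; falls back to the largest rank with a
  warning when the curve never decreases);
* **RSS inflection** — interior rank maximizing the second difference of
  the RSS curve (warning + smallest interior rank when the decline is
  linear);
* **randomized-data comparison** — the observed marginal RSS decrease is
  compared with the decrease on data permuted independently within each
  column (destroying gene covariation, preserving each array's marginal;
  the permutation scheme is a package choice).  The selected rank is the
  largest r whose whole prefix of marginal decreases beats the randomized
  baseline.

A residual-weighted consensus is available: run k weighted by
`(1/RSS_k)/Σ_j(1/RSS_j)` (an exact fit takes all weight).  The inverse-RSS
form is the simplest "relative residual error" weighting; it reduces to the
plain consensus under equal residuals.

## Feature selection

Rows of W are scored by metagene specificity:
`score_i = 1 + (1/log₂ r)·Σ_q p_iq log₂ p_iq` with `p_iq = W_iq/Σ_q W_iq`
(1 = loads one metagene, 0 = uniform; zero rows score 0 and are never
selected).  A feature is selected when `score_i > s` **and**
`max_q W_iq > median(W)` (both strict), with `s = μ + 3σ` where μ, σ are the
median and the **unscaled** median absolute deviation of the scores — no
1.4826 consistency factor, which materially lowers `s` relative to a
normal-consistent MAD.

## Synthetic data

The generator emulates a multi-class expression study with `r` well-
separated groups: each feature is assigned a dominant metagene round-robin;
dominant entries of `W0` sit at `signal`, the rest at `background`
(truncated normal, sd = 0.1·mean — so a zero mean yields exact zeros);
`H0` is the per-group block indicator with the same corruption;
`X = W0 H0 + noise` with truncated-Gaussian noise clipped at zero
(clipping is a simple, documented way to keep nonnegativity; a lognormal
model would avoid the atom at zero but complicate the ground truth).
Defaults: n = 200 features, p = 30 samples, r = 3, group sizes (15, 6, 9)
mirroring the classic leukemia study's 19/8/11 class proportions,
signal:background = 10:1, noise_sd = 0.1.

An optional `subtype_pair` makes two groups subtypes of a common parent:
each expresses the other's marker genes at `subtype_level × signal`
(default 0.5).  This reproduces the hierarchical class structure of the
leukemia benchmark (two lymphoblastic subtypes vs the myeloid class), under
which a rank-2 factorization has one dominant 2-way split and repeated runs
produce a perfect 0/1 consensus.  With flat, mutually equidistant groups
the rank-2 merge choice is initialization-dependent and the consensus is
*not* binary — a genuine property of the model, not an artifact.

What the generator does **not** emulate: probe-level noise, batch effects,
heavy-tailed expression distributions, correlated gene modules beyond the
planted blocks.  Passing tests on these fixtures demonstrate correctness of
the algorithms and estimators, not performance on real microarray data.

## Numerical notes and limitations

* Argmax tie-breaks go to the lowest metagene index; cluster labels are
  1-based in all user-facing output, 0-based internally.
* The offset vector of offset-NMF is not identifiable from data alone:
  adding any constant `γ·1` direction to rows of H while shifting `b`
  accordingly leaves the estimate unchanged, so a fit recovers *some* valid
  decomposition, not a unique offset.  The update formula itself is
  verified by holding W, H at the generating values, under which the offset
  converges exactly to the added constant row.
* Non-smooth NMF with θ = 0.5 cannot reproduce a factorization whose W rows
  are sparser than the smoothing cone allows: representability of `W0 H0`
  requires roughly `background/signal ≥ (θ/r)/(1 − 2θ/r)` per row (0.25 at
  θ = 0.5, r = 3).  Exact-recovery demonstrations therefore use a small θ
  (0.1); at larger θ the achievable explained variance saturates below 1 by
  design — the model trades fit for sparseness.
* SNMF/R solves each NNLS subproblem exactly by an active-set method per
  column; this is robust for the small ranks used here but quadratic in r.
* Fits are reproducible bit-for-bit given (method, seeding, seed); all file
  writers use fixed 12-significant-digit formatting so identical results
  give byte-identical files.
* Problem sizes in the shipped checks (e.g. 10 survey replicates of
  200 × 30 data at ranks 2–5 with 20 runs per rank) were chosen as the
  smallest designs at which the selection heuristics' behaviour is stable;
  larger designs change nothing qualitatively.
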