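# Methods

## Generative model

Sites are restriction fragments (unbinned) or fixed-width bins. Each site
`u` carries a mark vector `C_u` over an ordered catalog `M`: binary
presence/absence when unbinned, nonnegative counts after binning. Every
unordered site pair interacts independently; each co-occurring mark pair
(m, n) at the two ends is an independent Bernoulli "slot" with success
probability `x_mn`, so

    P(u ~ v | X) = 1 − Π_{m,n} (1 − x_mn)^{c^u_m c^v_n}.

The matrix X is assumed symmetric and *global*: the same mark-pair
propensities act at every locus. This is the model's central simplifying
assumption — it buys convexity and interpretability at the price of ignoring
locus-specific effects and any distance dependence.

With `x = 1 − e^{−z}`, the contact probability becomes
`1 − exp(−C_uᵀ Z C_v)`, and the negative log-likelihood of the observed
graph (a product over edges *and* non-edges) is convex in Z ≥ 0. The fitted
objective adds `λ₁‖Z‖_*` (nuclear norm: low-rank / block-community mark
structure) and `λ₂‖Z‖₁` (sparsity: only a few mark pairs matter). The sum of
a convex data term and two norms is convex, so the unbinned fit has a global
optimum; the test suite verifies the Jensen inequality numerically on random
draws.

### Non-edge accounting

The likelihood's non-edge sum is never computed by an O(n²) loop. With
`S = Σ_u C_u` and `T = Σ_u C_u C_uᵀ` accumulated per chromosome,

    Σ_{u<v} C_uᵀ Z C_v = (Sᵀ Z S − trace(T Z)) / 2,

so the data term costs O(|E|·|M| + n·|M|²). By default non-edges range over
within-chromosome pairs only (matching per-chromosome experimental
practice); `nonedge_scope="genome-wide"` lifts that. Cross-validation
restricts the likelihood to an explicit pair list instead, so training and
validation pairs never mix.

An observed edge between mark-free sites has model probability 0; its
log-term is clamped at `clamp_eps = 1e−10` and a warning is emitted, since
no X can explain it.

## ADMM solver

The objective is split with two auxiliary copies (Z₁ for the nuclear term,
Z₂ for the L1 term) and scaled duals U₁, U₂:

1. Z-block: projected gradient descent on
   `−log L(Z) + ρ/2(‖Z−Z₁+U₁‖² + ‖Z−Z₂+U₂‖²)` over Z ≥ 0, with Armijo
   backtracking (sufficient-decrease constant 1e−4, step doubling after
   success, at most 50 halvings), warm-started at the previous Z and capped
   at 200 inner iterations with a projected-gradient-norm stop at 1e−6.
   The iterate is symmetrized (averaged with its transpose) on return.
2. Z₁ ← SVD soft-threshold of (Z + U₁) at λ₁/ρ (closed form).
3. Z₂ ← entrywise soft-threshold of (Z + U₂) at λ₂/ρ (closed form).
4. U₁ += Z − Z₁, U₂ += Z − Z₂.

Defaults: ρ = 1.0, outer tolerance 1e−4, 500 outer iterations,
initialization Z = Z₁ = Z₂ = 0.01 (uniform), U = 0. None of these defaults
are delicate; the tiny-instance tests run at tighter tolerances.

Stopping requires both the primal residual max(‖Z−Z₁‖, ‖Z−Z₂‖) *and* the
dual residual ρ·max(‖Z₁−Z₁_old‖, ‖Z₂−Z₂_old‖) to fall below tol (scaled by
max(1, ‖Z‖)). The primal residual alone is not sufficient: with small
penalties the proximal steps make Z₁ track Z exactly, so it vanishes while
the likelihood block is still far from its optimum. Divergence (the
residual growing 10× over 20 iterations) raises an error rather than
returning silently.

The Z₁ block is unconstrained in sign — only the consensus variable Z
carries the Z ≥ 0 constraint — so the nuclear prox may output negative
entries that are reconciled through the consensus constraint.

## Binned (count) model

Binned counts follow a Poisson-binomial over `T = C_uᵀ 1 C_v` slots whose
probabilities are the multiset {x_mn repeated c^u_m·c^v_n times}. The exact
pmf ships as an O(T·k) dynamic-programming convolution (used for
diagnostics and as a sampling law); inside the likelihood the Le Cam Poisson
approximation `E'_uv ~ Poisson(C_uᵀ X C_v)` is used, whose total-variation
error is bounded by Σ p_i² (verified in tests). The binned objective is
treated as potentially multimodal and optimized directly in X over the box
0 ≤ x < 1 by projected gradient with Armijo backtracking, with the penalties
evaluated on Z(X) = −log(1−X) via subgradients, from 5 random starts
(best objective wins). Optimizing in X rather than z avoids the vanishing
gradient of the z-parameterization (dX/dZ = e^{−Z} → 0), which can strand an
iterate on a plateau at large z.

## Preprocessing conventions

* Coordinates are 0-based, BED half-open; contact positions are points
  assigned to bins by floor(pos / resolution).
* A mark belongs to a restriction site when one of its peaks is within
  100 bp (inclusive; distance 0 inside the peak, else the gap to the nearest
  peak edge). The threshold unit is base pairs and a peak may serve every
  site within range.
* Binned signal tracks are binarized by averaging replicates first, then
  log(1 + x) (natural log), then thresholding at 0.5 inclusive.
* Intra-bin contacts are dropped when binning (the likelihood is over
  distinct node pairs); the dropped total is logged so counts reconcile.
* Duplicate contact records are summed; self-pairs dropped with a warning;
  unbinned multi-counts collapse to presence/absence (the unbinned
  likelihood treats E as a set).

## Evaluation choices

* **Negative pairs for ROC**: a seeded uniform sample of within-chromosome
  non-edges, 10× the positive count (capped by availability), since scoring
  all O(n²) non-edges is unnecessary for a rank statistic.
* **Distance-decay baseline**: `P = α·d^{−β}` with β fixed in {1, 1.5, 2}
  and α fitted by 1-D Bernoulli maximum likelihood on clipped
  probabilities. The exponent is implemented as a decay (negative power):
  contact probability falls with genomic distance. α is a calibration
  parameter only — AUC is invariant to it.
* **Compartment calls**: the input matrix is converted to its row
  correlation matrix, and the two-way partition is the sign pattern of the
  eigenvector with the largest-magnitude eigenvalue (zero entries join the
  positive class). A global sign flip gives the same partition.
* **NVI**: variation of information with natural-log entropies, normalized
  by log n. nvi(p, p) = 0; the singletons-vs-one-block case attains 1.
* **Boundary confusion**: greedy nearest-first matching, each predicted
  boundary used at most once; default tolerance 0 bins (strict), settable.
* **Nested CV**: outer folds are random partitions of the scored pairs
  (or whole chromosomes in leave-one-chromosome-out mode); inner folds pick
  the (λ₁, λ₂) pair with the best mean validation AUC; exact ties break
  toward the larger, more regularized pair. Deterministic under a fixed
  seed. The default grid is {0.01, 0.1, 0.5}² .
* **TAD calling is out of scope**: the package consumes externally produced
  partitions/boundary sets and compares them (NVI, confusion counts); it
  does not reimplement a domain caller.

## Synthetic data

The simulator is the ground-truth factory for every test. `make_truth`
draws a symmetric X with a requested fraction of nonzero entries (default
0.35), placed preferentially within mark groups (two blocks by default) so
the truth is sparse *and* approximately low-rank — exactly the structure the
penalties encode. Per-mark densities are drawn once from Uniform(0.05, 0.3)
(realistic sparsity heterogeneity across ChIP-seq tracks). Sites sit every
4 kb on pseudo-chromosomes (a typical restriction-fragment scale). Contacts
are sampled pair-independently: Bernoulli with the model probability
(unbinned), slot-by-slot Poisson-binomial, or Poisson at λ_uv (binned),
within chromosomes.

Fixture sizes: tiny (3 marks × 8 sites; solvable by a derivative-free
oracle), small (6 × 500, one chromosome; the recovery study), medium
(16 × 3000 across 6 pseudo-chromosomes, mirroring a realistic mark-catalog
size). The medium truth uses scaled-down interaction probabilities
(within-block 0.1–0.3, background 0.02–0.1, densities 0.02–0.12) so that its
contact graph stays realistically sparse (~7% of within-chromosome pairs)
rather than saturating under the larger catalog; the small fixture keeps
stronger probabilities so each of its 21 matrix entries is well determined
by ~125k pairs.

What the simulator deliberately omits: distance-dependent contact decay,
polymer physics, TAD/loop-shaped structure, experimental noise and coverage
biases. Passing tests therefore demonstrate correctness of the estimator
*under its own generative assumptions* — recovery of a planted X, correct
likelihood algebra, solver optimality — not performance on real Hi-C data.
The distance-decay baselines are evaluated on this data precisely because
the simulation has no distance structure: a model that cannot beat them
there is broken, but beating them here says nothing about real genomes.

## Problem sizes and numerical choices in the shipped studies

The recovery study fits the small fixture at a penalty chosen by 2-fold
cross-validation over the diagonal grid {(0.01,0.01), (0.1,0.1),
(0.5,0.5)} and then refits at tolerance 1e−5; the held-out AUC study
trains on 80% of the medium fixture's scored pairs and evaluates on the
rest; the oracle comparison uses multistart bounded Powell (direction-set
restarts, 6 starts × 3 rounds) on the vectorized upper triangle of tiny
instances. These sizes were chosen so the studies are well determined
statistically while remaining desk-scale.

## Known limitations

* The global-X assumption ignores locus-specific and distance-dependent
  effects; real contact maps will violate it.
* An edge between mark-free sites is inexplicable under the model and only
  enters through a clamped term.
* The binned fit is multistart local optimization; restarts mitigate but do
  not guarantee global optimality.
* Matrix balancing (ICE/KR), peak calling, and read processing are out of
  scope — inputs are assumed to be called peaks and contact lists.
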