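# Methods

This note documents the model implemented by `hcfmda`, the parameters that
matter, the numerical conventions, and what the synthetic benchmark does
and does not show.

## Model

The data are a binary association matrix `X` (diseases × miRNAs), a
disease ontology given as a parent→child edge list, and a precomputed
miRNA functional-similarity matrix `FM`. The method is neighborhood
collaborative filtering over integrated similarities.

**Semantic similarity.** For disease `d`, every term `t` in its ancestor
closure contributes `ρ^k`, `k` the shortest downward distance from `t` to
`d`. This closed form equals the usual max-over-children recursion because
`ρ < 1` makes the maximum over downward paths be attained on a shortest
path; we compute it with a breadth-first traversal of the reversed graph.
Similarity is shared-ancestor contribution mass normalized by the two
semantic values. Pairs with disjoint closures, and diseases absent from
the DAG, are marked *unavailable* rather than zero.

**GIP kernels.** `exp(−δ‖BV_i − BV_j‖²)` on the rows (diseases) or columns
(miRNAs) of `X`, with `δ = δ′ / mean‖BV‖²`. If every profile is zero the
raw `δ′` is used (with a warning) — the kernel then degenerates to 1
everywhere, which only occurs on pathological inputs.

**Normalization and integration.** Each similarity matrix is z-scored over
its available entries (population standard deviation, diagonal included)
so the semantic/functional and kernel scales are commensurable; the
integrated matrices take the primary (semantic or functional) value where
it is available and the kernel value elsewhere. The availability gate is
evaluated on the *raw* matrix by default: z-scoring maps genuinely
positive similarities below zero, which would corrupt a post-normalization
positivity gate. `gate_on_raw=False` switches to the post-normalization
gate for comparison.

**Scoring.** The three evidence pools (SDA, SMA, SDMA) and their fusion
are described in the README. Conventions that the equations alone do not
fix:

* Neighborhoods exclude the query itself; ties in similarity break toward
  the smaller index, and ties in pair similarity toward ascending `(u, v)`,
  so results are independent of hash order.
* When fewer than `N` (or `K`) candidates exist, the sum is still divided
  by `N` (`K`); a shortfall is logged.
* Z-scored similarities can be negative. Negative-similarity neighbors
  participate in SDA/SMA (the score is a signed weighted mean), but the
  pair similarity `1/√((1/s_d)² + (1/s_m)²)` is undefined for nonpositive
  inputs, so such pairs are dropped from the SDMA pool.
* Scores are rankings, not probabilities; they are not clipped to [0, 1].

**SVD denoising.** The association evidence consumed by the three scorers
is the truncated-SVD reconstruction `X̃ = U_k Σ_k V_kᵀ` of the training
matrix. The rank is either given directly or chosen as the smallest rank
retaining a fraction (default 0.9) of the squared-singular-value energy.
Disabling SVD (`svd_enabled=false`) reproduces the pure neighborhood
model. Applying the truncation to `X` (rather than to the similarity
matrices, or as a latent-factor scorer in its own right) is this package's
design choice; the alternative variants can be emulated by composing the
exported primitives.

## Evaluation protocol

Leave-one-out cross-validation holds out each known association in turn.
Because the GIP kernels, the integrated similarities and the SVD
reconstruction all depend on the training matrix, the default protocol
recomputes all of them per fold; `fast_loocv=true` freezes the
similarities at their full-data values (a common shortcut in this
literature) and recomputes only the reconstruction. Candidates for a fold
are the held-out miRNA plus all miRNAs not known-associated with the
fold's disease; ranks use mean-rank tie handling, which makes a constant
scorer yield AUC exactly 0.5.

Folds have different candidate-set sizes, so they are pooled into one ROC
via the normalized mid-rank `1 − (rank − 0.5)/n_candidates` of every
candidate. AUC is the Mann–Whitney rank statistic (ties count ½) and is
asserted to agree with the trapezoidal area of the threshold-swept curve.
A per-disease-averaged AUC would be an alternative pooling; only the
pooled variant is implemented.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `rho` | 0.5 | per-generation decay of ancestor contributions (dimensionless, (0,1)) |
| `delta_prime_d`, `delta_prime_m` | 1.0 | raw GIP bandwidths before normalization by mean squared profile norm |
| `n_neighbors` (N) | 20 | disease and miRNA neighborhood size |
| `k_pairs` (K) | 20 | pairs kept in the SDMA pool (from the ≤ N² candidates) |
| `alpha` | 0.3 | disease- vs miRNA-neighborhood weight inside the (1−β) share |
| `beta` | 0.1 | weight of the pair-neighborhood evidence |
| `svd_rank` | 0.9 | truncation rank (integer) or retained energy fraction |

`ρ = 0.5` is the convention of the functional-similarity literature the
semantic measure comes from; `δ′ = 1` is the standard GIP normalization;
`α = 0.3, β = 0.1` are the grid-search optimum reported for the method on
real catalogue data; `N = K = 20` are round defaults in the absence of
published values — all are exposed in `PipelineConfig` and the CLI, and
`grid_search` sweeps `α`/`β`.

## Synthetic benchmark

The generator plants the assumption the method exploits: functionally
related miRNAs associate with semantically related diseases. Each disease
and miRNA joins each of `latent_rank` modules independently (Bernoulli
memberships, probability set in closed form so that the module-overlap
probability is twice the target density); exactly the target number of
ones is kept, preferring pairs sharing more modules with randomized
tie-breaking, and 2 % of entries are flipped as label noise. Overlap pairs
left at zero emulate the incompleteness of curated catalogues. The disease
tree hangs same-dominant-module diseases under the same subtree, 20 % of
diseases are left out of the tree, and 30 % of functional-similarity
entries are masked, exercising both kernel-fallback paths. Module-free
diseases hang directly off the root.

Default problem size is 60 × 80 at 5 % density — small enough that the
full rigorous LOOCV (hundreds of folds, each retraining kernels,
integration and SVD) runs in seconds, while keeping ≈ 330 folds for stable
AUC estimates. The negative control permutes the rows and columns of `X`
against the side information; note the GIP kernels are recomputed from the
permuted matrix and therefore retain self-consistent signal, so the
control isolates exactly the contribution of the semantic/functional
channels — chance-level control AUC (~0.5) indicates those channels carry
essentially all of the ranking signal at this scale.

What passing the benchmark shows: the pipeline recovers planted
module structure well above a matched control, and every computational
step equals its brute-force reference. What it does not show: performance
on real catalogues, whose disease vocabularies, annotation biases, DAG
topology and similarity calibration differ from the planted model; the
noise here is independent flips, whereas real false annotations are
correlated with study effort per disease.

## Degenerate inputs and edge cases

* Empty association file, non-square or asymmetric similarity bodies,
  cyclic or self-looped DAG edges → errors naming the offending line/cell;
  slight asymmetry (> 1e-8) is averaged with a warning.
* A similarity matrix that is constant over its available entries cannot
  be z-scored (error); in the pipeline a degenerate *primary* matrix falls
  back to the kernel entirely, with a warning.
* Diseases whose rows become all-zero during case-study "isolated" mode
  are scored purely from the disease-similarity channels.
* All floating-point comparisons in tests use explicit tolerances; the
  vectorized scorer is arithmetic-identical (not merely close) to the
  scalar reference on the SDMA path.

## Known limitations

* The rigorous LOOCV is O(folds × (kernel + SVD + scoring)); at catalogue
  scale (≈ 5400 folds on 383 × 495) it is minutes-to-hours territory —
  use `fast_loocv` for exploratory sweeps there.
* MeSH descriptor parsing and HMDD/dbDEMC lookups are out of scope: the
  DAG arrives as an edge list, and matching disease labels to ontology
  terms is the caller's responsibility.
* Multi-category diseases (several MeSH trees) are supported only insofar
  as the edge list encodes them as one DAG.
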