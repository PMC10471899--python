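# Methods

## Model

`pathreg` estimates gene-set enrichment as a penalized generalized linear
model.  The response is the vector of per-gene differential-expression
*P*-values, assumed beta-distributed with gene-specific mean μ_i and a single
precision φ shared across genes (shape parameters p_i = μ_i φ and
q_i = (1−μ_i) φ).  The mean is linked to the binary membership matrix **X**
through a logit link, logit(μ) = **Xβ**, so that β = 0 puts every gene at
μ = 1/2.  The fitted objective is

−log L(β, φ) + λ‖β‖₁ + ψ Σᵢ Σⱼ (βᵢ − βⱼ)² g_ij ,

with the fusion double sum running over all *ordered* pairs: each unordered
pair is counted twice and the diagonal contributes nothing.  This convention
matters when comparing ψ values across implementations; internally the sum
is evaluated as 2 βᵀLβ with L the graph Laplacian of the similarity weights.

Modeling assumptions worth stating explicitly:

- a *linear* combination of memberships drives the linear predictor — genes
  in several enriched sets get compounded means;
- one global precision φ; no per-gene or per-set dispersion;
- *P*-values are taken at face value (no beta-uniform mixture for the null
  component; exact 0/1 values are clamped to [ε, 1−ε], ε = 10⁻⁶ by default,
  rather than rescaled).

There is no intercept by default: under the logit link β = 0 already
corresponds to the μ = 1/2 baseline that matches the symmetric null of the
synthetic generator.  For real data whose global *P*-value level is shifted,
`ModelConfig(include_intercept=True)` adds an unpenalized intercept.

## Optimization

Estimation uses monotone proximal gradient descent.  The smooth part
(negative log-likelihood plus fusion penalty) is differentiated analytically;
the L1 term is handled by the soft-threshold proximal operator, so exact
zeros are attainable.  φ is parametrized as exp(θ) with θ unconstrained and
unpenalized.  The step size starts at `step_size` (default 0.05), is halved
whenever a step would increase the full objective (the step is rejected), and
regrows by 10% after each accepted epoch; the recorded once-per-epoch
objective trace is therefore non-increasing by construction.  Convergence is
declared when the relative objective change falls below `tol` (default 10⁻⁶,
cap `max_epochs` = 2000).  Optional mini-batching (`batch_size`) estimates
the likelihood gradient on shuffled batches rescaled to the full-data scale;
the monotone accept/reject safeguard still applies at the epoch level.
Against an independent L-BFGS fit of the same likelihood, the unpenalized
optimum agrees to ≲10⁻³ per coefficient at N = 200.

λ and ψ are selected by K-fold cross-validation over genes (default 5 folds,
grids {0} ∪ logspace(10⁻⁴, 10¹, 7)), scored by mean per-gene held-out
*unpenalized* log-likelihood.  Ties prefer the smallest λ, then the smallest
ψ — the most parsimonious model among equals.

## Similarity measures

Jaccard (|∩|/|∪|) and the overlap coefficient (|∩|/min) are built in; the
overlap coefficient saturates at 1 for nested sets and suits hierarchical
collections.  Any square matrix with entries in [0,1] can be supplied
instead (e.g. a semantic similarity computed elsewhere).  Similarities are
computed on the size-filtered database, by default from full term gene lists;
a `gene_universe` argument restricts terms to measured genes first, for
users who prefer similarity among observed memberships.  Size filtering
likewise counts full term gene lists, not the intersection with the measured
universe.

## Synthetic benchmark generator

The generator emulates a DE experiment with a known answer:

1. **Term database.** `generate_term_database` builds blocks of terms
   sharing a nested core (a prefix of a per-block core gene list of relative
   size `within_block_overlap`), remaining genes drawn from a common pool.
   This produces the high within-block/low between-block similarity profile
   of redundant curated collections without any download.
2. **Activated terms.** The first of `n_active` terms is uniform; each next
   one is drawn from the mixture (1−ρ)·uniform + ρ·S_j over not-yet-sampled
   terms, S_j the similarity column of the previous draw.  Draws are forced
   distinct (without-replacement renormalization) so the truth always has
   exactly `n_active` terms; if the mixture mass vanishes (ρ = 1, no similar
   terms left) the draw falls back to uniform and logs a warning.
3. **Activation vector.** Activated terms get coefficient −1 (configurable),
   all others 0.
4. **Annotation noise.** A fraction η of the 1-entries in activated-term
   columns is zeroed, uniformly without replacement; the count is
   round-half-up of η·m.  Inactive columns are untouched.
5. **Response.** μ = logistic(X_A β_A); p_i ~ Beta(μ_i φ, (1−μ_i) φ) with
   φ = 1 by default.

A master seed spawns per-step child seeds, so each step is reproducible in
isolation.  The gene universe is the sorted union of term genes.

**Null-gene law.** Genes in no activated term have μ = 1/2, hence
p ~ Beta(φ/2, φ/2).  At the default φ = 1 this is the arcsine law — more
boundary-heavy than uniform — and only φ = 2 makes null *P*-values exactly
Uniform(0,1).  The tests verify both: uniformity at φ = 2 and the
Beta(1/2, 1/2) law at φ = 1.  Consumers who want calibrated uniform nulls
should simulate with φ = 2.

What the generator does *not* emulate: read counts or an upstream DE
pipeline (only *P*-values are produced), gene-gene correlation within a
term, per-gene precision heterogeneity, and real GO-style directed-acyclic
hierarchy (blocks are flat).  Passing benchmarks here therefore demonstrate
correct recovery under the model's own generative assumptions, not
performance on any particular real dataset.

## Evaluation

A term is called enriched at threshold *t* when its (higher-is-better)
score is ≥ *t*; all methods are mapped onto this orientation first
(|β| for the regression, 1−p for Fisher and the null).  Sweeping *t* over
the distinct score values yields the PR curve, with tied scores moving as a
block and precision at zero calls defined as 1.  PR-AUC uses the step-wise
average-precision rule Σ ΔR·P (trapezoidal integration overestimates
PR-AUC and is deliberately not used).  Precision-at-recall reads the curve
at the strictest threshold whose recall reaches the target (0.8 by default).
Fisher's baseline stratifies genes at P < 0.05 (the stratification threshold
is configurable) and applies the one-sided hypergeometric tail; no
multiple-testing correction is applied because threshold sweeps make
rank-preserving corrections irrelevant to PR evaluation.

## Benchmark problem sizes

The shipped benchmark (tests and `scripts/acceptance.py`) uses a 200-term
database (sizes 20–100, 10 blocks, overlap 0.5, 3000-gene pool → ~2700
measured genes), 20 activated terms, φ = 1, η ∈ {0, 0.25}, ρ ∈ {0, 0.5},
10 replicates per condition.  The regression method selects (λ, ψ) per
replicate by 3-fold cross-validation over the coarse grid
λ ∈ {0, 1, 10} × ψ ∈ {0, 0.1, 1} — a desk-scale stand-in for the full
default grid that keeps the whole 40-replicate run at a few minutes on one
CPU.  Under these conditions the regression model's median PR-AUC exceeds
Fisher's exact test, which exceeds the random null, in every condition, and
its precision advantage at recall 0.8 is largest under annotation noise.

## Numerical notes and edge cases

- Fitted means are clipped to [10⁻¹², 1−10⁻¹²] before likelihood evaluation.
- `beta_log_likelihood` is evaluated via log-gamma functions and matches an
  independent beta-density implementation to 10⁻⁸ over random parameter
  triples.
- Ranking ties (equal |β|) break by term id ascending, making output tables
  byte-stable across reruns.
- The network view drops isolated nodes and keeps edges with similarity
  strictly greater than the threshold (default 0.1, top 50 terms); whichever
  similarity matrix was supplied at fit time is used.
- Degenerate inputs fail loudly: empty databases after size filtering,
  duplicate gene or term identifiers, *P*-values outside [0,1], folds with
  fewer than two genes, and an all-isolated network each raise a specific
  error (or log a warning where the result is still well defined).

## Known limitations

Confidence intervals for β are not provided (the penalties bias the
estimates; de-biasing is out of scope).  Only the logit link is implemented.
External methods enter the benchmark only as precomputed score tables.  The
beta likelihood treats *P*-values as exact draws; heavy discreteness (e.g.
permutation *P*-values with few permutations) violates that.
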