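# Methods

## Model

Two binary bipartite interaction networks are factorized jointly:
drug–disease `X⁽¹⁾` (n₁ × m₁) and drug–target `X⁽²⁾` (n₂ × m₂), each as a
product of non-negative factors `U⁽ⁱ⁾ V⁽ⁱ⁾ᵀ` of rank `rᵢ`. Four penalty
terms shape the fit:

1. **Weighted reconstruction.** Only positive interactions are observed;
   an absent entry is unknown, not negative. Observed entries enter the
   squared loss with weight 1, unobserved entries with weight `w ∈ [0,1)`
   (one-class collaborative filtering). The effective weights in all
   gradients are `W∘W`, i.e. 1 and `w²`.
2. **Cross-network consistency.** The sparse anchor matrix `S` (n₂ × n₁,
   at most one 1 per row and per column) identifies drugs present in both
   networks. The penalty `β‖(SU⁽¹⁾)(SU⁽¹⁾)ᵀ − U⁽²⁾U⁽²⁾ᵀ‖²_F` makes the
   *Gram matrices* of anchored drug factors agree — drugs similar in one
   domain's latent space stay similar after projection into the other.
   Agreement of Grams rather than factors themselves avoids forcing a
   common rank or basis alignment between domains.
3. **Within-network smoothness.** For each similarity matrix `A` with
   degree matrix `D` (row sums) and Laplacian `L = D − A`, the trace
   penalty `α tr(MᵀLM)` pulls latent rows of similar entities together.
4. **Sparsity.** An l1 penalty `γ(‖U‖₁ + ‖V‖₁)`; with non-negative
   factors this is just the entry sum.

Prediction is the inner product `X̃⁽ⁱ⁾(u,v) = U⁽ⁱ⁾(u,:) · V⁽ⁱ⁾(v,:)ᵀ`.
Known training positives are *not* masked at prediction time; excluding
them from a ranking is the evaluator's decision.

### Assumptions

- Interactions are adequately described by a low-rank non-negative
  structure; the model is linear in the latent space.
- A drug's latent representation is transferable between domains up to
  small perturbations (the anchored-Gram consistency).
- Similarity matrices are non-negative, (near-)symmetric, and informative
  about latent proximity; they may be bounded in [0,1] or unbounded
  (unbounded scales are used as-is by default, with an optional
  max-normalization flag, and flagged at load time).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r1, r2` | 90, 70 | factor ranks (dimensionless); clamped when infeasible, see below |
| `alpha` | 0.01 | weight of graph-Laplacian smoothness |
| `beta` | 0.01 | weight of cross-network Gram consistency |
| `gamma` | 0.01 | l1 sparsity weight |
| `w` | 0.3 | confidence of unobserved entries, in [0,1) |
| `delta` | 1e-6 | convergence tolerance on the objective change |
| `max_iter` | 500 | maximum update sweeps |
| `seed` | 0 | initialization seed |

The rank defaults suit networks of roughly a thousand entities per side.
A practical heuristic is `rᵢ ≤ 0.1·min(nᵢ, mᵢ)`: when a requested rank
exceeds `min(nᵢ, mᵢ)` (infeasible), it is clamped to
`max(1, ⌊0.1·min(nᵢ, mᵢ)⌋)` with a warning. Feasible ranks are honoured
as given, so deliberately small experiments are not second-guessed.

## Optimization

Multiplicative updates, alternating `U⁽¹⁾, U⁽²⁾, V⁽¹⁾, V⁽²⁾` per sweep
(order configurable; fixed by default for reproducibility):

```
U⁽¹⁾ ← U⁽¹⁾ ⊙ [X⁽¹⁾V⁽¹⁾ + α A_u⁽¹⁾U⁽¹⁾ + 2β Δ] ⁄ [T⁽¹⁾ + α D_u⁽¹⁾U⁽¹⁾ + 2β Θ + 0.5γ]
U⁽²⁾ ← U⁽²⁾ ⊙ [X⁽²⁾V⁽²⁾ + α A_u⁽²⁾U⁽²⁾ + 2β Ξ] ⁄ [T⁽²⁾ + α D_u⁽²⁾U⁽²⁾ + 2β U⁽²⁾U⁽²⁾ᵀU⁽²⁾ + 0.5γ]
V⁽ⁱ⁾ ← V⁽ⁱ⁾ ⊙ [X⁽ⁱ⁾ᵀU⁽ⁱ⁾ + α A_v⁽ⁱ⁾V⁽ⁱ⁾] ⁄ [(R⁽ⁱ⁾ᵀ + w² V⁽ⁱ⁾U⁽ⁱ⁾ᵀ)U⁽ⁱ⁾ + α D_v⁽ⁱ⁾V⁽ⁱ⁾ + 0.5γ]
```

with `Δ = SᵀU⁽²⁾U⁽²⁾ᵀSU⁽¹⁾`, `Θ = SᵀSU⁽¹⁾U⁽¹⁾ᵀSᵀSU⁽¹⁾`,
`Ξ = SU⁽¹⁾U⁽¹⁾ᵀSᵀU⁽²⁾`, `R⁽ⁱ⁾ = (1−w²)·I⁽ⁱ⁾⊙(U⁽ⁱ⁾V⁽ⁱ⁾ᵀ)`,
`T⁽ⁱ⁾ = (R⁽ⁱ⁾ + w²U⁽ⁱ⁾V⁽ⁱ⁾ᵀ)V⁽ⁱ⁾`, and `I⁽ⁱ⁾` the observed-entry
indicator. Each denominator equals the positive part of the gradient and
each numerator its negative part, so fixed points of the ratio are
stationary points of J. The reconstruction pieces touch the dense product
only through `I⊙(UVᵀ)` on the sparse support plus Gram products, giving
O(nmr + n²r) per sweep; `SᵀS` is constant and cached before the loop.

### Numerical choices

- **Initialization.** Factor entries are drawn uniformly from (0, 1),
  scaled by `sqrt(mean(X)/r)` so the initial product matches the data
  scale, from four independent seeded streams (one per factor matrix).
  Strictly positive initialization avoids spurious zero-locking:
  multiplicative rules can never revive an exact zero.
- **Division guard.** ε = 1e-12 is added to every denominator after the
  `0.5γ` shift. This keeps ratios defined at empty rows/columns while
  perturbing fixed points only at numerical precision.
- **Descent safeguard for the cross term.** The cross-network penalty is
  *quartic* in `U⁽¹⁾`/`U⁽²⁾`, and plain multiplicative ratio steps on
  quartic terms can overshoot — on random small instances with β ≥ 0.01
  the bare rules above occasionally increase J, and at β = 1 they can
  diverge (the same phenomenon is documented for symmetric NMF). The
  U-updates therefore use the bare rule as the proposed step and accept it
  only if the objective does not increase; otherwise the step is damped as
  `U ⊙ ratio^θ` with θ halved (30 attempts), falling back to no movement.
  Damping preserves non-negativity, exact zeros, and fixed points (a ratio
  of 1 is 1 at any θ), and the accepted-at-θ=1 path is bit-identical to
  the bare rule. With β = 0 the updates are the provably monotone weighted
  graph-regularized NMF rules and run unsafeguarded, which keeps the
  decoupled path exactly equal to two independent single-domain fits.
- **Convergence.** The loop stops when `|J(t+1) − J(t)| ≤ delta`
  (absolute, the default) or after `max_iter` sweeps; a relative variant
  (`|ΔJ| ≤ delta·max(|J|, 1)`) is available because J's scale is
  data-dependent. A non-finite objective aborts with a diagnostic.
- **Convergence behaviour in practice.** On the default synthetic
  conditions the objective falls steeply and then flattens: more than 99%
  of the total decrease is realized within the first 100 sweeps. The
  *absolute* tail is much slower — multiplicative updates approach
  stationary points sublinearly, and reaching `|ΔJ| ≤ 1e-6` at an
  objective scale of J ≈ 60 takes on the order of a thousand sweeps (it
  takes hundreds of sweeps even when initialized at the ground-truth
  factors). Practical runs should either use the relative criterion or
  treat `max_iter` as the effective stop; rankings are stable long before
  the absolute tolerance is met.
- **Tie-breaking.** All rankings sort by `(−score, candidate id)` — stable
  and platform-independent.

## Data handling

- Edge lists: `<row_id><sep><col_id>`, tab/comma auto-detected, header
  skipped only when explicitly flagged. Repeated edges collapse; a third
  column is honoured only when it is 0/1.
- Similarity matrices are symmetrized as `(A + Aᵀ)/2` on load; asymmetry
  beyond 1e-6 warns first. Negative or NaN entries are errors. The
  diagonal is kept as provided and degrees include it by default
  (`include_diagonal=False` zeroes self-similarities first; neither
  convention is canonical, both are supported).
- Anchors are exact, case-sensitive identifier equality between the two
  drug id lists — no fuzzy matching, to avoid silent mis-anchoring.
- Edge lists cannot represent isolated entities, so when a problem is
  assembled from files the similarity matrices define the entity universe
  and the interaction matrix is expanded to it.
- Model serialization writes one delimited file per factor with id
  headers at 17 significant digits plus a JSON manifest; reloading
  restores predictions bit-exactly (`float_precision="round_trip"`).

## Evaluation protocol

Three five-fold CV scenarios per domain: `pair` (partition known
interactions; held-out positives become unknowns — value 0, weight `w` —
in training), `new_row_entity` and `new_col_entity` (partition entities;
all their interactions are held out, the cold-start setting). The other
domain's network is kept whole during CV so anchors keep transferring
knowledge. Test sets in the `pair` scenario are balanced: each fold's
positives are scored against an equal number of uniformly sampled unknown
pairs (disjoint from all positives and across folds). Metrics: AUROC via
the rank statistic (ties count 1/2, identical to the normalized
Mann–Whitney U), AUPR as the uninterpolated step curve (average
precision; trapezoidal interpolation would inflate it), and precision@k
(k ∈ {5, 10, 15}). In the cold-start scenarios precision@k is computed
per held-out entity over all candidates and averaged; `pair` metrics are
pooled over the fold. Experiments are repeated (default 10×) with
independent folds and negatives; per-repeat values and their mean are
reported.

Enrichment of top-ranked predictions against a reference set uses the
upper-tail hypergeometric probability `P(X ≥ k)`, summed from log-pmf
terms with logsumexp, so p-values far below double underflow (e.g.
1e-144) are computed exactly.

## Synthetic data generator

The generator emulates the structural features the method relies on:
two sparse binary bipartite networks whose drug sets partially overlap
(default: half of the domain-2 drugs are anchored), planted low-rank
structure (cluster-style non-negative factors, rank 6), anchored drugs
sharing their factor rows across domains up to perturbation noise
(sd 0.05), and four intra-layer similarity matrices. Defaults: 80×60
drug–disease and 70×50 drug–target networks with densities 6% and 12% —
desk-scale stand-ins for networks thousands of entities wide whose real
densities (0.3–2%) would leave too few interactions per fold at this
size. The evaluated domain is deliberately the sparse one and the
auxiliary domain the denser one: the coupling exists to move information
from a whole, information-rich network into a sparse one.

Two deliberate realism choices:

- **Interactions are top-quantile binarizations** of the true score
  matrix `UVᵀ` (exact count, ties broken by index) rather than iid
  Bernoulli draws, so the planted ranking remains recoverable at low
  density and realized density matches the target to within one entry.
- **Similarities are noisy proxies.** Kernels (cosine by default, RBF
  optional) are computed from latent features perturbed with Gaussian
  noise (sd 0.5) — real chemical-fingerprint or semantic similarities
  correlate imperfectly with interaction-relevant structure. Noiseless
  kernels would make every prediction task solvable from similarities
  alone and mask any effect of the coupling.

What the generator does **not** emulate: marginal distributions of real
fingerprint similarities, degree heterogeneity/hubs, unbounded similarity
scales, biased (non-uniform) missingness, or inter-entity correlations
beyond the planted low-rank structure. Tests passing on this generator
show the machinery is correct and that cross-domain transfer works when
its assumptions hold; they do not certify effect sizes on real databases.

The transfer-benefit experiment masks 60% of the sparse domain's
positives, fits once with β = 0.01 and once with β = 0 from identical
initializations on identical training data, scores the held-out pairs
against the clean truth, and compares the paired AUROCs over 10
generator seeds with a one-sided sign test.

## Problem sizes used by the test suite and acceptance script

Update-rule and oracle checks run on random instances up to 20×20 at rank
≤ 4; decoupling on 25×20 / 20×15; transfer benefit and convergence on the
default 80×60 / 70×50 conditions; the enrichment example uses the
published counts (5,239,086 candidate pairs; 6,260 evaluated pairs; the
6,260 is reproduced by an actual top-20-per-disease ranking over a
593×313 problem). These sizes were chosen so the full pipeline,
repetitions included, runs in well under a minute on one core while still
exercising every code path at meaningful scale.

## Known limitations

- Linear latent-factor model: nonlinear interaction structure is out of
  reach by design.
- The anchor map is one-to-one by identifier; drugs with inconsistent
  identifiers across sources will silently remain un-anchored.
- Multiplicative updates converge slowly in absolute objective change
  (see above); they are also not guaranteed to find a global optimum of
  the non-convex objective — different seeds give different local optima.
- Raw similarity computation (fingerprints, sequence alignment, ontology
  semantics) and database access are out of scope; inputs are files.
- The balanced-negative evaluation protocol estimates ranking quality
  under a 1:1 class ratio; real screening settings are far more
  imbalanced and AUPR there would be lower for every method.
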