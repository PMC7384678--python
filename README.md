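# couplednmf

Joint drug repositioning and drug–target prediction by **coupled,
graph-regularized, weighted non-negative matrix factorization** of two
bipartite interaction networks linked through the drugs they share.

## The problem

Predicting new drug–disease indications and new drug–target interactions
are usually treated as separate link-prediction problems on separate
networks. But the two networks overlap: many drugs appear in both, and a
drug's targets are evidence about its plausible indications (and vice
versa). This package factorizes both networks *simultaneously* and
transfers knowledge between them through the shared drugs ("anchors"),
which is particularly valuable for sparse networks and cold-start
entities.

It is intended for computational drug-discovery researchers who have
binary interaction data (edge lists) and precomputed intra-layer
similarity matrices (e.g. chemical-fingerprint similarity between drugs,
semantic similarity between diseases, sequence similarity between
targets). Computing those similarities from raw structures/sequences is
out of scope — they are inputs.

## The model

Domain 1 is the drug–disease network `X⁽¹⁾ ∈ {0,1}^{n₁×m₁}`, domain 2 the
drug–target network `X⁽²⁾ ∈ {0,1}^{n₂×m₂}`. Each is approximated by
non-negative rank-`rᵢ` factors, `X⁽ⁱ⁾ ≈ U⁽ⁱ⁾ V⁽ⁱ⁾ᵀ`. With `S` the sparse
`n₂×n₁` anchor matrix (`S[i,j]=1` iff drug *i* of domain 2 is drug *j* of
domain 1), the fitted factors minimize

```
J = Σᵢ ‖W⁽ⁱ⁾ ⊙ (X⁽ⁱ⁾ − U⁽ⁱ⁾V⁽ⁱ⁾ᵀ)‖²_F                (weighted reconstruction)
  + β ‖(S U⁽¹⁾)(S U⁽¹⁾)ᵀ − U⁽²⁾U⁽²⁾ᵀ‖²_F             (cross-network consistency)
  + α Σᵢ [ tr(U⁽ⁱ⁾ᵀ L_u⁽ⁱ⁾ U⁽ⁱ⁾) + tr(V⁽ⁱ⁾ᵀ L_v⁽ⁱ⁾ V⁽ⁱ⁾) ]   (graph smoothness)
  + γ Σᵢ ( ‖U⁽ⁱ⁾‖₁ + ‖V⁽ⁱ⁾‖₁ )                       (sparsity)
```

subject to `U⁽ⁱ⁾, V⁽ⁱ⁾ ≥ 0`. `W⁽ⁱ⁾` is 1 on observed interactions and
`w ∈ [0,1)` elsewhere (one-class weighting: unobserved means unknown, not
negative); `L = D − A` are graph Laplacians of the similarity matrices.
Optimization is by alternating multiplicative updates; predicted
association scores are `X̃⁽ⁱ⁾ = U⁽ⁱ⁾V⁽ⁱ⁾ᵀ`. Defaults follow
`α = β = γ = 0.01`, `w = 0.3`. See `docs/methods.md` for the update rules,
convergence behaviour and all numerical choices.

## Worked example

No external data is needed — the synthetic generator produces a coupled
problem with planted shared drug factors:

```python
from couplednmf import (SyntheticSpec, HyperParameters, generate, fit,
                        predict_scores, rank_candidates)

problem, truth = generate(SyntheticSpec(seed=7))
hp = HyperParameters(r1=6, r2=6, alpha=0.01, beta=0.01, gamma=0.01,
                     w=0.3, seed=0, max_iter=500)
model = fit(problem, hp)
print(f"converged: {model.converged} after {model.iterations_run} sweeps, "
      f"J: {model.objective_trace[0]:.1f} -> {model.objective_trace[-1]:.1f}")

scores = predict_scores(model, 1)           # drug x disease score matrix
ranked = rank_candidates(problem.domain1.X.row_ids, scores[:, 0])
```

This prints:

```
converged: False after 500 sweeps, J: 675.8 -> 65.7
```

(the objective keeps creeping down below the default absolute tolerance
for a long tail — see `docs/methods.md`), and the top of the ranking for
the first disease is

```
dis0000  rank 1: drug0054* score=1.022
dis0000  rank 2: drug0037* score=0.972
dis0000  rank 3: drug0049* score=0.969
dis0000  rank 4: drug0040* score=0.962
dis0000  rank 5: drug0065* score=0.959
```

where `*` marks drugs whose interaction with `dis0000` was in the training
data: known positives score highest, as they should, and the scores of
unmarked candidates are the repositioning hypotheses. Scores are inner
products of non-negative latent factors — larger means more consistent
with the low-rank interaction structure and the similarity graphs.

The same works from the shell:

```
couplednmf simulate --out data/ --seed 7
couplednmf fit --interactions1 data/interactions_domain1.tsv ... --out model/
couplednmf predict --model model/ --top-k 20
couplednmf evaluate --interactions1 ... --scenario pair --out report/
```

Every run writes a `run_manifest.json` (config, config hash, input file
hashes, seed) sufficient to reproduce it exactly.

## Evaluation protocol

`run_experiment` implements three five-fold cross-validation scenarios per
domain — `pair` (hide known interactions), `new_row_entity` (cold-start
drugs) and `new_col_entity` (cold-start diseases/targets) — with balanced
negative sampling, AUROC, AUPR and precision@k, repeated with independent
folds and averaged. While one domain is under cross-validation the other
network is kept whole, so anchors keep transferring knowledge.
`hypergeometric_enrichment` gives the upper-tail p-value for overlap
between top-ranked predictions and a reference interaction set, computed
in log space so p-values like 1e-144 are exact.

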