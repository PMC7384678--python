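"""Cross-validation protocol, ranking metrics, and enrichment testing.

Three five-fold CV scenarios are supported for either domain:

* ``pair`` -- known interactions are split into folds; held-out positives
  are treated as unknowns (weight ``w``) during training and scored
  against an equal number of sampled unknown pairs.
* ``new_row_entity`` -- cold start for drugs: drugs are split into five
  disjoint subsets and all interactions of held-out drugs form the test
  set (their training rows are fully zeroed).
* ``new_col_entity`` -- the symmetric cold start for diseases/targets.

While one domain is under cross-validation, the other domain's network is
kept whole, so knowledge still flows through the anchors.  Metrics: AUROC
(rank statistic, ties count 1/2), AUPR (step curve, average-precision
style, no interpolation), and precision@k with deterministic tie-breaking
by (-score, candidate id).  The enrichment test is the upper-tail
hypergeometric survival probability, evaluated in log space so that
p-values far below double underflow of 1 - cdf remain exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp
from scipy.stats import hypergeom
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_model import BipartiteInteractionMatrix, CrossDomainProblem
from .factorization import HyperParameters, fit, predict_scores

__all__ = [
    "EvaluationSplit",
    "MetricReport",
    "split_pair_cv",
    "split_entity_cv",
    "sample_negatives",
    "auroc",
    "aupr",
    "precision_at_k",
    "rank_candidates",
    "hypergeometric_enrichment",
    "log10_hypergeometric_enrichment",
    "run_experiment",
]

SCENARIOS = ("pair", "new_row_entity", "new_col_entity")


@dataclass
class EvaluationSplit:
    """One fold of one CV scenario over one interaction matrix."""

    scenario: str
    fold_index: int
    test_positives: np.ndarray          # (t, 2) row/col index pairs
    test_negatives: np.ndarray          # (t, 2); empty for entity scenarios
    held_out_entities: np.ndarray       # entity indices (entity scenarios)
    rng_seed: int

    def train_matrix(self, X: BipartiteInteractionMatrix) -> BipartiteInteractionMatrix:
        """Training copy of X with this fold's test interactions zeroed."""
        train = X.values.tolil(copy=True)
        for i, j in self.test_positives:
            train[i, j] = 0.0
        return X.with_values(train.tocsr())


@dataclass
class MetricReport:
    """Per-repeat metric values and their means across repeats."""

    scenario: str
    domain_index: int
    n_repeats: int
    per_repeat: list = field(default_factory=list)  # list of dicts
    mean: dict = field(default_factory=dict)

    def finalize(self):
        keys = self.per_repeat[0].keys()
        self.mean = {k: float(np.mean([r[k] for r in self.per_repeat]))
                     for k in keys}
        return self


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_pair_cv(X: BipartiteInteractionMatrix, n_folds: int = 5,
                  seed: int = 0) -> list[EvaluationSplit]:
    """Partition the known interactions into folds; sample balanced negatives.

    Every positive appears in exactly one test fold.  Each fold also gets an
    equal number of uniformly sampled unknown pairs as test negatives,
    disjoint across folds and from all positives.
    """
    positives = X.positive_pairs()
    if len(positives) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positive interactions, have {len(positives)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds = np.array_split(order, n_folds)
    taken: set[tuple[int, int]] = set(map(tuple, positives))
    splits = []
    for f, idx in enumerate(folds):
        test_pos = positives[idx]
        test_neg = _sample_unknown_pairs(X, len(test_pos), rng, exclude=taken)
        taken.update(map(tuple, test_neg))
        splits.append(EvaluationSplit(
            scenario="pair", fold_index=f,
            test_positives=test_pos, test_negatives=test_neg,
            held_out_entities=np.empty(0, dtype=int), rng_seed=seed,
        ))
    return splits


def split_entity_cv(X: BipartiteInteractionMatrix, axis: str = "rows",
                    n_folds: int = 5, seed: int = 0) -> list[EvaluationSplit]:
    """Cold-start folds: partition entities, hold out all their interactions."""
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    n_entities = X.shape[0] if axis == "rows" else X.shape[1]
    if n_entities < n_folds:
        raise ValueError(
            f"need at least {n_folds} entities along {axis}, have {n_entities}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_entities)
    folds = np.array_split(order, n_folds)
    positives = X.positive_pairs()
    key = positives[:, 0] if axis == "rows" else positives[:, 1]
    scenario = "new_row_entity" if axis == "rows" else "new_col_entity"
    splits = []
    for f, entities in enumerate(folds):
        mask = np.isin(key, entities)
        splits.append(EvaluationSplit(
            scenario=scenario, fold_index=f,
            test_positives=positives[mask],
            test_negatives=np.empty((0, 2), dtype=int),
            held_out_entities=np.sort(entities), rng_seed=seed,
        ))
    return splits


def _sample_unknown_pairs(X: BipartiteInteractionMatrix, count: int, rng,
                          exclude: set | None = None) -> np.ndarray:
    n, m = X.shape
    forbidden = set(map(tuple, X.positive_pairs()))
    if exclude:
        forbidden = forbidden | set(exclude)
    if n * m - len(forbidden) < count:
        raise ValueError("not enough unknown pairs to sample negatives")
    chosen: list[tuple[int, int]] = []
    seen = set(forbidden)
    while len(chosen) < count:
        flat = rng.integers(0, n * m, size=max(4 * (count - len(chosen)), 16))
        for idx in flat:
            pair = (int(idx // m), int(idx % m))
            if pair not in seen:
                seen.add(pair)
                chosen.append(pair)
                if len(chosen) == count:
                    break
    return np.array(chosen, dtype=int)


def sample_negatives(X: BipartiteInteractionMatrix, test_positives,
                     seed: int = 0) -> np.ndarray:
    """Uniformly sample |test_positives| unknown pairs (all positives excluded)."""
    rng = np.random.default_rng(seed)
    return _sample_unknown_pairs(X, len(test_positives), rng)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _split_scores_labels(scored):
    scored = list(scored)
    scores = np.array([s for s, _ in scored], dtype=float)
    labels = np.array([int(l) for _, l in scored], dtype=int)
    return scores, labels


def auroc(scored) -> float:
    """Area under the ROC curve of (score, label) pairs; ties count 1/2.

    Equivalent to the normalized Mann-Whitney U statistic.
    """
    scores, labels = _split_scores_labels(scored)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both positive and negative examples")
    return float(roc_auc_score(labels, scores))


def aupr(scored) -> float:
    """Area under the precision-recall step curve (average precision)."""
    scores, labels = _split_scores_labels(scored)
    if labels.sum() == 0:
        raise ValueError("AUPR needs at least one positive example")
    return float(average_precision_score(labels, scores))


def rank_candidates(candidates, scores) -> list:
    """Candidates sorted by (-score, candidate id); deterministic under ties."""
    return [c for c, _ in sorted(zip(candidates, scores),
                                 key=lambda t: (-t[1], t[0]))]


def precision_at_k(ranked, truth, k: int) -> float:
    """Fraction of the top-k ranked candidates that are in the truth set."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds the {len(ranked)} available candidates; "
            "computing over all of them"
        )
        k = len(ranked)
    truth = set(truth)
    if not truth:
        return 0.0
    return sum(1 for c in ranked[:k] if c in truth) / k


def log10_hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """log10 of the upper-tail hypergeometric p-value P(X >= k).

    Population of N pairs contains K positives; n pairs are drawn and k of
    them are positive.  Summation runs over the log pmf of the tail, so
    p-values far beyond double underflow keep full precision.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(
            f"inconsistent counts: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 0.0
    support = np.arange(k, min(n, K) + 1)
    log_tail = logsumexp(hypergeom.logpmf(support, N, K, n))
    return float(log_tail / np.log(10.0))


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) (may underflow to 0.0
    below ~1e-308; use the log10 variant for extreme tails)."""
    return float(10.0 ** log10_hypergeometric_enrichment(N, K, n, k))


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def _training_problem(problem: CrossDomainProblem, domain_index: int,
                      split: EvaluationSplit) -> CrossDomainProblem:
    """Problem copy with the evaluated domain's test interactions removed;
    the other domain's network is kept whole."""
    from .data_model import DomainData

    dom = problem.domain(domain_index)
    X_train = split.train_matrix(dom.X)
    new_dom = DomainData(X_train, dom.A_row, dom.A_col, dom.L_row, dom.L_col)
    if domain_index == 1:
        return CrossDomainProblem(new_dom, problem.domain2, problem.anchors)
    return CrossDomainProblem(problem.domain1, new_dom, problem.anchors)


def _fold_metrics(problem, domain_index, split, hp, ks, neg_seed):
    train_problem = _training_problem(problem, domain_index, split)
    model = fit(train_problem, hp)
    scores = predict_scores(model, domain_index)
    X = problem.domain(domain_index).X
    out = {}
    if split.scenario == "pair":
        pairs = np.vstack([split.test_positives, split.test_negatives])
        labels = np.r_[np.ones(len(split.test_positives), dtype=int),
                       np.zeros(len(split.test_negatives), dtype=int)]
        vals = scores[pairs[:, 0], pairs[:, 1]]
        scored = list(zip(vals, labels))
        out["auroc"] = auroc(scored)
        out["aupr"] = aupr(scored)
        ranked = rank_candidates(
            [tuple(p) for p in pairs.tolist()], vals)
        truth = set(map(tuple, split.test_positives.tolist()))
        for k in ks:
            out[f"precision_at_{k}"] = precision_at_k(ranked, truth, k)
    else:
        # per held-out entity: rank all candidates, average precision@k;
        # AUROC/AUPR pooled over test positives vs sampled unknowns
        axis_rows = split.scenario == "new_row_entity"
        truth_by_entity: dict[int, set[int]] = {}
        for i, j in split.test_positives:
            e, c = (i, j) if axis_rows else (j, i)
            truth_by_entity.setdefault(int(e), set()).add(int(c))
        n_cand = X.shape[1] if axis_rows else X.shape[0]
        cands = np.arange(n_cand)
        for k in ks:
            vals = []
            for e, truth in truth_by_entity.items():
                svec = scores[e, :] if axis_rows else scores[:, e]
                ranked = rank_candidates(cands.tolist(), svec)
                vals.append(precision_at_k(ranked, truth, k))
            out[f"precision_at_{k}"] = float(np.mean(vals)) if vals else 0.0
        if len(split.test_positives):
            neg = sample_negatives(X, split.test_positives, seed=neg_seed)
            pairs = np.vstack([split.test_positives, neg])
            labels = np.r_[np.ones(len(split.test_positives), dtype=int),
                           np.zeros(len(neg), dtype=int)]
            vals = scores[pairs[:, 0], pairs[:, 1]]
            scored = list(zip(vals, labels))
            out["auroc"] = auroc(scored)
            out["aupr"] = aupr(scored)
    return out


def run_experiment(problem: CrossDomainProblem, hp: HyperParameters,
                   scenario: str, domain_index: int = 1,
                   n_repeats: int = 10, n_folds: int = 5, seed: int = 0,
                   ks=(5, 10, 15)) -> MetricReport:
    """Repeated five-fold CV of one scenario in one domain.

    Each repeat draws fresh folds (and negatives); per-fold metrics are
    averaged within a repeat, and the report carries per-repeat values and
    their mean across repeats.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    X = problem.domain(domain_index).X
    report = MetricReport(scenario=scenario, domain_index=domain_index,
                          n_repeats=n_repeats)
    for rep in range(n_repeats):
        rep_seed = seed + 1000 * rep
        if scenario == "pair":
            splits = split_pair_cv(X, n_folds=n_folds, seed=rep_seed)
        else:
            axis = "rows" if scenario == "new_row_entity" else "cols"
            splits = split_entity_cv(X, axis=axis, n_folds=n_folds,
                                     seed=rep_seed)
        hp_rep = hp.replace(seed=hp.seed + rep)
        fold_vals = [
            _fold_metrics(problem, domain_index, s, hp_rep, ks,
                          neg_seed=rep_seed + s.fold_index + 1)
            for s in splits
        ]
        keys = fold_vals[0].keys()
        report.per_repeat.append(
            {k: float(np.mean([fv[k] for fv in fold_vals])) for k in keys}
        )
    return report.finalize()
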