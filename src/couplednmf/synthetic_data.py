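"""Synthetic coupled two-domain problems with planted low-rank structure.

The generator emulates the structure of the real drug-disease /
drug-target inputs at desk scale: two sparse binary bipartite networks
whose drug sets partially overlap, plus four intra-layer similarity
matrices.  Ground truth is planted:

1. every entity gets a non-negative latent factor row with a dominant
   "cluster" coordinate (so similarities are informative);
2. anchored drugs (a configurable fraction of domain-2 drugs) copy their
   domain-1 factor row exactly, then receive small per-domain perturbation
   noise -- the cross-domain consistency assumption made literal;
3. interactions are the top-quantile entries of the true score matrix
   U V^T, binarized to hit the requested density (quantile binarization
   rather than iid Bernoulli keeps the planted ranking recoverable at
   low density);
4. similarities are a kernel (cosine or RBF) of *noise-perturbed* latent
   features: real similarity matrices (chemical fingerprints, semantic
   similarity) are imperfect proxies of interaction-relevant structure,
   and noiseless kernels would make the task trivially solvable from
   similarities alone;
5. optional label noise flips entries.

The default densities make the evaluated drug-disease domain the sparse
one (6%) and the auxiliary drug-target domain the information-rich one
(12%), mirroring the setting the coupling is designed for: knowledge
flows through the anchors from a whole auxiliary network into a sparse
target network.

Both the observable problem and the hidden truth are returned, enabling
parameter-recovery and transfer-benefit experiments without any external
database.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.stats import binomtest

from .data_model import (
    BipartiteInteractionMatrix,
    CrossDomainProblem,
    SimilarityMatrix,
    build_problem,
    write_anchor_map,
    write_interactions,
    write_similarity,
)
from .factorization import FactorModel, HyperParameters, fit, predict_scores

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "masked_split",
    "heldout_eval",
    "transfer_benefit",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic coupled problem."""

    n1: int = 80            # drugs in the drug-disease domain
    m1: int = 60            # diseases
    n2: int = 70            # drugs in the drug-target domain
    m2: int = 50            # targets
    r_true: int = 6         # planted rank
    overlap_fraction: float = 0.5   # fraction of domain-2 drugs anchored
    density1: float = 0.06          # sparse evaluated domain
    density2: float = 0.12          # information-rich auxiliary domain
    noise_flip_rate: float = 0.0
    similarity_kernel: str = "cosine"
    perturbation_sd: float = 0.05   # per-domain noise on shared drug rows
    similarity_feature_noise_sd: float = 0.5  # similarity = noisy proxy
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        for d in (self.density1, self.density2):
            if not (0.0 < d <= 0.5):
                raise ValueError("densities must lie in (0, 0.5]")
        if self.r_true > min(self.n1, self.m1, self.n2, self.m2):
            raise ValueError("r_true must not exceed any entity count")
        if not (0.0 <= self.noise_flip_rate < 0.5):
            raise ValueError("noise_flip_rate must lie in [0, 0.5)")
        if self.similarity_kernel not in ("cosine", "rbf"):
            raise ValueError("similarity_kernel must be 'cosine' or 'rbf'")
        if self.similarity_feature_noise_sd < 0:
            raise ValueError("similarity_feature_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Hidden factors and clean matrices behind a generated problem."""

    U1: np.ndarray
    V1: np.ndarray
    U2: np.ndarray
    V2: np.ndarray
    scores1: np.ndarray       # U1 @ V1.T
    scores2: np.ndarray
    X1_clean: np.ndarray      # binary, before label noise
    X2_clean: np.ndarray


def _latent_factors(n: int, r: int, rng) -> np.ndarray:
    """Cluster-structured non-negative factors: one dominant coordinate."""
    F = rng.uniform(0.0, 0.2, size=(n, r))
    clusters = rng.integers(0, r, size=n)
    F[np.arange(n), clusters] = rng.uniform(0.8, 1.2, size=n)
    return F


def _binarize_top(Y: np.ndarray, density: float) -> np.ndarray:
    """Keep exactly round(density * size) top entries (ties by flat index)."""
    n_keep = int(round(density * Y.size))
    if n_keep < 1:
        raise ValueError("requested density keeps zero interactions")
    flat_order = np.argsort(-Y.ravel(), kind="stable")
    X = np.zeros(Y.size)
    X[flat_order[:n_keep]] = 1.0
    return X.reshape(Y.shape)


def _cosine_kernel(F: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(F, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    sim = (F @ F.T) / np.outer(safe, safe)
    sim = np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def _rbf_kernel(F: np.ndarray) -> np.ndarray:
    sq = np.sum(F ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (F @ F.T), 0.0)
    bandwidth = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return np.exp(-d2 / (2.0 * bandwidth))


def generate(spec: SyntheticSpec) -> tuple[CrossDomainProblem, GroundTruth]:
    """Draw one coupled problem and its hidden ground truth."""
    rng = np.random.default_rng(spec.seed)
    r = spec.r_true

    ids1 = [f"drug{i:04d}" for i in range(spec.n1)]
    dis_ids = [f"dis{i:04d}" for i in range(spec.m1)]
    tgt_ids = [f"tgt{i:04d}" for i in range(spec.m2)]

    n_anchor = int(round(spec.overlap_fraction * spec.n2))
    n_anchor = min(n_anchor, spec.n1, spec.n2)
    anchor_dom1 = rng.choice(spec.n1, size=n_anchor, replace=False)
    ids2 = [ids1[a] for a in anchor_dom1]
    ids2 += [f"xdrug{i:04d}" for i in range(spec.n2 - n_anchor)]
    order = rng.permutation(spec.n2)
    ids2 = [ids2[i] for i in order]

    U1 = _latent_factors(spec.n1, r, rng)
    V1 = _latent_factors(spec.m1, r, rng)
    V2 = _latent_factors(spec.m2, r, rng)
    U2 = _latent_factors(spec.n2, r, rng)
    # anchored drugs share their domain-1 factor row (plus small noise)
    dom1_of = {d: i for i, d in enumerate(ids1)}
    for i2, d in enumerate(ids2):
        if d in dom1_of:
            row = U1[dom1_of[d]] + rng.normal(0.0, spec.perturbation_sd, size=r)
            U2[i2] = np.maximum(row, 0.0)

    scores1 = U1 @ V1.T
    scores2 = U2 @ V2.T
    X1_clean = _binarize_top(scores1, spec.density1)
    X2_clean = _binarize_top(scores2, spec.density2)

    def flip(X):
        if spec.noise_flip_rate <= 0:
            return X.copy()
        flips = rng.random(X.shape) < spec.noise_flip_rate
        return np.abs(X - flips.astype(float))

    X1 = flip(X1_clean)
    X2 = flip(X2_clean)
    if X1.sum() == 0 or X2.sum() == 0:
        raise ValueError("generated network has no positive interactions")

    kernel = _cosine_kernel if spec.similarity_kernel == "cosine" else _rbf_kernel

    def proxy(F):
        # similarities are computed from noisy copies of the latent
        # features, emulating imperfect real-world similarity measures
        noisy = F + rng.normal(0.0, spec.similarity_feature_noise_sd, F.shape)
        return kernel(np.maximum(noisy, 0.0))

    Au1 = SimilarityMatrix(ids1, proxy(U1))
    Av1 = SimilarityMatrix(dis_ids, proxy(V1))
    Au2 = SimilarityMatrix(ids2, proxy(U2))
    Av2 = SimilarityMatrix(tgt_ids, proxy(V2))

    X1m = BipartiteInteractionMatrix(ids1, dis_ids, sp.csr_matrix(X1),
                                     "drug_disease")
    X2m = BipartiteInteractionMatrix(ids2, tgt_ids, sp.csr_matrix(X2),
                                     "drug_target")
    problem = build_problem(X1m, Au1, Av1, X2m, Au2, Av2)
    truth = GroundTruth(U1=U1, V1=V1, U2=U2, V2=V2,
                        scores1=scores1, scores2=scores2,
                        X1_clean=X1_clean, X2_clean=X2_clean)
    return problem, truth


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def masked_split(X: BipartiteInteractionMatrix, fraction: float, seed: int):
    """Hold out a fraction of positives plus an equal number of unknowns.

    Returns (training matrix with held-out positives zeroed, test pairs,
    test labels).
    """
    from .evaluation import _sample_unknown_pairs

    rng = np.random.default_rng(seed)
    positives = X.positive_pairs()
    n_test = max(1, int(round(fraction * len(positives))))
    idx = rng.choice(len(positives), size=n_test, replace=False)
    test_pos = positives[idx]
    test_neg = _sample_unknown_pairs(X, n_test, rng)
    train = X.values.tolil(copy=True)
    for i, j in test_pos:
        train[i, j] = 0.0
    X_train = X.with_values(train.tocsr())
    pairs = np.vstack([test_pos, test_neg])
    labels = np.r_[np.ones(n_test, dtype=int), np.zeros(n_test, dtype=int)]
    return X_train, pairs, labels


def heldout_eval(truth: GroundTruth, model: FactorModel,
                 test_pairs: np.ndarray, domain_index: int = 1) -> dict:
    """AUROC/AUPR of a model's scores against the clean hidden labels."""
    from .evaluation import aupr, auroc

    scores = predict_scores(model, domain_index)
    clean = truth.X1_clean if domain_index == 1 else truth.X2_clean
    vals = scores[test_pairs[:, 0], test_pairs[:, 1]]
    labels = clean[test_pairs[:, 0], test_pairs[:, 1]].astype(int)
    scored = list(zip(vals, labels))
    return {"auroc": auroc(scored), "aupr": aupr(scored)}


def transfer_benefit(spec: SyntheticSpec, hp: HyperParameters,
                     n_seeds: int = 10, mask_fraction: float = 0.6) -> dict:
    """Paired comparison of coupled (beta > 0) vs decoupled (beta = 0) fits.

    For each seed: generate a problem, mask a fraction of domain-1
    positives as the test set, fit once with the given beta and once with
    beta = 0 on identical training data and initializations, and score the
    held-out pairs against the clean truth.  Reports per-seed AUROC pairs
    and a one-sided sign test that the coupled fit wins.
    """
    from .data_model import CrossDomainProblem, DomainData

    auroc_beta, auroc_zero = [], []
    for s in range(n_seeds):
        problem, truth = generate(replace(spec, seed=spec.seed + s))
        X_train, pairs, _ = masked_split(problem.domain1.X, mask_fraction,
                                         seed=spec.seed + 7919 * (s + 1))
        d1 = problem.domain1
        train_problem = CrossDomainProblem(
            DomainData(X_train, d1.A_row, d1.A_col, d1.L_row, d1.L_col),
            problem.domain2, problem.anchors,
        )
        hp_s = hp.replace(seed=hp.seed + s)
        model_b = fit(train_problem, hp_s)
        model_0 = fit(train_problem, hp_s.replace(beta=0.0))
        auroc_beta.append(heldout_eval(truth, model_b, pairs)["auroc"])
        auroc_zero.append(heldout_eval(truth, model_0, pairs)["auroc"])
    wins = sum(b > z for b, z in zip(auroc_beta, auroc_zero))
    losses = sum(b < z for b, z in zip(auroc_beta, auroc_zero))
    if wins + losses:
        p = binomtest(wins, wins + losses, alternative="greater").pvalue
    else:
        p = 1.0
    return {
        "auroc_beta": auroc_beta,
        "auroc_zero": auroc_zero,
        "mean_gain": float(np.mean(np.array(auroc_beta) - np.array(auroc_zero))),
        "wins": wins,
        "losses": losses,
        "sign_test_p": float(p),
    }


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(problem: CrossDomainProblem, outdir) -> list:
    """Write the seven input files (2 edge lists, 4 similarities, anchors)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    d1, d2 = problem.domain1, problem.domain2
    files = {
        "interactions_domain1.tsv": lambda p: write_interactions(d1.X, p),
        "interactions_domain2.tsv": lambda p: write_interactions(d2.X, p),
        "similarity_drug_domain1.tsv": lambda p: write_similarity(d1.A_row, p),
        "similarity_col_domain1.tsv": lambda p: write_similarity(d1.A_col, p),
        "similarity_drug_domain2.tsv": lambda p: write_similarity(d2.A_row, p),
        "similarity_col_domain2.tsv": lambda p: write_similarity(d2.A_col, p),
        "anchors.tsv": lambda p: write_anchor_map(
            problem.anchors, d2.X.row_ids, d1.X.row_ids, p),
    }
    paths = []
    for name, writer in files.items():
        path = os.path.join(outdir, name)
        writer(path)
        paths.append(path)
    return paths
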