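"""Coupled graph-regularized weighted NMF with anchored drug factors.

The model factorizes two binary interaction matrices simultaneously,

* domain 1: drug-disease ``X1 ~ U1 @ V1.T`` (n1 x m1, rank r1),
* domain 2: drug-target  ``X2 ~ U2 @ V2.T`` (n2 x m2, rank r2),

and couples them through the drugs present in both networks.  With
``S`` the sparse n2 x n1 anchor matrix (S[i, j] = 1 iff drug i of domain 2
is drug j of domain 1), the objective minimized is

    J =   sum_i || W_i (*) (X_i - U_i V_i^T) ||_F^2
        + beta * || (S U1)(S U1)^T - U2 U2^T ||_F^2
        + alpha * sum_i ( tr(U_i^T L_u_i U_i) + tr(V_i^T L_v_i V_i) )
        + gamma * sum_i ( ||U_i||_1 + ||V_i||_1 ),       U_i, V_i >= 0

where (*) is the Hadamard product, W_i is 1 on observed interactions and
w in [0, 1) elsewhere (one-class weighting), L = D - A are the graph
Laplacians of the intra-layer similarity matrices, and the beta term makes
the Gram matrices of anchored drug factors agree across domains.

Optimization uses multiplicative updates, which preserve non-negativity
and monotonically decrease J.  The reconstruction terms only ever touch
observed entries through the sparse indicator, so a sweep costs
O(n m r + n^2 r); ``S^T S`` is cached once before the loop.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import BipartiteInteractionMatrix, CrossDomainProblem

__all__ = [
    "HyperParameters",
    "FactorModel",
    "FitState",
    "objective",
    "cross_consistency",
    "update_U1",
    "update_U2",
    "update_V",
    "fit",
    "fit_single_domain",
    "predict_scores",
    "save_model",
    "load_model",
]

#: division guard added to every multiplicative-update denominator
EPS = 1e-12

_DEFAULT_ORDER = ("U1", "U2", "V1", "V2")


@dataclass
class HyperParameters:
    """All tunables of the coupled factorization.

    ``alpha`` weights within-network smoothness, ``beta`` cross-network
    consistency, ``gamma`` the l1 sparsity penalty; ``w`` is the confidence
    assigned to unobserved interactions.  Convergence stops the sweep loop
    once |J(t+1) - J(t)| <= delta (or the relative analogue).
    """

    r1: int = 90
    r2: int = 70
    alpha: float = 0.01
    beta: float = 0.01
    gamma: float = 0.01
    w: float = 0.3
    delta: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    convergence: str = "abs"          # "abs": |dJ| <= delta; "rel": |dJ|/|J| <= delta
    update_order: tuple = _DEFAULT_ORDER

    def __post_init__(self):
        if self.r1 < 1 or self.r2 < 1:
            raise ValueError("ranks must be positive integers")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("alpha, beta, gamma must be >= 0")
        if not (0.0 <= self.w < 1.0):
            raise ValueError(f"w must lie in [0, 1), got {self.w}")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.convergence not in ("abs", "rel"):
            raise ValueError("convergence must be 'abs' or 'rel'")
        if sorted(self.update_order) != sorted(_DEFAULT_ORDER):
            raise ValueError("update_order must permute ('U1','U2','V1','V2')")

    def replace(self, **kw) -> "HyperParameters":
        d = self.__dict__.copy()
        d.update(kw)
        return HyperParameters(**d)


@dataclass
class FactorModel:
    """Fitted non-negative factors plus the optimization trace."""

    U1: np.ndarray
    V1: np.ndarray
    U2: np.ndarray
    V2: np.ndarray
    hp: HyperParameters
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    iterations_run: int = 0
    row_ids1: list = None
    col_ids1: list = None
    row_ids2: list = None
    col_ids2: list = None
    # training positives per domain, as (row, col) index pairs
    train_positives1: list = None
    train_positives2: list = None


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _masked_uv(rows: np.ndarray, cols: np.ndarray,
               U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """(U V^T) evaluated only at the given index pairs."""
    return np.einsum("ij,ij->i", U[rows], V[cols])


def _weighted_recon(X: sp.csr_matrix, rows, cols, U, V, w: float) -> float:
    """|| W (*) (X - U V^T) ||_F^2 without forming the dense residual.

    Splits the sum into observed entries (weight 1) and unobserved entries
    (weight w):  sum_obs (1 - yhat)^2 + w^2 (||U V^T||_F^2 - sum_obs yhat^2).
    """
    yhat = _masked_uv(rows, cols, U, V)
    total_sq = float(np.sum((U.T @ U) * (V.T @ V)))  # ||UV^T||_F^2
    obs = float(np.sum((1.0 - yhat) ** 2))
    return obs + w * w * (total_sq - float(np.sum(yhat ** 2)))


def cross_consistency(U1: np.ndarray, U2: np.ndarray,
                      S: sp.spmatrix) -> float:
    """Disagreement ||(S U1)(S U1)^T - U2 U2^T||_F^2 between drug Grams."""
    if S.shape != (U2.shape[0], U1.shape[0]):
        raise ValueError(
            f"anchor matrix shape {S.shape} incompatible with factors "
            f"({U2.shape[0]} x {U1.shape[0]} expected)"
        )
    P = S @ U1
    C = P @ P.T - U2 @ U2.T
    return float(np.sum(C * C))


def _smoothness(L: np.ndarray, M: np.ndarray) -> float:
    return float(np.sum(M * (L @ M)))


def objective(problem: CrossDomainProblem, model: FactorModel,
              hp: HyperParameters | None = None) -> float:
    """Evaluate the unified objective J for the given factors."""
    hp = hp or model.hp
    factors = [(model.U1, model.V1), (model.U2, model.V2)]
    J = 0.0
    for i, (U, V) in enumerate(factors, start=1):
        dom = problem.domain(i)
        n, m = dom.X.shape
        if U.shape[0] != n or V.shape[0] != m or U.shape[1] != V.shape[1]:
            raise ValueError(f"factor shapes inconsistent with domain {i}")
        if np.any(U < 0) or np.any(V < 0):
            raise ValueError("factors must be non-negative")
        coo = dom.X.values.tocoo()
        J += _weighted_recon(dom.X.values, coo.row, coo.col, U, V, hp.w)
        J += hp.alpha * (_smoothness(dom.L_row.laplacian, U)
                         + _smoothness(dom.L_col.laplacian, V))
        J += hp.gamma * (float(np.sum(U)) + float(np.sum(V)))
    J += hp.beta * cross_consistency(model.U1, model.U2,
                                     problem.anchors.matrix_form)
    return J


# ---------------------------------------------------------------------------
# multiplicative updates
# ---------------------------------------------------------------------------

@dataclass
class FitState:
    """Everything one update sweep needs, with static pieces precomputed."""

    X1: sp.csr_matrix
    X2: sp.csr_matrix
    rows1: np.ndarray            # observed-entry indices of X1 (indicator I1)
    cols1: np.ndarray
    rows2: np.ndarray
    cols2: np.ndarray
    Au1: np.ndarray
    du1: np.ndarray              # degree diagonals
    Av1: np.ndarray
    dv1: np.ndarray
    Au2: np.ndarray
    du2: np.ndarray
    Av2: np.ndarray
    dv2: np.ndarray
    S: sp.csr_matrix
    StS: sp.csr_matrix           # cached S^T S
    hp: HyperParameters
    U1: np.ndarray = None
    V1: np.ndarray = None
    U2: np.ndarray = None
    V2: np.ndarray = None

    @property
    def has_cross(self) -> bool:
        return self.hp.beta > 0 and self.S.nnz > 0


def _recon_numer_denom(X, rows, cols, U, V, w):
    """Gradient split of the weighted reconstruction term w.r.t. U.

    numerator part: X V (observed entries have weight 1, X=1 there);
    denominator part: T = ((1 - w^2) I (*) (U V^T) + w^2 U V^T) V.
    """
    M = sp.csr_matrix((_masked_uv(rows, cols, U, V), (rows, cols)),
                      shape=X.shape)
    T = (1.0 - w * w) * (M @ V) + (w * w) * (U @ (V.T @ V))
    return X @ V, T


def _descent_safeguard(state: FitState, name: str,
                       ratio: np.ndarray) -> np.ndarray:
    """Accept the multiplicative step only if it does not increase J.

    The plain ratio rule provably descends for the quadratic terms (it is
    the weighted graph-regularized NMF update), but the cross-network
    consistency term is *quartic* in U1 and U2, and there the full step can
    overshoot.  Exponent halving -- U (*) ratio^theta with theta = 1, 1/2,
    1/4, ... -- keeps non-negativity, exact zeros and fixed points (a ratio
    of 1 is 1 at any theta), reduces to the printed rule whenever that rule
    descends, and falls back to no movement if no damped step descends.
    Only used when the cross term is active; the beta = 0 path is the
    untouched plain rule.
    """
    U = getattr(state, name)
    J0 = _state_objective(state)
    theta = 1.0
    for _ in range(30):
        candidate = U * ratio ** theta if theta != 1.0 else U * ratio
        setattr(state, name, candidate)
        J = _state_objective(state)
        setattr(state, name, U)
        if J <= J0 * (1.0 + 1e-12):
            return candidate
        theta *= 0.5
    return U.copy()


def update_U1(state: FitState) -> np.ndarray:
    hp = state.hp
    U1, V1, U2 = state.U1, state.V1, state.U2
    num, T1 = _recon_numer_denom(state.X1, state.rows1, state.cols1,
                                 U1, V1, hp.w)
    num = num + hp.alpha * (state.Au1 @ U1)
    den = T1 + hp.alpha * (state.du1[:, None] * U1) + 0.5 * hp.gamma
    if state.has_cross:
        P = state.S @ U1
        delta = state.S.T @ (U2 @ (U2.T @ P))          # S^T U2 U2^T S U1
        Q = state.StS @ U1
        theta = Q @ (U1.T @ Q)                         # S^T S U1 U1^T S^T S U1
        num = num + 2.0 * hp.beta * delta
        den = den + 2.0 * hp.beta * theta
        return _descent_safeguard(state, "U1", num / (den + EPS))
    return U1 * (num / (den + EPS))


def update_U2(state: FitState) -> np.ndarray:
    hp = state.hp
    U1, U2, V2 = state.U1, state.U2, state.V2
    num, T2 = _recon_numer_denom(state.X2, state.rows2, state.cols2,
                                 U2, V2, hp.w)
    num = num + hp.alpha * (state.Au2 @ U2)
    den = T2 + hp.alpha * (state.du2[:, None] * U2) + 0.5 * hp.gamma
    if hp.beta > 0:
        if state.S.nnz > 0:
            P = state.S @ U1
            xi = P @ (P.T @ U2)                        # S U1 U1^T S^T U2
            num = num + 2.0 * hp.beta * xi
        den = den + 2.0 * hp.beta * (U2 @ (U2.T @ U2))
        return _descent_safeguard(state, "U2", num / (den + EPS))
    return U2 * (num / (den + EPS))


def update_V(state: FitState, domain_index: int) -> np.ndarray:
    hp = state.hp
    if domain_index == 1:
        X, rows, cols, U, V = state.X1, state.rows1, state.cols1, state.U1, state.V1
        Av, dv = state.Av1, state.dv1
    elif domain_index == 2:
        X, rows, cols, U, V = state.X2, state.rows2, state.cols2, state.U2, state.V2
        Av, dv = state.Av2, state.dv2
    else:
        raise ValueError("domain index must be 1 or 2")
    w2 = hp.w * hp.w
    # (R^T + w^2 V U^T) U  with R = (1 - w^2) I (*) (U V^T)
    M = sp.csr_matrix((_masked_uv(rows, cols, U, V), (rows, cols)),
                      shape=X.shape)
    den = (1.0 - w2) * (M.T @ U) + w2 * (V @ (U.T @ U))
    den = den + hp.alpha * (dv[:, None] * V) + 0.5 * hp.gamma
    num = X.T @ U + hp.alpha * (Av @ V)
    return V * (num / (den + EPS))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _clamped_ranks(hp: HyperParameters, problem: CrossDomainProblem):
    """Clamp an infeasible rank to the 0.1*min(n, m) heuristic, warning."""
    ranks = []
    for i, r in ((1, hp.r1), (2, hp.r2)):
        n, m = problem.domain(i).X.shape
        if r > min(n, m):
            r_new = max(1, int(0.1 * min(n, m)))
            warnings.warn(
                f"rank r{i}={r} exceeds min(n, m)={min(n, m)} for domain {i}; "
                f"clamped to {r_new} (<= 0.1*min(n, m) heuristic)"
            )
            r = r_new
        ranks.append(r)
    return tuple(ranks)


def _init_factor(n: int, r: int, x_mean: float, rng) -> np.ndarray:
    """Strictly positive uniform init, scale-matched so U V^T ~ mean(X)."""
    scale = np.sqrt(max(x_mean, 1e-4) / r)
    return rng.uniform(1e-12, 1.0, size=(n, r)) * scale


def _factor_rngs(seed: int):
    """Four independent streams (U1, V1, U2, V2) derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def _build_state(problem: CrossDomainProblem, hp: HyperParameters) -> FitState:
    d1, d2 = problem.domain1, problem.domain2
    coo1 = d1.X.values.tocoo()
    coo2 = d2.X.values.tocoo()
    S = problem.anchors.matrix_form.tocsr()
    return FitState(
        X1=d1.X.values, X2=d2.X.values,
        rows1=coo1.row, cols1=coo1.col, rows2=coo2.row, cols2=coo2.col,
        Au1=d1.A_row.values, du1=d1.L_row.degree,
        Av1=d1.A_col.values, dv1=d1.L_col.degree,
        Au2=d2.A_row.values, du2=d2.L_row.degree,
        Av2=d2.A_col.values, dv2=d2.L_col.degree,
        S=S, StS=(S.T @ S).tocsr(), hp=hp,
    )


def _state_objective(state: FitState, beta_term: bool = True) -> float:
    hp = state.hp
    J = _weighted_recon(state.X1, state.rows1, state.cols1,
                        state.U1, state.V1, hp.w)
    J += _weighted_recon(state.X2, state.rows2, state.cols2,
                         state.U2, state.V2, hp.w)
    for U, Au, du in ((state.U1, state.Au1, state.du1),
                      (state.U2, state.Au2, state.du2)):
        J += hp.alpha * (float(np.sum(U * (du[:, None] * U)))
                         - float(np.sum(U * (Au @ U))))
    for V, Av, dv in ((state.V1, state.Av1, state.dv1),
                      (state.V2, state.Av2, state.dv2)):
        J += hp.alpha * (float(np.sum(V * (dv[:, None] * V)))
                         - float(np.sum(V * (Av @ V))))
    J += hp.gamma * float(np.sum(state.U1) + np.sum(state.V1)
                          + np.sum(state.U2) + np.sum(state.V2))
    if beta_term and hp.beta > 0:
        J += hp.beta * cross_consistency(state.U1, state.U2, state.S)
    return J


_UPDATES = {
    "U1": lambda st: setattr(st, "U1", update_U1(st)),
    "U2": lambda st: setattr(st, "U2", update_U2(st)),
    "V1": lambda st: setattr(st, "V1", update_V(st, 1)),
    "V2": lambda st: setattr(st, "V2", update_V(st, 2)),
}


def _converged(J_prev: float, J: float, hp: HyperParameters) -> bool:
    dJ = abs(J - J_prev)
    if hp.convergence == "rel":
        return dJ <= hp.delta * max(abs(J_prev), 1.0)
    return dJ <= hp.delta


def fit(problem: CrossDomainProblem, hp: HyperParameters | None = None,
        init: dict | None = None) -> FactorModel:
    """Fit both domains jointly by alternating multiplicative updates.

    A sweep updates U1, U2, V1, V2 (order configurable through
    ``hp.update_order``); the loop stops when |J(t+1) - J(t)| <= delta or
    after ``max_iter`` sweeps.  ``init`` may supply explicit starting
    factors (keys U1, V1, U2, V2); otherwise factors are drawn uniformly,
    seeded, with one independent stream per factor matrix.
    """
    hp = hp or HyperParameters()
    r1, r2 = _clamped_ranks(hp, problem)
    hp = hp.replace(r1=r1, r2=r2)
    state = _build_state(problem, hp)

    n1, m1 = problem.domain1.X.shape
    n2, m2 = problem.domain2.X.shape
    if init is not None:
        state.U1 = np.array(init["U1"], dtype=float)
        state.V1 = np.array(init["V1"], dtype=float)
        state.U2 = np.array(init["U2"], dtype=float)
        state.V2 = np.array(init["V2"], dtype=float)
    else:
        rngs = _factor_rngs(hp.seed)
        mean1 = problem.domain1.X.n_interactions / (n1 * m1)
        mean2 = problem.domain2.X.n_interactions / (n2 * m2)
        state.U1 = _init_factor(n1, r1, mean1, rngs[0])
        state.V1 = _init_factor(m1, r1, mean1, rngs[1])
        state.U2 = _init_factor(n2, r2, mean2, rngs[2])
        state.V2 = _init_factor(m2, r2, mean2, rngs[3])

    trace = [_state_objective(state)]
    converged = False
    iterations = 0
    for _ in range(hp.max_iter):
        for key in hp.update_order:
            _UPDATES[key](state)
        J = _state_objective(state)
        if not np.isfinite(J):
            raise RuntimeError(
                f"objective became non-finite at sweep {iterations + 1}"
            )
        trace.append(J)
        iterations += 1
        if _converged(trace[-2], J, hp):
            converged = True
            break

    return FactorModel(
        U1=state.U1, V1=state.V1, U2=state.U2, V2=state.V2, hp=hp,
        objective_trace=trace, converged=converged, iterations_run=iterations,
        row_ids1=list(problem.domain1.X.row_ids),
        col_ids1=list(problem.domain1.X.col_ids),
        row_ids2=list(problem.domain2.X.row_ids),
        col_ids2=list(problem.domain2.X.col_ids),
        train_positives1=[list(map(int, p))
                          for p in problem.domain1.X.positive_pairs()],
        train_positives2=[list(map(int, p))
                          for p in problem.domain2.X.positive_pairs()],
    )


def fit_single_domain(X: BipartiteInteractionMatrix, A_row, A_col,
                      hp: HyperParameters, domain_index: int = 1):
    """Graph-regularized weighted NMF of one network alone (no coupling).

    Runs the same update arithmetic as :func:`fit` restricted to one
    domain with beta = 0.  Factor initialization draws from the same
    per-factor seed streams the joint fit uses for that domain, so a joint
    fit with beta = 0 and no anchors reproduces this result exactly.
    """
    from .data_model import DomainData, build_laplacian

    if domain_index not in (1, 2):
        raise ValueError("domain index must be 1 or 2")
    dom = DomainData(X, A_row, A_col)
    n, m = X.shape
    r = hp.r1 if domain_index == 1 else hp.r2
    if r > min(n, m):
        r_new = max(1, int(0.1 * min(n, m)))
        warnings.warn(f"rank {r} infeasible; clamped to {r_new}")
        r = r_new
    coo = X.values.tocoo()
    hp0 = hp.replace(beta=0.0, r1=r, r2=r)
    empty = sp.csr_matrix((n, n))
    state = FitState(
        X1=X.values, X2=X.values,
        rows1=coo.row, cols1=coo.col, rows2=coo.row, cols2=coo.col,
        Au1=dom.A_row.values, du1=dom.L_row.degree,
        Av1=dom.A_col.values, dv1=dom.L_col.degree,
        Au2=dom.A_row.values, du2=dom.L_row.degree,
        Av2=dom.A_col.values, dv2=dom.L_col.degree,
        S=empty, StS=empty, hp=hp0,
    )
    rngs = _factor_rngs(hp.seed)
    ru, rv = (rngs[0], rngs[1]) if domain_index == 1 else (rngs[2], rngs[3])
    x_mean = X.n_interactions / (n * m)
    U = _init_factor(n, r, x_mean, ru)
    V = _init_factor(m, r, x_mean, rv)
    state.U1 = state.U2 = U
    state.V1 = state.V2 = V

    def single_J():
        J = _weighted_recon(state.X1, state.rows1, state.cols1,
                            state.U1, state.V1, hp0.w)
        J += hp0.alpha * (float(np.sum(state.U1 * (state.du1[:, None] * state.U1)))
                          - float(np.sum(state.U1 * (state.Au1 @ state.U1))))
        J += hp0.alpha * (float(np.sum(state.V1 * (state.dv1[:, None] * state.V1)))
                          - float(np.sum(state.V1 * (state.Av1 @ state.V1))))
        J += hp0.gamma * float(np.sum(state.U1) + np.sum(state.V1))
        return J

    trace = [single_J()]
    converged = False
    iterations = 0
    for _ in range(hp.max_iter):
        state.U1 = state.U2 = update_U1(state)
        state.V1 = state.V2 = update_V(state, 1)
        J = single_J()
        if not np.isfinite(J):
            raise RuntimeError("objective became non-finite")
        trace.append(J)
        iterations += 1
        if _converged(trace[-2], J, hp0):
            converged = True
            break
    return state.U1, state.V1, trace, converged


# ---------------------------------------------------------------------------
# prediction and serialization
# ---------------------------------------------------------------------------

def predict_scores(model: FactorModel, domain_index: int) -> np.ndarray:
    """Dense association scores X~ = U V^T for one domain.

    Training positives are not masked here; excluding known interactions
    from a ranking is the evaluator's (or caller's) decision.
    """
    if domain_index == 1:
        return model.U1 @ model.V1.T
    if domain_index == 2:
        return model.U2 @ model.V2.T
    raise ValueError("domain index must be 1 or 2")


def save_model(model: FactorModel, outdir):
    """One delimited file per factor matrix (id headers) plus a manifest."""
    os.makedirs(outdir, exist_ok=True)
    names = {"U1": model.row_ids1, "V1": model.col_ids1,
             "U2": model.row_ids2, "V2": model.col_ids2}
    for name, ids in names.items():
        M = getattr(model, name)
        idx = ids if ids is not None else [str(i) for i in range(M.shape[0])]
        df = pd.DataFrame(M, index=idx,
                          columns=[f"f{k}" for k in range(M.shape[1])])
        df.to_csv(os.path.join(outdir, f"{name}.csv"), float_format="%.17g")
    manifest = {
        "hyperparameters": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in model.hp.__dict__.items()},
        "objective_trace": list(map(float, model.objective_trace)),
        "converged": bool(model.converged),
        "iterations_run": int(model.iterations_run),
        "train_positives1": model.train_positives1 or [],
        "train_positives2": model.train_positives2 or [],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_model(outdir) -> FactorModel:
    with open(os.path.join(outdir, "manifest.json")) as fh:
        manifest = json.load(fh)
    hpd = manifest["hyperparameters"]
    hpd["update_order"] = tuple(hpd["update_order"])
    hp = HyperParameters(**hpd)
    mats, ids = {}, {}
    for name in ("U1", "V1", "U2", "V2"):
        df = pd.read_csv(os.path.join(outdir, f"{name}.csv"), index_col=0,
                         float_precision="round_trip")
        mats[name] = df.to_numpy(dtype=float)
        ids[name] = [str(x) for x in df.index]
    return FactorModel(
        U1=mats["U1"], V1=mats["V1"], U2=mats["U2"], V2=mats["V2"], hp=hp,
        objective_trace=manifest["objective_trace"],
        converged=manifest["converged"],
        iterations_run=manifest["iterations_run"],
        row_ids1=ids["U1"], col_ids1=ids["V1"],
        row_ids2=ids["U2"], col_ids2=ids["V2"],
        train_positives1=manifest.get("train_positives1", []),
        train_positives2=manifest.get("train_positives2", []),
    )
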