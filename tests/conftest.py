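import numpy as np
import pytest
import scipy.sparse as sp

from couplednmf import (
    BipartiteInteractionMatrix,
    HyperParameters,
    SimilarityMatrix,
    SyntheticSpec,
    build_problem,
    generate,
)
from couplednmf.factorization import _build_state, _init_factor


@pytest.fixture(scope="session")
def tiny_problem():
    """Small deterministic coupled problem for fast factorization tests."""
    spec = SyntheticSpec(n1=12, m1=10, n2=10, m2=8, r_true=3,
                         density1=0.2, density2=0.2, seed=42)
    problem, truth = generate(spec)
    return problem, truth


@pytest.fixture(scope="session")
def default_problem():
    spec = SyntheticSpec()
    problem, truth = generate(spec)
    return problem, truth


def make_random_problem(rng, n1=6, m1=5, n2=5, m2=4, n_anchor=2):
    """Random small two-domain problem built from raw constructors."""
    ids1 = [f"a{i}" for i in range(n1)]
    # first n_anchor domain-2 drugs share ids with domain 1
    ids2 = ids1[:n_anchor] + [f"b{i}" for i in range(n2 - n_anchor)]
    cols1 = [f"c{i}" for i in range(m1)]
    cols2 = [f"d{i}" for i in range(m2)]

    def binary(n, m):
        X = (rng.random((n, m)) < 0.3).astype(float)
        if X.sum() == 0:
            X[0, 0] = 1.0
        return sp.csr_matrix(X)

    def sim(ids):
        n = len(ids)
        A = rng.random((n, n))
        return SimilarityMatrix(ids, (A + A.T) / 2)

    X1 = BipartiteInteractionMatrix(ids1, cols1, binary(n1, m1), "drug_disease")
    X2 = BipartiteInteractionMatrix(ids2, cols2, binary(n2, m2), "drug_target")
    return build_problem(X1, sim(ids1), sim(cols1), X2, sim(ids2), sim(cols2))


def make_state(problem, hp: HyperParameters, rng):
    """FitState with strictly positive random factors, for update-rule tests."""
    state = _build_state(problem, hp)
    n1, m1 = problem.domain1.X.shape
    n2, m2 = problem.domain2.X.shape
    state.U1 = _init_factor(n1, hp.r1, 0.3, rng)
    state.V1 = _init_factor(m1, hp.r1, 0.3, rng)
    state.U2 = _init_factor(n2, hp.r2, 0.3, rng)
    state.V2 = _init_factor(m2, hp.r2, 0.3, rng)
    return state
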