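import numpy as np
import pytest
import scipy.sparse as sp

from couplednmf import (
    BipartiteInteractionMatrix,
    FactorModel,
    HyperParameters,
    SimilarityMatrix,
    SyntheticSpec,
    build_problem,
    cross_consistency,
    fit,
    fit_single_domain,
    generate,
    load_model,
    objective,
    predict_scores,
    save_model,
)
from couplednmf.factorization import (
    FitState,
    _state_objective,
    update_U1,
    update_U2,
    update_V,
)

from conftest import make_random_problem, make_state


# ---------------------------------------------------------------------------
# loop oracles (no linear-algebra shortcuts)
# ---------------------------------------------------------------------------

def objective_loops(problem, U1, V1, U2, V2, alpha, beta, gamma, w):
    """Term-by-term objective computed with explicit entry loops."""
    J = 0.0
    for i, (U, V) in ((1, (U1, V1)), (2, (U2, V2))):
        dom = problem.domain(i)
        X = dom.X.toarray()
        n, m = X.shape
        r = U.shape[1]
        for u in range(n):
            for v in range(m):
                yhat = sum(U[u, k] * V[v, k] for k in range(r))
                weight = 1.0 if X[u, v] > 0 else w
                J += (weight * (X[u, v] - yhat)) ** 2
        for A, L, M in ((dom.A_row.values, dom.L_row.laplacian, U),
                        (dom.A_col.values, dom.L_col.laplacian, V)):
            for a in range(L.shape[0]):
                for b in range(L.shape[0]):
                    for k in range(M.shape[1]):
                        J += alpha * L[a, b] * M[a, k] * M[b, k]
        for M in (U, V):
            for a in range(M.shape[0]):
                for k in range(M.shape[1]):
                    J += gamma * M[a, k]
    J += beta * cross_loops(U1, U2, problem.anchors.matrix_form.toarray())
    return J


def cross_loops(U1, U2, S):
    """||(S U1)(S U1)^T - U2 U2^T||_F^2 by explicit loops."""
    n2, n1 = S.shape
    r1, r2 = U1.shape[1], U2.shape[1]
    P = [[sum(S[i, j] * U1[j, k] for j in range(n1)) for k in range(r1)]
         for i in range(n2)]
    total = 0.0
    for a in range(n2):
        for b in range(n2):
            left = sum(P[a][k] * P[b][k] for k in range(r1))
            right = sum(U2[a, k] * U2[b, k] for k in range(r2))
            total += (left - right) ** 2
    return total


def test_objective_matches_loop_oracle():
    rng = np.random.default_rng(0)
    for trial in range(5):
        problem = make_random_problem(rng, n1=4, m1=3, n2=4, m2=2, n_anchor=2)
        hp = HyperParameters(r1=2, r2=2, alpha=0.7, beta=0.4, gamma=0.2, w=0.3)
        U1, V1 = rng.random((4, 2)), rng.random((3, 2))
        U2, V2 = rng.random((4, 2)), rng.random((2, 2))
        model = FactorModel(U1, V1, U2, V2, hp)
        J = objective(problem, model, hp)
        J_oracle = objective_loops(problem, U1, V1, U2, V2,
                                   hp.alpha, hp.beta, hp.gamma, hp.w)
        assert J == pytest.approx(J_oracle, rel=1e-10)


def test_objective_zero_cases():
    rng = np.random.default_rng(1)
    problem = make_random_problem(rng, n1=4, m1=3, n2=4, m2=2)
    hp = HyperParameters(r1=2, r2=2, alpha=0.0, beta=0.0, gamma=0.0, w=0.3)
    # perfect reconstruction with alpha=beta=gamma=0 gives J = 0:
    # X = I_n @ X^T.T is an exact non-negative factorization
    X1 = problem.domain1.X.toarray()
    X2 = problem.domain2.X.toarray()
    hp0 = HyperParameters(r1=4, r2=4, alpha=0, beta=0, gamma=0, w=0.3)
    model = FactorModel(np.eye(4), X1.T, np.eye(4), X2.T, hp0)
    assert objective(problem, model, hp0) == pytest.approx(0.0, abs=1e-12)


def test_objective_rejects_negative_factors_and_bad_shapes():
    rng = np.random.default_rng(2)
    problem = make_random_problem(rng, n1=4, m1=3, n2=4, m2=2)
    hp = HyperParameters(r1=2, r2=2)
    good = lambda: FactorModel(rng.random((4, 2)), rng.random((3, 2)),
                               rng.random((4, 2)), rng.random((2, 2)), hp)
    m = good()
    m.U1 = m.U1 - 2.0
    with pytest.raises(ValueError, match="non-negative"):
        objective(problem, m, hp)
    m = good()
    m.V1 = rng.random((5, 2))
    with pytest.raises(ValueError, match="inconsistent"):
        objective(problem, m, hp)


def test_cross_consistency_examples():
    rng = np.random.default_rng(3)
    # identity anchors, identical factors -> zero disagreement
    U1 = rng.random((3, 2))
    S = sp.identity(3, format="csr")
    assert cross_consistency(U1, U1.copy(), S) == pytest.approx(0.0, abs=1e-15)
    # no anchors -> ||U2 U2^T||_F^2
    U2 = rng.random((3, 2))
    S0 = sp.csr_matrix((3, 3))
    G = U2 @ U2.T
    assert cross_consistency(U1, U2, S0) == pytest.approx(float(np.sum(G * G)))
    # one-anchor toy matches the loop oracle
    S1 = sp.csr_matrix((np.ones(1), ([1], [2])), shape=(3, 3))
    assert cross_consistency(U1, U2, S1) == pytest.approx(
        cross_loops(U1, U2, S1.toarray()), rel=1e-10)
    with pytest.raises(ValueError, match="anchor"):
        cross_consistency(U1, U2, sp.csr_matrix((4, 3)))


# ---------------------------------------------------------------------------
# update rules
# ---------------------------------------------------------------------------

def test_updates_preserve_nonnegativity_and_zeros():
    rng = np.random.default_rng(4)
    for trial in range(10):
        problem = make_random_problem(rng)
        hp = HyperParameters(r1=2, r2=2, w=float(rng.choice([0.0, 0.3, 0.9])),
                             beta=float(rng.choice([0.0, 0.01, 1.0])))
        state = make_state(problem, hp, rng)
        state.U1[0, :] = 0.0  # multiplicative rule cannot revive exact zeros
        new_U1 = update_U1(state)
        assert np.all(new_U1 >= 0)
        assert np.all(new_U1[0, :] == 0.0)
        assert np.all(update_U2(state) >= 0)
        assert np.all(update_V(state, 1) >= 0)
        assert np.all(update_V(state, 2) >= 0)


def test_update_stationary_at_exact_factorization():
    """At an exact non-negative factorization with no regularization the
    multiplicative ratio is 1 and factors stay put (up to the eps guard)."""
    rng = np.random.default_rng(5)
    problem = make_random_problem(rng, n1=5, m1=4, n2=5, m2=3, n_anchor=0)
    hp = HyperParameters(r1=5, r2=5, alpha=0.0, beta=0.0, gamma=1e-30, w=0.3)
    state = make_state(problem, hp, rng)
    state.U1 = np.eye(5)
    state.V1 = problem.domain1.X.toarray().T.copy()
    new_U1 = update_U1(state)
    # rows of drugs with at least one interaction are at a fixed point;
    # a drug with no interactions has numerator = denominator = 0 and decays
    active = problem.domain1.X.toarray().sum(axis=1) > 0
    mask = (state.U1 > 0) & active[:, None]
    assert mask.any()
    assert np.allclose(new_U1[mask], state.U1[mask], rtol=1e-9)


def test_single_update_does_not_increase_objective():
    rng = np.random.default_rng(6)
    for trial in range(8):
        problem = make_random_problem(rng)
        hp = HyperParameters(r1=2, r2=2,
                             alpha=float(rng.choice([0.0, 0.01, 0.5])),
                             beta=float(rng.choice([0.0, 0.01, 1.0])),
                             gamma=float(rng.choice([0.0, 0.01])),
                             w=float(rng.choice([0.0, 0.3, 0.9])))
        state = make_state(problem, hp, rng)
        for op in (lambda s: setattr(s, "U1", update_U1(s)),
                   lambda s: setattr(s, "U2", update_U2(s)),
                   lambda s: setattr(s, "V1", update_V(s, 1)),
                   lambda s: setattr(s, "V2", update_V(s, 2))):
            before = _state_objective(state)
            op(state)
            after = _state_objective(state)
            assert after <= before * (1 + 1e-8) + 1e-12


# ---------------------------------------------------------------------------
# fit loop
# ---------------------------------------------------------------------------

def test_fit_trace_non_increasing_and_converges(tiny_problem):
    problem, _ = tiny_problem
    hp = HyperParameters(r1=3, r2=3, max_iter=1500, delta=1e-6)
    model = fit(problem, hp)
    tr = np.array(model.objective_trace)
    assert np.all(np.diff(tr) <= 1e-8 * np.maximum(np.abs(tr[:-1]), 1e-30))
    assert model.converged
    assert len(tr) == model.iterations_run + 1
    assert np.all(model.U1 >= 0) and np.all(model.V2 >= 0)


def test_fit_infinite_delta_stops_after_one_sweep(tiny_problem):
    problem, _ = tiny_problem
    hp = HyperParameters(r1=3, r2=3, delta=np.inf)
    model = fit(problem, hp)
    assert model.iterations_run == 1 and model.converged


def test_fit_is_deterministic(tiny_problem):
    problem, _ = tiny_problem
    hp = HyperParameters(r1=3, r2=3, max_iter=30, delta=1e-300, seed=7)
    m1 = fit(problem, hp)
    m2 = fit(problem, hp)
    np.testing.assert_array_equal(m1.U1, m2.U1)
    np.testing.assert_array_equal(m1.V2, m2.V2)


def test_rank_clamped_with_warning(tiny_problem):
    problem, _ = tiny_problem  # 12x10 and 10x8
    hp = HyperParameters(r1=90, r2=70, max_iter=2)
    with pytest.warns(UserWarning, match="clamped"):
        model = fit(problem, hp)
    assert model.U1.shape[1] <= 1 + int(0.1 * 10)
    assert model.hp.r1 <= min(problem.domain1.X.shape)


def test_decoupled_fit_equals_two_single_domain_fits():
    """beta = 0 with no anchors must reproduce independent per-domain
    graph-regularized factorizations exactly (same seeds, same schedule)."""
    spec = SyntheticSpec(n1=15, m1=12, n2=12, m2=10, r_true=3,
                         density1=0.2, density2=0.2,
                         overlap_fraction=0.0, seed=9)
    problem, _ = generate(spec)
    assert len(problem.anchors) == 0
    hp = HyperParameters(r1=3, r2=3, beta=0.0, max_iter=40, delta=1e-300,
                         seed=5)
    joint = fit(problem, hp)
    d1, d2 = problem.domain1, problem.domain2
    U1, V1, _, _ = fit_single_domain(d1.X, d1.A_row, d1.A_col, hp, 1)
    U2, V2, _, _ = fit_single_domain(d2.X, d2.A_row, d2.A_col, hp, 2)
    assert np.max(np.abs(joint.U1 - U1)) <= 1e-10
    assert np.max(np.abs(joint.V1 - V1)) <= 1e-10
    assert np.max(np.abs(joint.U2 - U2)) <= 1e-10
    assert np.max(np.abs(joint.V2 - V2)) <= 1e-10


def test_permutation_equivariance():
    """Permuting domain-1 drugs (and the anchors) permutes U1 rows and
    leaves the objective and the de-permuted scores unchanged."""
    rng = np.random.default_rng(10)
    problem = make_random_problem(rng, n1=6, m1=5, n2=5, m2=4, n_anchor=3)
    n1 = 6
    perm = rng.permutation(n1)
    d1 = problem.domain1
    Xp = BipartiteInteractionMatrix(
        [d1.X.row_ids[p] for p in perm], list(d1.X.col_ids),
        d1.X.values[perm, :], d1.X.domain_tag)
    Aup = SimilarityMatrix([d1.A_row.ids[p] for p in perm],
                           d1.A_row.values[np.ix_(perm, perm)])
    problem_p = build_problem(Xp, Aup, d1.A_col,
                              problem.domain2.X, problem.domain2.A_row,
                              problem.domain2.A_col)
    hp = HyperParameters(r1=2, r2=2, max_iter=25, delta=1e-300, seed=3)
    init = {
        "U1": rng.random((n1, 2)) + 0.1, "V1": rng.random((5, 2)) + 0.1,
        "U2": rng.random((5, 2)) + 0.1, "V2": rng.random((4, 2)) + 0.1,
    }
    init_p = dict(init, U1=init["U1"][perm, :])
    m = fit(problem, hp, init=init)
    mp = fit(problem_p, hp, init=init_p)
    np.testing.assert_allclose(m.objective_trace, mp.objective_trace,
                               rtol=1e-10)
    np.testing.assert_allclose(mp.U1, m.U1[perm, :], rtol=1e-9, atol=1e-12)
    s = predict_scores(m, 1)
    sp_ = predict_scores(mp, 1)
    np.testing.assert_allclose(sp_, s[perm, :], rtol=1e-9, atol=1e-12)


def test_practical_convergence_curve_flattens(default_problem):
    """The objective decreases steadily and the bulk of the decrease
    (>99%) is realized within the first 100 sweeps."""
    problem, _ = default_problem
    hp = HyperParameters(r1=6, r2=6, max_iter=300, delta=1e-300)
    model = fit(problem, hp)
    tr = np.array(model.objective_trace)
    assert np.all(np.diff(tr) <= 1e-8 * np.maximum(np.abs(tr[:-1]), 1e-30))
    assert (tr[0] - tr[100]) >= 0.99 * (tr[0] - tr[-1])


# ---------------------------------------------------------------------------
# prediction and serialization
# ---------------------------------------------------------------------------

def test_predict_scores_examples():
    hp = HyperParameters(r1=2, r2=2)
    eye = np.eye(2)
    m = FactorModel(eye, eye, eye, eye, hp)
    np.testing.assert_array_equal(predict_scores(m, 1), np.eye(2))
    u = np.array([[1.0], [2.0]])
    v = np.array([[3.0], [1.0]])
    m2 = FactorModel(u, v, u, v, HyperParameters(r1=1, r2=1))
    np.testing.assert_array_equal(predict_scores(m2, 1), [[3, 1], [6, 2]])
    z = np.zeros((2, 1))
    m3 = FactorModel(z, z, z, z, HyperParameters(r1=1, r2=1))
    assert np.all(predict_scores(m3, 2) == 0)


def test_model_serialization_round_trip(tiny_problem, tmp_path):
    problem, _ = tiny_problem
    hp = HyperParameters(r1=3, r2=3, max_iter=20, delta=1e-300, seed=1)
    model = fit(problem, hp)
    save_model(model, tmp_path / "model")
    loaded = load_model(tmp_path / "model")
    for name in ("U1", "V1", "U2", "V2"):
        np.testing.assert_array_equal(getattr(model, name),
                                      getattr(loaded, name))
    np.testing.assert_array_equal(predict_scores(model, 1),
                                  predict_scores(loaded, 1))
    assert loaded.hp == model.hp
    assert loaded.converged == model.converged
    assert loaded.row_ids1 == model.row_ids1
    assert loaded.train_positives1 == model.train_positives1


def test_hyperparameter_validation():
    with pytest.raises(ValueError):
        HyperParameters(r1=0)
    with pytest.raises(ValueError):
        HyperParameters(w=1.0)
    with pytest.raises(ValueError):
        HyperParameters(alpha=-0.1)
    with pytest.raises(ValueError):
        HyperParameters(delta=0.0)
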