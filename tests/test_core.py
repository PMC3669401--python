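import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pandanet.core import (
    PandaConfig,
    compute_availability,
    compute_responsibility,
    hamming_distance,
    normalize_network,
    normalize_seeds,
    run_panda,
    tanimoto_similarity,
    update_cooperativity,
    update_coregulation,
    update_regulatory,
)


def tanimoto_oracle(X, Y):
    """Scalar double-loop reference for the continuous Tanimoto score."""
    out = np.zeros((X.shape[0], Y.shape[1]))
    for i in range(X.shape[0]):
        for j in range(Y.shape[1]):
            x, y = X[i, :], Y[:, j]
            dot = sum(xi * yi for xi, yi in zip(x, y))
            den = sum(xi * xi for xi in x) + sum(yi * yi for yi in y) - abs(dot)
            out[i, j] = 0.0 if den <= 0 else dot / np.sqrt(den)
    return out


class TestNormalize:
    def test_two_by_two_checkerboard(self):
        got = normalize_network(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(got, [[-1.0, 1.0], [1.0, -1.0]], atol=1e-12)

    def test_affine_invariance(self, rng):
        A = rng.normal(size=(5, 7))
        base = normalize_network(A)
        np.testing.assert_allclose(normalize_network(3.5 * A + 2.0), base, atol=1e-10)

    def test_degenerate_row_uses_overall_zscore(self):
        A = np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 4.0], [5.0, 1.0, 3.0]])
        out = normalize_network(A)
        assert np.all(np.isfinite(out))

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_network(np.full((3, 3), 2.0))
        with pytest.raises(ValueError, match="grid"):
            normalize_network(np.array([[1.0, 2.0, 3.0]]))


class TestTanimoto:
    def test_hand_cases(self):
        e = np.array([[1.0, 0.0]])
        assert tanimoto_similarity(e, e.T)[0, 0] == pytest.approx(1.0)
        z = np.zeros((1, 2))
        assert tanimoto_similarity(e, z.T)[0, 0] == 0.0
        assert tanimoto_similarity(z, z.T)[0, 0] == 0.0
        y = np.array([[1.0, 1.0]])
        assert tanimoto_similarity(e, y.T)[0, 0] == pytest.approx(1 / np.sqrt(2))

    def test_matches_scalar_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(5, 7))
            Y = rng.normal(size=(7, 4))
            np.testing.assert_allclose(
                tanimoto_similarity(X, Y), tanimoto_oracle(X, Y), atol=1e-12
            )

    def test_role_symmetry_and_sign(self, rng):
        x = rng.normal(size=(1, 6))
        y = rng.normal(size=(6, 1))
        a = tanimoto_similarity(x, y)[0, 0]
        b = tanimoto_similarity(y.T, x.T)[0, 0]
        assert a == pytest.approx(b)
        assert np.sign(a) == np.sign(float((x @ y)[0, 0]))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_finite_for_nonzero_vectors(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(3, 4))
        Y = rng.normal(size=(4, 3))
        assert np.all(np.isfinite(tanimoto_similarity(X, Y)))


class TestMessages:
    def test_responsibility_identity_cooperativity(self):
        P = np.eye(3)
        W = np.zeros((3, 4))
        W[0, 2] = 1.0  # gene 2 targeted only by TF 0
        R = compute_responsibility(P, W)
        assert R[0, 2] == pytest.approx(1.0)

    def test_availability_identity_coregulation(self):
        C = np.eye(4)
        W = np.zeros((3, 4))
        W[1, 0] = 1.0  # TF 1 targets only gene 0
        A = compute_availability(W, C)
        assert A[1, 0] == pytest.approx(1.0)

    def test_zero_regulatory_grid_gives_zero_messages(self):
        W = np.zeros((3, 4))
        assert np.all(compute_responsibility(np.eye(3), W) == 0)
        assert np.all(compute_availability(W, np.eye(4)) == 0)

    def test_messages_match_oracle(self, rng):
        P = rng.normal(size=(4, 4))
        W = rng.normal(size=(4, 6))
        C = rng.normal(size=(6, 6))
        np.testing.assert_allclose(
            compute_responsibility(P, W), tanimoto_oracle(P, W), atol=1e-12
        )
        np.testing.assert_allclose(
            compute_availability(W, C), tanimoto_oracle(W, C), atol=1e-12
        )


class TestUpdates:
    def test_regulatory_update_rules(self, rng):
        W = rng.normal(size=(3, 4))
        R = rng.normal(size=(3, 4))
        A = rng.normal(size=(3, 4))
        np.testing.assert_allclose(update_regulatory(W, R, A, 0.0), W)
        fix = update_regulatory(W, W, W, 0.7)  # (R+A)/2 == W is a fixed point
        np.testing.assert_allclose(fix, W)
        out = update_regulatory(np.zeros((2, 2)), np.ones((2, 2)), np.ones((2, 2)), 0.05)
        np.testing.assert_allclose(out, 0.05)

    def test_identical_tf_rows_give_norm_offdiagonal(self):
        w = np.array([1.0, -2.0, 0.5, 3.0])
        W = np.vstack([w, w])
        P = np.zeros((2, 2))
        P_new = update_cooperativity(P, W, alpha=1.0, t=0)
        assert P_new[0, 1] == pytest.approx(np.linalg.norm(w))

    def test_alpha_zero_keeps_p_and_c(self, rng):
        W = rng.normal(size=(3, 5))
        P = rng.normal(size=(3, 3))
        P = (P + P.T) / 2
        C = rng.normal(size=(5, 5))
        C = (C + C.T) / 2
        np.testing.assert_allclose(update_cooperativity(P, W, 0.0, 3), P)
        np.testing.assert_allclose(update_coregulation(C, W, 0.0, 3), C)

    def test_diagonal_growth_is_monotone_in_t(self, rng):
        W = rng.normal(size=(4, 6))
        P = np.eye(4)
        d_prev = None
        for t in range(5):
            cand = update_cooperativity(np.zeros((4, 4)), W, alpha=1.0, t=t)
            d = np.diag(cand).copy()
            if d_prev is not None:
                assert np.all(d > d_prev)
            d_prev = d

    def test_symmetry_preserved(self, rng):
        W = rng.normal(size=(4, 6))
        C = rng.normal(size=(6, 6))
        C = (C + C.T) / 2
        out = update_coregulation(C, W, 0.05, 2)
        assert np.max(np.abs(out - out.T)) <= 1e-12


class TestHamming:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (np.ones((3, 3)), np.ones((3, 3)), 0.0),
            (np.zeros((2, 2)), np.full((2, 2), 0.1), 0.1),
            (np.zeros((2, 2)), np.array([[1.0, 0], [0, 0]]), 0.25),
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming_distance(a, b) == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            hamming_distance(np.zeros((2, 2)), np.zeros((2, 3)))


class TestRunPanda:
    def test_alpha_zero_is_identity_on_normalized_seeds(self, tiny_seeds):
        norm = normalize_seeds(tiny_seeds)
        state, _ = run_panda(tiny_seeds, PandaConfig(alpha=0.0, max_iter=50))
        np.testing.assert_allclose(state.W, norm.regulatory.weights)

    def test_converges_on_simulated_triple(self, sim_seeds):
        _, seeds = sim_seeds
        state, trace = run_panda(seeds, PandaConfig())
        assert state.converged
        assert state.t < 500
        assert trace[-1] < 1e-5

    def test_trace_shows_learning_then_decay(self, sim_seeds):
        _, seeds = sim_seeds
        _, trace = run_panda(seeds, PandaConfig())
        late = trace[199] if len(trace) >= 200 else trace[-1]
        assert late < trace[9]

    def test_symmetry_through_full_run(self, sim_seeds):
        _, seeds = sim_seeds
        state, _ = run_panda(seeds, PandaConfig())
        assert np.max(np.abs(state.P - state.P.T)) <= 1e-10
        assert np.max(np.abs(state.C - state.C.T)) <= 1e-10

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PandaConfig(alpha=1.5)
        with pytest.raises(ValueError):
            PandaConfig(tol=0.0)
        with pytest.raises(ValueError):
            PandaConfig(max_iter=0)
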