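"""Velocity estimation, transition kernels, absorption probabilities, latent time."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from npbfates import KineticParams, simulate_kinetics
from npbfates.containers import CountMatrix
from npbfates.fate import (
    absorption_probabilities,
    combine_kernels,
    compute_moments,
    connectivity_kernel,
    estimate_velocity,
    knn_indices,
    latent_time,
    simulate_absorption,
    terminal_sets_from_labels,
    velocity_kernel,
)


def _cm_with_layers(s, u):
    s = np.asarray(s)
    return CountMatrix(
        counts=sp.csr_matrix(s.astype(np.int64)),
        gene_ids=[f"G{i}" for i in range(s.shape[0])],
        cell_barcodes=[f"C{j}" for j in range(s.shape[1])],
        layers={"spliced": sp.csr_matrix(np.asarray(s, dtype=np.int64)),
                "unspliced": sp.csr_matrix(np.asarray(u, dtype=np.int64))},
    )


class TestComputeMoments:
    def test_k_covering_all_cells_gives_global_mean(self):
        rng = np.random.default_rng(0)
        s = rng.poisson(8, size=(5, 12))
        u = rng.poisson(3, size=(5, 12))
        cm = _cm_with_layers(s, u)
        u_sm, s_sm, _, _ = compute_moments(cm, n_pcs=3, k=11)
        np.testing.assert_allclose(s_sm, np.tile(s.mean(axis=1, keepdims=True), 12))
        np.testing.assert_allclose(u_sm, np.tile(u.mean(axis=1, keepdims=True), 12))

    def test_planted_clusters_give_group_means(self):
        rng = np.random.default_rng(1)
        a = rng.poisson([[40], [5], [5]], size=(3, 15))
        b = rng.poisson([[5], [40], [5]], size=(3, 15))
        s = np.hstack([a, b])
        u = s // 2
        cm = _cm_with_layers(s, u)
        u_sm, s_sm, _, _ = compute_moments(cm, n_pcs=2, k=14)
        for j in range(15):
            np.testing.assert_allclose(s_sm[:, j], a.mean(axis=1), atol=1e-6)
            np.testing.assert_allclose(s_sm[:, 15 + j], b.mean(axis=1), atol=1e-6)

    def test_k_too_large_rejected(self):
        cm = _cm_with_layers(np.ones((3, 5)), np.ones((3, 5)))
        with pytest.raises(ValueError, match="more than"):
            compute_moments(cm, n_pcs=2, k=5)


class TestEstimateVelocity:
    def test_exact_steady_state_gives_zero_velocity(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(1, 10, size=(4, 50))
        u = 0.5 * s
        vel, gamma_hat, valid = estimate_velocity(u, s)
        np.testing.assert_allclose(gamma_hat, 0.5, atol=1e-12)
        np.testing.assert_allclose(vel, 0.0, atol=1e-12)

    def test_scale_equivariance_of_gamma(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(1, 10, size=(3, 60))
        u = 0.3 * s + 0.05 * rng.normal(size=s.shape)
        _, g1, _ = estimate_velocity(u, s)
        _, g2, _ = estimate_velocity(7.0 * u, 7.0 * s)
        np.testing.assert_allclose(g1, g2, rtol=1e-10)

    def test_induction_phase_velocity_positive(self):
        # cells early on the kinetic curve have u above the steady-state line
        ts = np.linspace(0.05, 4.0, 80)
        u, s = simulate_kinetics(KineticParams(alpha=5.0, beta=2.0, gamma_rate=1.0, t=ts))
        vel, _, _ = estimate_velocity(u[None, :], s[None, :], quantile=0.1)
        early = ts < 0.5
        assert (vel[0, early] > 0).all()

    def test_all_zero_spliced_excluded_with_warning(self):
        u = np.array([[1.0, 2.0], [1.0, 1.0]])
        s = np.array([[0.0, 0.0], [2.0, 3.0]])
        with pytest.warns(UserWarning, match="excluded"):
            vel, gamma_hat, valid = estimate_velocity(u, s)
        assert not valid[0] and valid[1]
        np.testing.assert_allclose(vel[0], 0.0)


class TestVelocityKernel:
    def test_three_cell_softmax_oracle(self):
        pcs = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        vel = np.array([[1.0, 1.0], [0, 0], [0, 0]])
        knn = np.array([[0, 1, 2], [1, 0, 2], [2, 0, 1]])
        T = velocity_kernel(pcs, vel, knn, softmax_scale=4.0).toarray()
        cos = np.array([0.0, np.cos(np.pi / 4), np.cos(np.pi / 4)])
        expected = np.exp(4 * cos) / np.exp(4 * cos).sum()
        np.testing.assert_allclose(T[0, [0, 1, 2]], expected, atol=1e-12)

    def test_zero_scale_gives_uniform_rows(self):
        rng = np.random.default_rng(0)
        pcs = rng.normal(size=(10, 3))
        vel = rng.normal(size=(10, 3))
        knn = knn_indices(pcs, 4)
        T = velocity_kernel(pcs, vel, knn, softmax_scale=0.0).toarray()
        assert np.allclose(T[T > 0], 0.25)

    def test_large_scale_concentrates_on_aligned_neighbour(self):
        pcs = np.array([[0.0], [1.0], [-1.0]])
        vel = np.array([[1.0], [0.0], [0.0]])
        knn = np.array([[0, 1, 2], [1, 0, 2], [2, 0, 1]])
        T = velocity_kernel(pcs, vel, knn, softmax_scale=200.0).toarray()
        assert T[0, 1] > 0.999

    def test_zero_velocity_cell_uniform_fallback(self):
        pcs = np.array([[0.0], [1.0], [-1.0]])
        vel = np.zeros((3, 1))
        knn = np.array([[0, 1, 2], [1, 0, 2], [2, 0, 1]])
        T = velocity_kernel(pcs, vel, knn, softmax_scale=4.0).toarray()
        np.testing.assert_allclose(T[0, [0, 1, 2]], 1 / 3)

    def test_entropy_decreases_with_scale(self):
        rng = np.random.default_rng(3)
        pcs = rng.normal(size=(30, 4))
        vel = rng.normal(size=(30, 4))
        knn = knn_indices(pcs, 6)

        def mean_entropy(scale):
            T = velocity_kernel(pcs, vel, knn, softmax_scale=scale).toarray()
            P = np.where(T > 0, T, 1.0)
            return -(T * np.log(P)).sum(axis=1).mean()

        ents = [mean_entropy(s) for s in (0.0, 1.0, 4.0, 10.0)]
        assert all(a >= b - 1e-12 for a, b in zip(ents, ents[1:]))


class TestConnectivityAndCombine:
    def test_ring_graph_half_half(self):
        n = 6
        A = sp.lil_matrix((n, n))
        for i in range(n):
            A[i, (i + 1) % n] = 1.0
            A[i, (i - 1) % n] = 1.0
        T = connectivity_kernel(A.tocsr()).toarray()
        assert np.allclose(T[T > 0], 0.5)

    def test_isolated_cell_self_loop(self):
        A = sp.lil_matrix((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.warns(UserWarning, match="isolated"):
            T = connectivity_kernel(A.tocsr()).toarray()
        assert T[2, 2] == 1.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        idx = knn_indices(rng.normal(size=(40, 3)), 5)
        T = connectivity_kernel(idx)
        np.testing.assert_allclose(np.asarray(T.sum(axis=1)).ravel(), 1.0, atol=1e-10)

    def test_combine_weights(self):
        rng = np.random.default_rng(1)
        idx = knn_indices(rng.normal(size=(20, 3)), 4)
        Tc = connectivity_kernel(idx)
        Tv = velocity_kernel(rng.normal(size=(20, 3)), rng.normal(size=(20, 3)), idx)
        assert (combine_kernels(Tv, Tc, 1.0, 0.0) != Tv).nnz == 0
        both = combine_kernels(Tv, Tc, 0.8, 0.2).toarray()
        lo = np.minimum(Tv.toarray(), Tc.toarray())
        hi = np.maximum(Tv.toarray(), Tc.toarray())
        assert ((both >= lo - 1e-12) & (both <= hi + 1e-12)).all()
        with pytest.raises(ValueError, match="sum to 1"):
            combine_kernels(Tv, Tc, 0.8, 0.3)
        np.testing.assert_allclose(np.asarray(both.sum(axis=1)).ravel(), 1.0, atol=1e-10)


class TestAbsorptionProbabilities:
    def test_terminal_cells_get_indicator_rows(self):
        T = sp.csr_matrix(np.full((4, 4), 0.25))
        F = absorption_probabilities(T, {"a": [0], "b": [1]})
        assert F.iloc[0].tolist() == [1.0, 0.0]
        assert F.iloc[1].tolist() == [0.0, 1.0]

    def test_single_terminal_fate_all_ones(self):
        T = sp.csr_matrix(np.full((5, 5), 0.2))
        F = absorption_probabilities(T, {"only": [4]})
        np.testing.assert_allclose(F["only"], 1.0, atol=1e-10)

    def test_four_state_chain_exact_and_monte_carlo(self):
        # A -> B -> {C (0.3), D (0.7)}
        T = np.array([
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.3, 0.7],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ])
        tsets = {"C": [2], "D": [3]}
        F = absorption_probabilities(sp.csr_matrix(T), tsets)
        np.testing.assert_allclose(F.iloc[0], [0.3, 0.7], atol=1e-12)
        rng = np.random.default_rng(0)
        mc = simulate_absorption(T, tsets, start=0, n_walks=100_000, rng=rng)
        assert abs(mc[0] - 0.3) < 0.01 and abs(mc[1] - 0.7) < 0.01

    def test_unreachable_cells_raise_with_names(self):
        T = np.array([
            [0.5, 0.5, 0.0],
            [0.5, 0.5, 0.0],
            [0.0, 0.0, 1.0],
        ])
        with pytest.raises(ValueError, match="no path"):
            absorption_probabilities(sp.csr_matrix(T), {"f": [2]})

    def test_rows_sum_to_one_on_random_chain(self):
        rng = np.random.default_rng(5)
        T = rng.dirichlet(np.ones(20), size=20)
        F = absorption_probabilities(sp.csr_matrix(T), {"a": [0, 1], "b": [2]})
        np.testing.assert_allclose(F.sum(axis=1), 1.0, atol=1e-8)


class TestLatentTime:
    def _chain(self, n=20):
        A = sp.lil_matrix((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1.0
        return A.tocsr()

    def test_chain_graph_monotone_from_root(self):
        n = 20
        table = pd.DataFrame({"stage": ["HH4"] + ["ss8"] * (n - 1)},
                             index=[f"C{j}" for j in range(n)])
        lt = latent_time(self._chain(n), table, stage_order=["HH4", "ss8"])
        assert lt.iloc[0] == 0.0
        assert lt.max() == 1.0
        assert (np.diff(lt.to_numpy()) > 0).all()

    def test_disconnected_graph_raises(self):
        A = sp.lil_matrix((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        table = pd.DataFrame({"stage": ["HH4"] * 4}, index=list("abcd"))
        with pytest.raises(ValueError, match="disconnected"):
            latent_time(A.tocsr(), table, stage_order=["HH4"])


class TestTwoFateKineticFlow:
    def test_cells_near_a_fate_absorb_into_it(self):
        """Two kinetic branches diverging from a common origin: cells close to
        a terminal set receive >= 0.9 absorption probability for that fate."""
        n_per = 30
        ts = np.linspace(0.1, 3.0, n_per)
        # gene 0 rises along branch A, gene 1 along branch B; gene 2 constant
        uA, sA = simulate_kinetics(KineticParams(6.0, 2.0, 1.0, ts))
        base_u, base_s = 0.5, 1.0
        s = np.zeros((3, 2 * n_per))
        u = np.zeros((3, 2 * n_per))
        s[0, :n_per], u[0, :n_per] = sA, uA
        s[1, n_per:], u[1, n_per:] = sA, uA
        s[2], u[2] = base_s, base_u
        s[0, n_per:], u[0, n_per:] = 0.05, 0.02
        s[1, :n_per], u[1, :n_per] = 0.05, 0.02
        pcs = s.T.copy()
        vel, _, _ = estimate_velocity(u, s, quantile=0.1)
        knn = knn_indices(pcs, 6)
        Tv = velocity_kernel(pcs, vel.T @ np.eye(3), knn, softmax_scale=4.0)
        Tc = connectivity_kernel(knn)
        T = combine_kernels(Tv, Tc, 0.8, 0.2)
        tsets = {"A": list(range(n_per - 3, n_per)),
                 "B": list(range(2 * n_per - 3, 2 * n_per))}
        F = absorption_probabilities(T, tsets)
        near_a = list(range(n_per - 8, n_per - 3))
        near_b = list(range(2 * n_per - 8, 2 * n_per - 3))
        assert (F.iloc[near_a]["A"] >= 0.9).all()
        assert (F.iloc[near_b]["B"] >= 0.9).all()


class TestTerminalSelectors:
    def test_state_at_stage_selector(self):
        states = np.array(["N", "NC", "NC", "PPR"])
        stages = np.array(["ss4", "ss4", "ss8", "ss8"])
        out = terminal_sets_from_labels(states, stages, {"nc": ["NC@ss8"]})
        assert out["nc"].tolist() == [2]

    def test_empty_selector_raises(self):
        with pytest.raises(ValueError, match="no cells"):
            terminal_sets_from_labels(np.array(["N"]), np.array(["ss8"]),
                                      {"nc": ["NC@ss8"]})
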