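"""Graphical lasso, EBIC selection, and the two network configurations."""

import numpy as np
import pandas as pd
import pytest

from emanet import (
    DetrendConfig,
    EmaDataset,
    NetworkConfig,
    SymptomSchema,
    approach1_embedded_network,
    approach2_residual_network,
    build_basis,
    correlation_matrix,
    detrend_person,
    ebic,
    estimate_network,
    glasso_solve,
    standardize_basis,
)
from emanet.network import GlassoSolution, precision_to_partial
from emanet.synthetic_data import chain_precision


def random_correlation(p, n, rng):
    return np.corrcoef(rng.standard_normal((n, p)), rowvar=False)


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_correlation(self, rng):
        x = rng.standard_normal(50)
        S = correlation_matrix(np.column_stack([x, x, rng.standard_normal(50)]))
        assert S[0, 1] == pytest.approx(1.0)

    def test_two_by_two_matches_definition(self, rng):
        Y = rng.standard_normal((40, 2))
        S = correlation_matrix(Y)
        r = np.corrcoef(Y[:, 0], Y[:, 1])[0, 1]
        assert S[0, 1] == pytest.approx(r)
        np.testing.assert_allclose(np.diag(S), 1.0)

    def test_independent_noise_has_small_offdiagonals(self, rng):
        S = correlation_matrix(rng.standard_normal((1000, 6)))
        off = S[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_constant_column_rejected_and_n_lt_p_warns(self, rng):
        Y = rng.standard_normal((30, 3))
        Y[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(Y)
        with pytest.warns(UserWarning, match="singular"):
            correlation_matrix(rng.standard_normal((4, 6)))

    def test_spearman_option(self, rng):
        Y = rng.standard_normal((60, 3))
        S = correlation_matrix(Y, method="spearman")
        from scipy import stats

        expected = stats.spearmanr(Y[:, 0], Y[:, 1]).statistic
        assert S[0, 1] == pytest.approx(expected)


class TestGlasso:
    def test_unpenalized_solution_inverts_correlation(self, rng):
        S = random_correlation(3, 200, rng)
        sol = glasso_solve(S, 0.0)
        np.testing.assert_allclose(sol.precision, np.linalg.inv(S), atol=1e-5)

    def test_full_shrinkage_gives_diagonal_precision(self, rng):
        S = random_correlation(4, 100, rng)
        lam = np.max(np.abs(S - np.eye(4))) * 1.001
        sol = glasso_solve(S, lam)
        off = sol.precision[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_identity_input_is_fixed_point(self):
        for lam in (0.0, 0.1, 0.9):
            sol = glasso_solve(np.eye(5), lam)
            np.testing.assert_allclose(sol.precision, np.eye(5), atol=1e-8)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso_solve(np.eye(3), -0.1)

    def test_non_psd_input_repaired_with_warning(self):
        S = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(S).min() < 0
        with pytest.warns(UserWarning, match="PSD"):
            sol = glasso_solve(S, 0.1)
        assert np.linalg.eigvalsh(sol.precision).min() > 0


class TestEbic:
    def test_hand_computed_two_node_case(self):
        # p=2, n=100, one edge; likelihood terms worked out longhand
        T = np.array([[1.25, -0.5], [-0.5, 1.25]])
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        sign, logdet = np.linalg.slogdet(T)
        ll = 50.0 * (logdet - np.trace(S @ T))
        expected = -2.0 * ll + 1 * np.log(100) + 4 * 0.5 * 1 * np.log(2)
        sol = GlassoSolution(T, 0.1, 0.0, True, 5)
        assert ebic(sol, S, 100, gamma=0.5) == pytest.approx(expected)

    def test_gamma_zero_reduces_to_bic(self):
        T = np.array([[1.25, -0.5], [-0.5, 1.25]])
        S = np.eye(2)
        sol = GlassoSolution(T, 0.1, 0.0, True, 5)
        sign, logdet = np.linalg.slogdet(T)
        ll = 50.0 * (logdet - np.trace(S @ T))
        assert ebic(sol, S, 100, gamma=0.0) == pytest.approx(-2 * ll + np.log(100))

    def test_sparser_solution_preferred_at_equal_likelihood(self):
        # same precision values, artificially different sparsity patterns
        T_sparse = np.eye(5)
        T_dense = np.eye(5) + 1e-3 * (np.ones((5, 5)) - np.eye(5))
        S = np.eye(5)
        e_sparse = ebic(GlassoSolution(T_sparse, 0.1, 0, True, 1), S, 100, 0.5)
        e_dense = ebic(GlassoSolution(T_dense, 0.1, 0, True, 1), S, 100, 0.5)
        assert e_sparse < e_dense


class TestEstimateNetwork:
    def test_partial_correlation_transform_and_symmetry(self, rng):
        T = chain_precision(6, 0.3)
        L = np.linalg.cholesky(np.linalg.inv(T))
        Y = rng.standard_normal((150, 6)) @ L.T
        net = estimate_network(Y, [f"S{i}" for i in range(6)])
        W2 = precision_to_partial(net.precision)
        np.testing.assert_array_equal(net.W, W2)
        np.testing.assert_array_equal(net.W, net.W.T)
        np.testing.assert_array_equal(np.diag(net.W), 0.0)
        assert np.abs(net.W).max() <= 1.0

    def test_edge_count_monotone_along_penalty_path(self, rng):
        S = random_correlation(6, 80, rng)
        lam_max = np.max(np.abs(S - np.eye(6)))
        counts = []
        for lam in np.geomspace(lam_max, 0.01 * lam_max, 25):
            T = glasso_solve(S, float(lam)).precision
            iu = np.triu_indices(6, k=1)
            counts.append(int((np.abs(T[iu]) > 1e-10).sum()))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_chain_structure_recovered(self, rng):
        # partial correlation 0.4: strong enough that the per-edge
        # likelihood gain clearly exceeds the EBIC edge cost at n=100
        T = chain_precision(8, 0.4)
        L = np.linalg.cholesky(np.linalg.inv(T))
        hits, spec = [], []
        for _ in range(10):
            Y = rng.standard_normal((100, 8)) @ L.T
            net = estimate_network(Y, [f"S{i}" for i in range(8)],
                                   config=NetworkConfig(n_lambda=50))
            found = {(i, j) for i in range(8) for j in range(i + 1, 8) if net.W[i, j] != 0}
            true = {(i, i + 1) for i in range(7)}
            hits.append(len(found & true) / len(true))
            spec.append(1 - len(found - true) / 21)
        assert np.mean(hits) > 0.8
        assert np.mean(spec) > 0.7

    def test_independent_noise_usually_empty(self, rng):
        empty = 0
        for _ in range(10):
            Y = rng.standard_normal((100, 10))
            net = estimate_network(Y, [f"S{i}" for i in range(10)],
                                   config=NetworkConfig(n_lambda=50))
            empty += net.is_empty
        assert empty >= 7

    def test_single_node_degenerate(self, rng):
        net = estimate_network(rng.standard_normal((50, 1)), ["A"])
        assert net.uninterpretable and net.is_empty


class TestApproaches:
    def two_symptom_dataset(self, schedule100, rng):
        schema = SymptomSchema.from_items(["Headache", "Fatigue"])
        Y = np.clip(np.round(2 + rng.standard_normal((100, 2))), 0, 6)
        return EmaDataset("p", Y, schedule100, schema)

    def test_embedded_network_has_symptoms_plus_temporal_nodes(self, schedule100, rng):
        ds = self.two_symptom_dataset(schedule100, rng)
        basis = standardize_basis(build_basis(ds.timestamps))
        net = approach1_embedded_network(ds, basis, NetworkConfig(n_lambda=40))
        assert len(net.nodes) == 9  # 2 symptom + 7 temporal
        assert net.kinds.count("symptom") == 2
        assert net.kinds.count("temporal") == 7

    def test_residual_network_with_single_symptom_flagged(self):
        from emanet.detrend import DetrendResult

        res = DetrendResult("Headache", (), {"intercept": 0.0}, 0.0,
                            np.zeros(20), 0.1, 20)
        net = approach2_residual_network([res])
        assert net.uninterpretable
        assert net.is_empty

    def test_residual_networks_require_aligned_rows(self):
        from emanet.detrend import DetrendResult

        a = DetrendResult("A", (), {}, 0.0, np.zeros(20), 0.1, 20)
        b = DetrendResult("B", (), {}, 0.0, np.zeros(25), 0.1, 25)
        with pytest.raises(ValueError, match="identical rows"):
            approach2_residual_network([a, b])
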