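"""Principal network projection: combined-matrix placement, SVD energy
fractions, rank selection, Parseval-type score identities and core cuts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gwgen.datatypes import NodeModel, RealGWGEN
from gwgen.pnp import (
    CombinedMatrix,
    build_combined_matrix,
    decompose,
    eigenexpression_fractions,
    extract_core,
    principal_network_projection,
    projection_scores,
    select_rank,
)
from gwgen.synthetic import generate_candidate_gwgen, simulate_expression
from gwgen.netio import apply_degree_cap
from gwgen.identification import identify_gwgen


def _combined(df: pd.DataFrame) -> CombinedMatrix:
    kinds = pd.Series("protein", index=sorted(set(df.index) | set(df.columns)))
    return CombinedMatrix(matrix=df, kinds=kinds)


def _tiny_real() -> RealGWGEN:
    kinds = pd.Series({"TF000": "tf", "GEN0000": "gene", "GEN0001": "gene",
                       "MIR000": "mirna"})
    models = {
        "GEN0000": NodeModel("GEN0000", "gene", {"TF000": 0.7, "MIR000": -0.3},
                             basal=1.0, rss=0.0, n_samples=10, aic=-10.0),
        "GEN0001": NodeModel("GEN0001", "gene", {"TF000": -0.4},
                             basal=2.0, rss=0.0, n_samples=10, aic=-10.0),
        "TF000": NodeModel("TF000", "tf", {}, basal=1.0, rss=0.0,
                           n_samples=10, aic=-10.0),
        "MIR000": NodeModel("MIR000", "mirna", {}, basal=1.0, rss=0.0,
                            n_samples=10, aic=-10.0),
    }
    return RealGWGEN(kinds=kinds, models=models)


class TestCombinedMatrix:
    def test_single_edge_placement(self):
        W = build_combined_matrix(_tiny_real())
        assert W.matrix.loc["GEN0000", "TF000"] == 0.7
        assert W.matrix.loc["GEN0000", "MIR000"] == -0.3
        assert W.matrix.loc["GEN0001", "TF000"] == -0.4

    def test_nonzero_multiset_equals_ability_multiset(self, small_identified):
        W = build_combined_matrix(small_identified)
        nonzero = sorted(W.matrix.to_numpy()[W.matrix.to_numpy() != 0.0])
        abilities = sorted(c for m in small_identified.models.values()
                           for c in m.regulators.values())
        np.testing.assert_allclose(nonzero, abilities)

    def test_empty_network_rejected(self):
        real = _tiny_real()
        for m in real.models.values():
            m.regulators.clear()
        with pytest.raises(ValueError):
            build_combined_matrix(real)


class TestDecomposition:
    def test_diagonal_singular_values(self):
        W = _combined(pd.DataFrame(np.diag([3.0, 1.0]),
                                   index=["a", "b"], columns=["c", "d"]))
        _, d, _ = decompose(W)
        np.testing.assert_allclose(d, [3.0, 1.0])

    def test_reconstruction_error(self, rng):
        A = rng.normal(size=(20, 15))
        W = _combined(pd.DataFrame(A, index=[f"r{i}" for i in range(20)],
                                   columns=[f"c{i}" for i in range(15)]))
        T, d, H = decompose(W)
        err = np.linalg.norm(A - T @ np.diag(d) @ H.T) / np.linalg.norm(A)
        assert err <= 1e-10

    def test_rank_one_energy(self, rng):
        u, v = rng.normal(size=8), rng.normal(size=5)
        W = _combined(pd.DataFrame(np.outer(u, v),
                                   index=[f"r{i}" for i in range(8)],
                                   columns=[f"c{i}" for i in range(5)]))
        _, d, _ = decompose(W)
        E = eigenexpression_fractions(d)
        assert E[0] == pytest.approx(1.0, abs=1e-12)


class TestEnergyFractions:
    @pytest.mark.parametrize("d,expected", [
        ([2.0, 0.0, 0.0], [1.0, 0.0, 0.0]),
        ([3.0, 1.0], [0.9, 0.1]),
    ])
    def test_examples(self, d, expected):
        np.testing.assert_allclose(eigenexpression_fractions(np.array(d)), expected)

    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=20)
           .filter(lambda d: sum(x * x for x in d) > 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_loop_oracle_and_sums_to_one(self, d):
        d = np.asarray(d)
        E = eigenexpression_fractions(d)
        total = sum(x * x for x in d)
        for s, val in enumerate(E):
            assert val == pytest.approx(d[s] ** 2 / total, abs=1e-14)
        assert E.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            eigenexpression_fractions(np.zeros(3))


class TestRankSelection:
    @pytest.mark.parametrize("E,threshold,expected", [
        ([0.9, 0.1], 0.85, 1),
        ([0.25, 0.25, 0.25, 0.25], 0.85, 4),
        ([0.5, 0.3, 0.2], 1.0, 3),
    ])
    def test_examples(self, E, threshold, expected):
        assert select_rank(np.array(E), threshold) == expected

    def test_threshold_one_counts_nonzero_singular_values(self):
        d = np.array([3.0, 2.0, 1.0, 0.0])
        E = eigenexpression_fractions(d)
        assert select_rank(E, 1.0) == 3

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=12),
           st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_minimality(self, d, threshold):
        E = eigenexpression_fractions(np.sort(np.array(d))[::-1])
        S = select_rank(E, threshold)
        assert np.cumsum(E)[S - 1] >= threshold - 1e-9
        if S > 1:
            assert np.cumsum(E)[S - 2] < threshold


class TestProjectionScores:
    def _random_W(self, rng, m=12, n=9):
        return _combined(pd.DataFrame(rng.normal(size=(m, n)),
                                      index=[f"r{i}" for i in range(m)],
                                      columns=[f"c{i}" for i in range(n)]))

    def test_full_rank_scores_are_column_norms(self, rng):
        W = self._random_W(rng)
        T, d, H = decompose(W)
        down, up = projection_scores(W, T, H, S=len(d))
        np.testing.assert_allclose(down, np.linalg.norm(W.to_numpy(), axis=0),
                                   atol=1e-8)
        np.testing.assert_allclose(up, np.linalg.norm(W.to_numpy(), axis=1),
                                   atol=1e-8)
        assert (down >= 0).all() and (up >= 0).all()
        # Parseval: total squared score equals the Frobenius energy
        assert np.sum(down ** 2) == pytest.approx(
            np.linalg.norm(W.to_numpy()) ** 2, rel=1e-8)

    def test_zero_column_scores_zero(self, rng):
        A = rng.normal(size=(6, 4))
        A[:, 2] = 0.0
        W = _combined(pd.DataFrame(A, index=[f"r{i}" for i in range(6)],
                                   columns=[f"c{i}" for i in range(4)]))
        T, d, H = decompose(W)
        down, _ = projection_scores(W, T, H, S=len(d))
        assert down.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_scores_nondecreasing_in_rank(self, rng):
        W = self._random_W(rng)
        T, d, H = decompose(W)
        prev_down, prev_up = None, None
        for S in range(1, len(d) + 1):
            down, up = projection_scores(W, T, H, S)
            if prev_down is not None:
                assert (down.to_numpy() >= prev_down.to_numpy() - 1e-10).all()
                assert (up.to_numpy() >= prev_up.to_numpy() - 1e-10).all()
            prev_down, prev_up = down, up

    def test_permutation_equivariance(self, rng):
        W = self._random_W(rng)
        T, d, H = decompose(W)
        down, up = projection_scores(W, T, H, S=2)
        perm_rows = rng.permutation(W.matrix.index)
        perm_cols = rng.permutation(W.matrix.columns)
        Wp = CombinedMatrix(matrix=W.matrix.loc[perm_rows, perm_cols],
                            kinds=W.kinds)
        Tp, dp, Hp = decompose(Wp)
        downp, upp = projection_scores(Wp, Tp, Hp, S=2)
        np.testing.assert_allclose(downp[down.index], down, atol=1e-8)
        np.testing.assert_allclose(upp[up.index], up, atol=1e-8)


class TestCoreExtraction:
    def test_top_k_larger_than_network_keeps_everything(self, small_identified):
        result = principal_network_projection(small_identified)
        core = extract_core(small_identified, result, top_k=10_000)
        assert core.node_set == (set(result.downstream.index)
                                 | set(result.upstream.index))

    def test_top_k_matches_sort_oracle(self, small_identified):
        result = principal_network_projection(small_identified)
        core = extract_core(small_identified, result, top_k=3)
        score = {}
        for n in set(result.downstream.index) | set(result.upstream.index):
            vals = [result.downstream.get(n, -np.inf), result.upstream.get(n, -np.inf)]
            score[n] = max(vals)
        expected = sorted(score, key=lambda n: (-score[n], n))[:3]
        assert list(core.nodes.index) == expected

    def test_core_edges_are_induced(self, small_identified):
        result = principal_network_projection(small_identified)
        core = extract_core(small_identified, result, top_k=12)
        keep = core.node_set
        for row in core.edges.itertuples(index=False):
            assert row.source_id in keep and row.target_id in keep
        assert core.edge_triples() <= small_identified.edge_set()

    def test_high_ability_hubs_land_in_core(self):
        """Nodes in the top decile of both degree and |ability| in the
        planted truth should almost all survive a 25% core cut."""
        candidate, truth = generate_candidate_gwgen(
            n_proteins=30, n_genes=60, n_mirnas=12, n_lncrnas=4,
            true_density=0.15, seed=91)
        data = simulate_expression(truth, n_samples=80, seed=92)
        real = identify_gwgen(apply_degree_cap(candidate, data), data)
        result = principal_network_projection(real)
        n_nodes = len(set(result.downstream.index) | set(result.upstream.index))
        core = extract_core(real, result, top_k=max(1, n_nodes // 4))

        degree: dict[str, int] = {}
        strength: dict[str, float] = {}
        for tgt, regs in truth.coefficients.items():
            for src, coef in regs.items():
                for n in (tgt, src):
                    degree[n] = degree.get(n, 0) + 1
                    strength[n] = max(strength.get(n, 0.0), abs(coef))
        deg_cut = np.quantile(sorted(degree.values()), 0.9)
        str_cut = np.quantile(sorted(strength.values()), 0.9)
        hubs = [n for n in degree
                if degree[n] >= deg_cut and strength[n] >= str_cut]
        assert hubs
        hit = sum(h in core.node_set for h in hubs) / len(hubs)
        assert hit >= 0.9
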