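"""Constrained least squares and AIC order detection: regression builders
against loop oracles, solvers against normal-equations/QP references, and
recovery of planted regulator sets."""

import numpy as np
import pandas as pd
import pytest

from gwgen.datatypes import CandidateGWGEN, ExpressionDataset
from gwgen.evaluation import (
    edge_recovery,
    nested_vs_exhaustive_agreement,
    null_order_rate,
    parameter_errors,
)
from gwgen.identification import (
    RegressionProblem,
    build_protein_regression,
    build_target_regression,
    compute_aic,
    identify_gwgen,
    select_order,
    solve_least_squares,
)
from gwgen.netio import apply_degree_cap
from gwgen.synthetic import generate_candidate_gwgen, simulate_expression

from .oracles import normal_equations_solve, qp_bound_oracle


def _toy_data(values: dict[str, list[float]], kinds: dict[str, str]):
    n = len(next(iter(values.values())))
    df = pd.DataFrame(values, index=[f"S{i}" for i in range(n)]).T
    return ExpressionDataset(values=df, kinds=pd.Series(kinds))


class TestBuilders:
    def test_protein_regressor_is_elementwise_product(self):
        data = _toy_data({"PA": [2.0, 3.0], "PB": [1.0, 4.0]},
                         {"PA": "protein", "PB": "protein"})
        net = CandidateGWGEN(kinds=data.kinds, ppi={("PA", "PB")})
        prob = build_protein_regression("PA", net, data)
        np.testing.assert_allclose(prob.matrix, [[2.0, 1.0], [12.0, 1.0]])
        assert prob.labels == ["PB"]
        assert not prob.constrained.any()

    def test_zero_partner_fit_returns_mean_basal(self):
        data = _toy_data({"PA": [2.0, 4.0, 6.0]}, {"PA": "protein"})
        net = CandidateGWGEN(kinds=data.kinds)
        prob = build_protein_regression("PA", net, data)
        omega, rss = solve_least_squares(prob)
        assert omega[-1] == pytest.approx(4.0)

    def test_target_row_layout_tf_then_mirna_product(self):
        data = _toy_data({"TF0": [1.0, 2.0], "MIR0": [3.0, 1.0], "G1": [5.0, 4.0]},
                         {"TF0": "tf", "MIR0": "mirna", "G1": "gene"})
        net = CandidateGWGEN(kinds=data.kinds, grn={("TF0", "G1"), ("MIR0", "G1")})
        prob = build_target_regression("G1", net, data)
        np.testing.assert_allclose(prob.matrix, [[1.0, 15.0, 1.0], [2.0, 4.0, 1.0]])
        assert prob.labels == ["TF0", "MIR0"]
        np.testing.assert_array_equal(prob.constrained, [False, True])

    def test_label_order_is_tf_lncrna_mirna(self):
        data = _toy_data(
            {"TF0": [1, 2], "LNC0": [2, 1], "MIR0": [3, 1], "G1": [5, 4]},
            {"TF0": "tf", "LNC0": "lncrna", "MIR0": "mirna", "G1": "gene"})
        net = CandidateGWGEN(kinds=data.kinds,
                             grn={("MIR0", "G1"), ("LNC0", "G1"), ("TF0", "G1")})
        prob = build_target_regression("G1", net, data)
        assert prob.labels == ["TF0", "LNC0", "MIR0"]

    def test_matrix_matches_bruteforce_loop(self, small_instance, rng):
        candidate, truth, data = small_instance
        for node in list(candidate.kinds.index)[::7]:
            prob = (build_protein_regression(node, candidate, data)
                    if candidate.kinds[node] in ("protein", "receptor", "tf")
                    else build_target_regression(node, candidate, data))
            y = data.series(node)
            for n in range(prob.n_samples):
                for j, lab in enumerate(prob.labels):
                    x = data.series(lab)[n]
                    if (candidate.kinds[node] in ("protein", "receptor", "tf")
                            or candidate.kinds[lab] == "mirna"):
                        x *= y[n]
                    assert prob.matrix[n, j] == pytest.approx(x)
                assert prob.matrix[n, -1] == 1.0


class TestSolver:
    def _random_problem(self, rng, p=5, n=30, constrained_frac=0.5):
        A = np.column_stack([rng.lognormal(0, 0.5, size=(n, p)), np.ones(n)])
        y = rng.normal(size=n)
        mask = rng.random(p) < constrained_frac
        return RegressionProblem(node_id="x", kind="gene", response=y,
                                 matrix=A, labels=[f"R{i}" for i in range(p)],
                                 constrained=mask)

    def test_unconstrained_matches_normal_equations(self, rng):
        for _ in range(50):
            prob = self._random_problem(rng, constrained_frac=0.0)
            omega, _ = solve_least_squares(prob)
            ref = normal_equations_solve(prob.matrix, prob.response)
            np.testing.assert_allclose(omega, ref, atol=1e-8)

    def test_constrained_matches_qp_oracle(self, rng):
        for _ in range(100):
            p = int(rng.integers(1, 8))
            prob = self._random_problem(rng, p=p)
            omega, rss = solve_least_squares(prob)
            assert (omega[:-1][prob.constrained] <= 1e-12).all()
            ref = qp_bound_oracle(prob.matrix, prob.response,
                                  np.append(prob.constrained, False))
            assert rss == pytest.approx(ref, abs=1e-8)

    def test_constrained_objective_at_least_unconstrained(self, rng):
        for _ in range(20):
            prob = self._random_problem(rng)
            _, rss_c = solve_least_squares(prob)
            free = RegressionProblem(
                node_id="x", kind="gene", response=prob.response,
                matrix=prob.matrix, labels=prob.labels,
                constrained=np.zeros_like(prob.constrained))
            _, rss_u = solve_least_squares(free)
            assert rss_c >= rss_u - 1e-10

    def test_positive_effect_in_constrained_slot_returns_zero(self, rng):
        n = 40
        m = rng.lognormal(0, 0.5, size=n)
        y = 2.0 + 1.5 * m * 1.0  # positive association with the product slot
        prob = RegressionProblem(node_id="g", kind="gene", response=y * 1.0,
                                 matrix=np.column_stack([y * m, np.ones(n)]),
                                 labels=["MIR0"],
                                 constrained=np.array([True]))
        omega, _ = solve_least_squares(prob)
        assert omega[0] == 0.0


class TestAIC:
    def test_unit_variance_two_parameters(self):
        # log(1) = 0 in any base; penalty 2·2/4 = 1
        assert compute_aic(4.0, 4, 2) == pytest.approx(1.0)

    def test_penalty_monotone_in_delta(self):
        aics = [compute_aic(10.0, 50, d) for d in range(1, 6)]
        assert all(b > a for a, b in zip(aics, aics[1:]))

    def test_zero_rss_uses_floor(self):
        val = compute_aic(0.0, 10, 3)
        assert np.isfinite(val)
        assert val == pytest.approx(np.log10(1e-12) + 0.6)
        # among perfect fits the smaller parameter count wins
        assert compute_aic(0.0, 10, 2) < val


class TestOrderSelection:
    def test_recovers_planted_subset_among_decoys(self, rng):
        n = 60
        X = rng.lognormal(0, 0.5, size=(n, 5))
        y = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 3.0
        prob = RegressionProblem(node_id="g", kind="gene", response=y,
                                 matrix=np.column_stack([X, np.ones(n)]),
                                 labels=[f"R{i}" for i in range(5)],
                                 constrained=np.zeros(5, dtype=bool))
        model = select_order(prob)
        assert set(model.regulators) == {"R0", "R1"}
        assert model.regulators["R0"] == pytest.approx(0.8, abs=1e-8)
        assert model.basal == pytest.approx(3.0, abs=1e-8)

    def test_null_responses_mostly_select_order_zero(self):
        rate = null_order_rate(n_replicates=40, seed=123)
        assert rate >= 0.8  # full 100-replicate study in the acceptance suite

    def test_nested_family_agrees_with_exhaustive_search(self):
        assert nested_vs_exhaustive_agreement(n_instances=40, seed=7) >= 0.95

    def test_parameter_error_shrinks_with_noise(self):
        """Median planted-parameter error must be monotone non-increasing
        as noise sd drops 0.1 → 0.01 → 0."""
        candidate, truth = generate_candidate_gwgen(
            n_proteins=12, n_genes=20, n_mirnas=6, n_lncrnas=3, seed=31)
        errs = []
        for sd in (0.1, 0.01, 0.0):
            data = simulate_expression(truth.with_noise(sd), n_samples=80, seed=32)
            real = identify_gwgen(apply_degree_cap(candidate, data), data)
            errs.append(parameter_errors(truth, real)["mean_abs_error"])
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] <= 1e-8


class TestIdentifyGWGEN:
    def test_identified_edges_subset_of_candidate(self, small_instance,
                                                  small_identified):
        candidate, _, _ = small_instance
        assert small_identified.edge_set() <= candidate.edge_set()

    def test_noiseless_recovery_is_exact(self, small_instance, small_identified):
        _, truth, _ = small_instance
        rec = edge_recovery(truth, small_identified)
        assert rec["precision"] == 1.0 and rec["recall"] == 1.0
        assert parameter_errors(truth, small_identified)["max_abs_error"] < 1e-8

    def test_mirna_abilities_never_positive(self, small_identified):
        for m in small_identified.models.values():
            for reg, coef in m.regulators.items():
                if small_identified.kinds[reg] == "mirna":
                    assert coef <= 0

    def test_missing_node_in_data_is_reported(self, small_instance):
        candidate, _, data = small_instance
        trimmed = ExpressionDataset(values=data.values.iloc[1:],
                                    kinds=data.kinds.iloc[1:])
        with pytest.raises((RuntimeError, ValueError)):
            identify_gwgen(candidate, trimmed)
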