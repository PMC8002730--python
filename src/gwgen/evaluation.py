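"""Recovery metrics and benchmark experiments against planted truth.

These helpers quantify how well identification recovers a synthetic
ground truth: edge precision/recall/F1, planted-parameter errors, the
common/distinctive split between two conditions, and Monte-Carlo studies
of the order-selection behaviour (null rejection rate, nested-family vs
exhaustive-subset agreement).
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np

from .datatypes import GroundTruthModel, RealGWGEN
from .identification import (
    RegressionProblem,
    compute_aic,
    identify_gwgen,
    select_order,
    solve_least_squares,
)
from .netio import apply_degree_cap
from .synthetic import (
    generate_candidate_gwgen,
    signal_sd,
    simulate_expression,
)


def edge_recovery(truth: GroundTruthModel, real: RealGWGEN) -> dict[str, float]:
    """Precision/recall/F1 of the identified edge set against the truth."""
    t, r = truth.edge_set(), real.edge_set()
    tp, fp, fn = len(t & r), len(r - t), len(t - r)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}


def parameter_errors(truth: GroundTruthModel, real: RealGWGEN) -> dict[str, float]:
    """Absolute errors of every planted coefficient and basal level.

    A pruned planted regulator counts as an estimate of 0.  Only computed
    targets are compared (source nodes have no planted equation).
    """
    errs = []
    for tgt in sorted(truth.basal):
        model = real.models[tgt]
        for src, coef in sorted(truth.coefficients.get(tgt, {}).items()):
            errs.append(abs(model.regulators.get(src, 0.0) - coef))
        errs.append(abs(model.basal - truth.basal[tgt]))
    errs = np.asarray(errs)
    return {"max_abs_error": float(errs.max()),
            "mean_abs_error": float(errs.mean()),
            "n_parameters": int(errs.size)}


def condition_split(edges_a: set, edges_b: set) -> dict[str, set]:
    return {"common": edges_a & edges_b,
            "only_a": edges_a - edges_b,
            "only_b": edges_b - edges_a}


# ---------------------------------------------------------------------------
# benchmark experiments

DEFAULT_SIZES = dict(n_proteins=50, n_genes=100, n_mirnas=20, n_lncrnas=5,
                     true_density=0.1, decoy_ratio=2.0)


def exact_recovery_experiment(seed: int = 0, n_samples: int = 80,
                              **sizes) -> dict[str, float]:
    """Noise-free planted-network recovery at the default study sizes."""
    params = {**DEFAULT_SIZES, **sizes}
    candidate, truth = generate_candidate_gwgen(seed=seed, **params)
    data = simulate_expression(truth, n_samples=n_samples, seed=seed + 1)
    capped = apply_degree_cap(candidate, data)
    real = identify_gwgen(capped, data)
    out = edge_recovery(truth, real)
    out.update(parameter_errors(truth, real))
    out["n_true_edges"] = truth.n_true_edges
    out["n_candidate_edges"] = candidate.n_edges
    return out


def noisy_recovery_experiment(seeds: list[int], n_samples: int = 100,
                              noise_factor: float = 0.1,
                              **sizes) -> dict[str, float]:
    """Edge-recovery F1 with noise sd set to ``noise_factor`` times the
    noise-free signal sd, averaged over seeds."""
    params = {**DEFAULT_SIZES, **sizes}
    f1s = []
    for seed in seeds:
        candidate, truth = generate_candidate_gwgen(seed=seed, **params)
        clean = simulate_expression(truth, n_samples=n_samples, seed=seed + 1)
        sd = noise_factor * signal_sd(clean)
        noisy_truth = replace(truth, noise_sd=sd)
        data = simulate_expression(noisy_truth, n_samples=n_samples, seed=seed + 1)
        real = identify_gwgen(apply_degree_cap(candidate, data), data)
        f1s.append(edge_recovery(truth, real)["f1"])
    return {"mean_f1": float(np.mean(f1s)), "min_f1": float(np.min(f1s)),
            "n_seeds": len(seeds)}


def _null_problem(rng: np.random.Generator, n_samples: int,
                  n_candidates: int) -> RegressionProblem:
    y = rng.normal(size=n_samples)
    X = rng.lognormal(0.0, 0.5, size=(n_samples, n_candidates))
    matrix = np.column_stack([X, np.ones(n_samples)])
    return RegressionProblem(node_id="null", kind="gene", response=y,
                             matrix=matrix,
                             labels=[f"R{i}" for i in range(n_candidates)],
                             constrained=np.zeros(n_candidates, dtype=bool))


def null_order_rate(n_replicates: int = 100, seed: int = 0,
                    n_samples: int = 100, n_candidates: int = 3) -> float:
    """Fraction of pure-noise responses for which order 0 is selected."""
    hits = 0
    for i in range(n_replicates):
        rng = np.random.default_rng([seed, i])
        model = select_order(_null_problem(rng, n_samples, n_candidates))
        hits += model.order == 0
    return hits / n_replicates


def exhaustive_best_subset(problem: RegressionProblem) -> tuple[float, frozenset[str]]:
    """Reference search: AIC minimum over *all* regulator subsets."""
    best = None
    for k in range(len(problem.labels) + 1):
        for combo in itertools.combinations(problem.labels, k):
            sub = problem.subproblem(list(combo))
            _, rss = solve_least_squares(sub)
            aic = compute_aic(rss, problem.n_samples, k + 1)
            if best is None or aic < best[0] - 1e-12:
                best = (aic, frozenset(combo))
    return best


def nested_vs_exhaustive_agreement(n_instances: int = 200, seed: int = 0,
                                   n_samples: int = 40,
                                   max_candidates: int = 5) -> float:
    """Fraction of random noiseless instances on which the nested-family
    AIC minimum equals the exhaustive-subset minimum.

    Each instance plants a random subset of the candidates with abilities
    in ±[0.2, 1] and a basal level, generates exact responses, and compares
    the two searches.
    """
    agree = 0
    for i in range(n_instances):
        rng = np.random.default_rng([seed, i])
        k_cand = int(rng.integers(1, max_candidates + 1))
        k_true = int(rng.integers(0, k_cand + 1))
        X = rng.lognormal(0.0, 0.5, size=(n_samples, k_cand))
        which = rng.choice(k_cand, size=k_true, replace=False)
        beta = np.zeros(k_cand)
        beta[which] = (rng.uniform(0.2, 1.0, size=k_true)
                       * rng.choice([-1.0, 1.0], size=k_true))
        y = X @ beta + rng.uniform(2.0, 6.0)
        problem = RegressionProblem(
            node_id=f"inst{i}", kind="gene", response=y,
            matrix=np.column_stack([X, np.ones(n_samples)]),
            labels=[f"R{j}" for j in range(k_cand)],
            constrained=np.zeros(k_cand, dtype=bool))
        nested = select_order(problem)
        _, best_set = exhaustive_best_subset(problem)
        agree += frozenset(nested.regulators) == best_set
    return agree / n_instances
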