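"""Independent reference implementations used only to check the package."""

import itertools

import numpy as np


def qp_bound_oracle(A: np.ndarray, y: np.ndarray,
                    constrained: np.ndarray) -> float:
    """Optimal objective of min ‖Aω−y‖² s.t. ω[constrained] ≤ 0, found by
    enumerating every active set of the inequality constraints."""
    n, p = A.shape
    idx = list(np.where(constrained)[0])
    best = np.inf
    for r in range(len(idx) + 1):
        for active in itertools.combinations(idx, r):
            free = [j for j in range(p) if j not in active]
            sol = np.zeros(p)
            if free:
                coef, *_ = np.linalg.lstsq(A[:, free], y, rcond=None)
                sol[free] = coef
            if (sol[idx] <= 1e-10).all():
                rss = float(np.sum((A @ sol - y) ** 2))
                best = min(best, rss)
    return best


def normal_equations_solve(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct solve of AᵀA ω = Aᵀ y (full-rank problems only)."""
    return np.linalg.solve(A.T @ A, A.T @ y)


def optimal_cover(drug_targets: dict[str, set[str]],
                  targets: set[str]) -> int:
    """Smallest number of drugs whose covered-target union includes all
    coverable targets, by exhaustive subset search."""
    coverable = targets & set().union(*drug_targets.values()) if drug_targets else set()
    drugs = sorted(drug_targets)
    for r in range(len(drugs) + 1):
        for combo in itertools.combinations(drugs, r):
            if coverable <= set().union(set(), *(drug_targets[d] for d in combo)):
                return r
    return len(drugs)
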