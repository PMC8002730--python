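"""Regulator identification by (constrained) least squares + AIC pruning.

Every node owns one regression equation built from the candidate network:

  protein i :  p_i[n] = [p_i·p_j1, …, p_i·p_jk, 1] · [λ_1 … λ_k, ψ]
  target  x :  g_x[n] = [t_u…, l_k…, g_x·m_v…, 1] · [α…, β…, −γ…, ψ]

miRNA-slot coefficients represent −γ and are constrained non-positive, so
they are fitted by bounded-variable least squares.  The model order is then
detected by ranking regressors on |coefficient|·sd(regressor), refitting
the nested family k = 0…K and keeping the k that minimises

  AIC(k) = log_b( max(RSS/N, floor) ) + 2·(k+1)/N

with a configurable log base ``b`` (default 10) and a variance floor that
keeps perfect fits comparable (the parsimony penalty then decides).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .datatypes import (
    CandidateGWGEN,
    ExpressionDataset,
    NodeModel,
    PROTEIN_KINDS,
    RealGWGEN,
)

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_FLOOR = 1e-12
DEFAULT_LOG_BASE = 10.0


@dataclass
class RegressionProblem:
    """One node's equation: response, regressor matrix (ones column last),
    regulator labels and the non-positivity mask for miRNA slots."""

    node_id: str
    kind: str
    response: np.ndarray            # (N,)
    matrix: np.ndarray              # (N, k+1); last column all ones
    labels: list[str]               # length k, regulator node ids
    constrained: np.ndarray         # (k,) bool; True where coefficient <= 0

    def __post_init__(self) -> None:
        n, p = self.matrix.shape
        if len(self.response) != n:
            raise ValueError("response/matrix row mismatch")
        if p != len(self.labels) + 1:
            raise ValueError("matrix must have one column per regulator plus a ones column")
        if len(self.constrained) != len(self.labels):
            raise ValueError("constraint mask length mismatch")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subproblem(self, labels: list[str]) -> "RegressionProblem":
        """Restriction to a subset of regulators (plus the basal column)."""
        idx = [self.labels.index(l) for l in labels]
        cols = idx + [len(self.labels)]
        return RegressionProblem(
            node_id=self.node_id, kind=self.kind, response=self.response,
            matrix=self.matrix[:, cols], labels=list(labels),
            constrained=self.constrained[idx],
        )


def build_protein_regression(node_id: str, net: CandidateGWGEN,
                             data: ExpressionDataset) -> RegressionProblem:
    """Bilinear PPI equation: regressor columns are p_i·p_j for each
    candidate partner j, with an unconstrained basal column."""
    if net.kinds[node_id] not in PROTEIN_KINDS:
        raise ValueError(f"{node_id!r} is not a protein-kind node")
    partners = net.regulators_for_equation(node_id)
    missing = [p for p in partners if p not in data.values.index]
    if missing:
        raise ValueError(f"partners of {node_id!r} missing from data: {missing}")
    p_i = data.series(node_id)
    cols = [p_i * data.series(j) for j in partners]
    matrix = np.column_stack(cols + [np.ones(len(p_i))])
    return RegressionProblem(node_id=node_id, kind=net.kinds[node_id],
                             response=p_i, matrix=matrix, labels=list(partners),
                             constrained=np.zeros(len(partners), dtype=bool))


def build_target_regression(node_id: str, net: CandidateGWGEN,
                            data: ExpressionDataset) -> RegressionProblem:
    """Regulatory equation for a gene/lncRNA/miRNA target.

    Column order is (TFs, lncRNAs, miRNAs, basal); miRNA columns are the
    bilinear products response·m and carry the non-positivity constraint.
    """
    kind = net.kinds[node_id]
    if kind in PROTEIN_KINDS:
        raise ValueError(f"{node_id!r} is protein-kind; use build_protein_regression")
    regs = net.regulators_for_equation(node_id)
    missing = [r for r in regs if r not in data.values.index]
    if missing:
        raise ValueError(f"regulators of {node_id!r} missing from data: {missing}")
    tfs = sorted(r for r in regs if net.kinds[r] == "tf")
    lncs = sorted(r for r in regs if net.kinds[r] == "lncrna")
    mirs = sorted(r for r in regs if net.kinds[r] == "mirna")
    y = data.series(node_id)
    cols = [data.series(r) for r in tfs + lncs] + [y * data.series(m) for m in mirs]
    matrix = np.column_stack(cols + [np.ones(len(y))])
    constrained = np.array([False] * (len(tfs) + len(lncs)) + [True] * len(mirs))
    return RegressionProblem(node_id=node_id, kind=kind, response=y,
                             matrix=matrix, labels=tfs + lncs + mirs,
                             constrained=constrained)


def build_regression(node_id: str, net: CandidateGWGEN,
                     data: ExpressionDataset) -> RegressionProblem:
    if net.kinds[node_id] in PROTEIN_KINDS:
        return build_protein_regression(node_id, net, data)
    return build_target_regression(node_id, net, data)


def solve_least_squares(problem: RegressionProblem) -> tuple[np.ndarray, float]:
    """Minimise ½‖Ω·ω − y‖² subject to masked coefficients ≤ 0.

    Returns the full parameter vector (regulators then basal) and the
    residual sum of squares.  Unconstrained problems use the normal
    least-squares solution; constrained ones bounded-variable least squares.
    """
    A, y = problem.matrix, problem.response
    n, p = A.shape
    if n < p:
        raise ValueError(
            f"equation for {problem.node_id!r} has {p} parameters but only "
            f"{n} samples; apply the degree cap first")
    if not problem.constrained.any():
        omega, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < p:
            logger.warning("rank-deficient regression for %s (rank %d < %d); "
                           "minimum-norm solution used", problem.node_id, rank, p)
    else:
        ub = np.full(p, np.inf)
        ub[:-1][problem.constrained] = 0.0
        res = lsq_linear(A, y, bounds=(np.full(p, -np.inf), ub),
                         method="bvls", tol=1e-14)
        omega = res.x
    resid = A @ omega - y
    return omega, float(resid @ resid)


def compute_aic(rss: float, n: int, delta: int, *,
                variance_floor: float = DEFAULT_VARIANCE_FLOOR,
                log_base: float = DEFAULT_LOG_BASE) -> float:
    """Information criterion log_b(ε̂²) + 2Δ/N with ε̂² = RSS/N floored.

    The floor keeps zero-residual fits finite and comparable: among perfect
    fits the smaller parameter count Δ wins.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if delta < 1:
        raise ValueError("delta must be >= 1 (basal term)")
    var = max(rss / n, variance_floor)
    return float(np.log(var) / np.log(log_base) + 2.0 * delta / n)


def select_order(problem: RegressionProblem, *,
                 variance_floor: float = DEFAULT_VARIANCE_FLOOR,
                 log_base: float = DEFAULT_LOG_BASE) -> NodeModel:
    """Detect the real regulator set of one node.

    Fits the full candidate model, ranks regressors by descending
    |coefficient|·sd(regressor column) (ties broken by node id), refits the
    nested family k = 0…K and returns the AIC-minimising model (ties go to
    the smaller k).  Regulators whose fitted coefficient is exactly zero
    (an active non-positivity constraint) are never selected.
    """
    n = problem.n_samples
    K = len(problem.labels)
    if K:
        omega_full, _ = solve_least_squares(problem)
        sds = problem.matrix[:, :K].std(axis=0)
        score = np.abs(omega_full[:K]) * sds
        ranked = sorted(range(K), key=lambda j: (-score[j], problem.labels[j]))
        ranked_labels = [problem.labels[j] for j in ranked
                         if abs(omega_full[j]) > 0.0]
    else:
        ranked_labels = []

    best: tuple[float, int, np.ndarray, float, list[str]] | None = None
    for k in range(len(ranked_labels) + 1):
        sub = problem.subproblem(ranked_labels[:k])
        omega, rss = solve_least_squares(sub)
        aic = compute_aic(rss, n, k + 1, variance_floor=variance_floor,
                          log_base=log_base)
        if best is None or aic < best[0] - 1e-12:
            best = (aic, k, omega, rss, ranked_labels[:k])

    aic, k, omega, rss, labels = best
    regulators = {l: float(c) for l, c in zip(labels, omega[:k]) if c != 0.0}
    return NodeModel(node_id=problem.node_id, kind=problem.kind,
                     regulators=dict(sorted(regulators.items())),
                     basal=float(omega[-1]), rss=rss, n_samples=n, aic=aic)


def identify_gwgen(net: CandidateGWGEN, data: ExpressionDataset, *,
                   variance_floor: float = DEFAULT_VARIANCE_FLOOR,
                   log_base: float = DEFAULT_LOG_BASE) -> RealGWGEN:
    """Identify the real GWGEN: one pruned NodeModel per node.

    Every node in the candidate network gets an equation (intercept-only
    when it has no candidate regulators); the identified edge set is
    exactly the union of selected regulators and is always a subset of the
    candidate edge set.
    """
    missing = [n for n in net.kinds.index if n not in data.values.index]
    if missing:
        raise ValueError(f"nodes missing from expression data: {missing[:5]}")
    models: dict[str, NodeModel] = {}
    for node_id in sorted(net.kinds.index):
        try:
            problem = build_regression(node_id, net, data)
            models[node_id] = select_order(problem, variance_floor=variance_floor,
                                           log_base=log_base)
        except Exception as exc:
            raise RuntimeError(f"identification failed at node {node_id!r}: {exc}") from exc
    logger.info("identified %d node models", len(models))
    return RealGWGEN(kinds=net.kinds.copy(), models=models)
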