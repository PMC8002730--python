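"""Principal network projection: score nodes by how much of the identified
network's SVD energy they carry, and cut out the core subnetwork.

The identified abilities are assembled into a combined matrix W whose rows
are equation-owning (downstream-receiving) nodes and whose columns are
upstream-capable nodes (proteins, receptors, TFs, lncRNAs, miRNAs), with
W[target, regulator] equal to the estimated ability.  W = T·D·Hᵀ is
decomposed by SVD; the eigenexpression fraction E_s = d_s²/Σd² measures
each singular component's energy share; the minimal rank S with cumulative
energy ≥ the threshold (default 0.85) defines the principal structure; and
each column (row) is scored by the 2-norm of its projection onto the top-S
right (left) singular vectors.  High-scoring nodes form the core GWGEN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    CoreGWGEN,
    GRN_REGULATOR_KINDS,
    PROTEIN_KINDS,
    RealGWGEN,
    edge_type_for,
    ppi_pair,
)

logger = logging.getLogger(__name__)

DEFAULT_ENERGY_THRESHOLD = 0.85
DEFAULT_TOP_K = 2000

_ROW_KIND_ORDER = {"protein": 0, "receptor": 0, "tf": 0, "gene": 1,
                   "lncrna": 2, "mirna": 3}
_COL_KIND_ORDER = {"protein": 0, "receptor": 0, "tf": 1, "lncrna": 2, "mirna": 3}


@dataclass
class CombinedMatrix:
    """Dense signed-ability matrix with labelled rows (targets) and columns
    (upstream nodes), in block order: proteins, genes, lncRNAs, miRNAs."""

    matrix: pd.DataFrame
    kinds: pd.Series

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


@dataclass
class ProjectionResult:
    """SVD of W plus derived quantities: singular values, eigenexpression
    fractions, selected rank S, and per-node projection scores."""

    singular_values: np.ndarray
    energy_fractions: np.ndarray
    rank: int
    threshold: float
    left_vectors: pd.DataFrame       # T: rows × components
    right_vectors: pd.DataFrame      # H: columns × components
    downstream: pd.Series            # per-column 2-norm projection score
    upstream: pd.Series              # per-row 2-norm projection score


def build_combined_matrix(real: RealGWGEN) -> CombinedMatrix:
    """Place every selected ability at W[target, regulator]; zeros elsewhere."""
    if not any(m.order for m in real.models.values()):
        raise ValueError("identified network has no selected edges")
    rows = sorted(real.models, key=lambda n: (_ROW_KIND_ORDER[real.kinds[n]], n))
    cols = sorted((n for n in real.kinds.index
                   if real.kinds[n] in PROTEIN_KINDS | GRN_REGULATOR_KINDS),
                  key=lambda n: (_COL_KIND_ORDER[real.kinds[n]], n))
    W = pd.DataFrame(0.0, index=rows, columns=cols)
    for nid, model in real.models.items():
        for reg, ability in model.regulators.items():
            W.loc[nid, reg] = ability
    return CombinedMatrix(matrix=W, kinds=real.kinds.copy())


def decompose(W: CombinedMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD W = T·D·Hᵀ with descending singular values.

    Sign convention: each right singular vector is flipped so its largest-
    magnitude entry is positive (scores are unaffected — they square the
    projections — but stored vectors are reproducible).
    """
    A = W.to_numpy()
    if not np.isfinite(A).all():
        raise ValueError("combined matrix contains non-finite entries")
    T, d, Ht = np.linalg.svd(A, full_matrices=False)
    H = Ht.T
    for s in range(H.shape[1]):
        j = int(np.argmax(np.abs(H[:, s])))
        if H[j, s] < 0:
            H[:, s] = -H[:, s]
            T[:, s] = -T[:, s]
    return T, d, H


def eigenexpression_fractions(d: np.ndarray) -> np.ndarray:
    """E_s = d_s² / Σ d_s² (energy share of each singular component)."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("singular values must be non-negative")
    total = float(np.sum(d ** 2))
    if total == 0:
        raise ValueError("all singular values are zero; fractions undefined")
    return d ** 2 / total


def select_rank(E: np.ndarray, threshold: float = DEFAULT_ENERGY_THRESHOLD) -> int:
    """Smallest S with cumulative energy Σ_{s≤S} E_s ≥ threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(E)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def projection_scores(W: CombinedMatrix, T: np.ndarray, H: np.ndarray,
                      S: int) -> tuple[pd.Series, pd.Series]:
    """2-norm projection scores of the top-S principal structure.

    The s-th principal component of W is the dyad d_s·t_s·h_sᵀ.  A column
    (downstream node) w_:,c lives in row space and its projection onto
    component s is t_sᵀ·w_:,c = d_s·h_s[c]; a row (upstream node) w_r,:
    projects onto h_s as w_r,:·h_s = d_s·t_s[r].  The score is the 2-norm
    of the first S projections.
    """
    A = W.to_numpy()
    if not 1 <= S <= H.shape[1]:
        raise ValueError(f"S must be in [1, {H.shape[1]}]")
    proj_cols = T[:, :S].T @ A          # (S, n_cols)
    down = pd.Series(np.sqrt((proj_cols ** 2).sum(axis=0)), index=W.matrix.columns)
    proj_rows = A @ H[:, :S]            # (n_rows, S)
    up = pd.Series(np.sqrt((proj_rows ** 2).sum(axis=1)), index=W.matrix.index)
    return down, up


def principal_network_projection(
        real: RealGWGEN,
        threshold: float = DEFAULT_ENERGY_THRESHOLD) -> ProjectionResult:
    """Full PNP pass: combined matrix → SVD → rank selection → scores."""
    W = build_combined_matrix(real)
    T, d, H = decompose(W)
    E = eigenexpression_fractions(d)
    S = select_rank(E, threshold)
    down, up = projection_scores(W, T, H, S)
    comp = [f"C{s + 1}" for s in range(len(d))]
    return ProjectionResult(
        singular_values=d, energy_fractions=E, rank=S, threshold=threshold,
        left_vectors=pd.DataFrame(T, index=W.matrix.index, columns=comp),
        right_vectors=pd.DataFrame(H, index=W.matrix.columns, columns=comp),
        downstream=down, upstream=up)


def extract_core(real: RealGWGEN, result: ProjectionResult,
                 top_k: int = DEFAULT_TOP_K) -> CoreGWGEN:
    """Keep the top_k nodes by projection score and their induced edges.

    A node active in both roles is scored by the larger of its upstream and
    downstream projections; ties in the ranking break by node id.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    node_ids = sorted(set(result.downstream.index) | set(result.upstream.index))
    rows = []
    for n in node_ids:
        dn = float(result.downstream.get(n, np.nan))
        upv = float(result.upstream.get(n, np.nan))
        rows.append({"kind": real.kinds[n],
                     "score_downstream": dn, "score_upstream": upv,
                     "score": np.nanmax([dn, upv])})
    nodes = pd.DataFrame(rows, index=pd.Index(node_ids, name="node_id"))
    order = sorted(node_ids, key=lambda n: (-nodes.loc[n, "score"], n))
    nodes = nodes.loc[order]
    nodes["rank"] = np.arange(1, len(nodes) + 1)
    core_nodes = nodes.iloc[:min(top_k, len(nodes))]
    keep = set(core_nodes.index)

    edge_rows = []
    for nid in sorted(real.models):
        m = real.models[nid]
        if nid not in keep:
            continue
        for reg in sorted(m.regulators):
            if reg in keep:
                edge_rows.append({
                    "source_id": reg, "target_id": nid,
                    "edge_type": edge_type_for(real.kinds[reg], real.kinds[nid]),
                    "ability": m.regulators[reg]})
    edges = pd.DataFrame(edge_rows,
                         columns=["source_id", "target_id", "edge_type", "ability"])
    logger.info("core: %d/%d nodes, %d edges", len(core_nodes), len(nodes), len(edges))
    return CoreGWGEN(nodes=core_nodes.copy(), edges=edges,
                     provenance={"threshold": result.threshold,
                                 "rank": result.rank, "top_k": top_k})
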