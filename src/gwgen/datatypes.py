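"""Core containers for genome-wide genetic and epigenetic networks (GWGENs).

A GWGEN couples an undirected protein-protein interaction network (PPIN)
over protein-like nodes (proteins, receptors, transcription factors) with a
directed gene-regulatory network (GRN) in which TFs, lncRNAs and miRNAs
regulate genes, lncRNAs and miRNAs.  The containers here distinguish the
*candidate* network (a Boolean hypothesis set, typically database-derived
or synthetic) from the *identified* network (the subset surviving
regression and information-criterion pruning, with signed abilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Kinds that participate in the PPIN and may appear as interaction partners.
PROTEIN_KINDS = frozenset({"protein", "receptor", "tf"})
#: Kinds allowed on the source side of a regulatory (GRN) edge.
GRN_REGULATOR_KINDS = frozenset({"tf", "lncrna", "mirna"})
#: Kinds allowed on the target side of a regulatory (GRN) edge.
GRN_TARGET_KINDS = frozenset({"gene", "lncrna", "mirna"})
NODE_KINDS = frozenset({"protein", "receptor", "tf", "gene", "lncrna", "mirna"})

EDGE_TYPES = (
    "ppi",
    "tf_gene", "tf_lncrna", "tf_mirna",
    "lncrna_gene", "lncrna_lncrna", "lncrna_mirna",
    "mirna_gene", "mirna_lncrna", "mirna_mirna",
)

_GRN_SUFFIX = {"gene": "gene", "lncrna": "lncrna", "mirna": "mirna"}


def ppi_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected PPI edge."""
    if a == b:
        raise ValueError(f"protein self-interaction is not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def edge_type_for(src_kind: str, tgt_kind: str) -> str:
    """Edge-type label implied by the kinds of the two endpoints."""
    if src_kind in PROTEIN_KINDS and tgt_kind in PROTEIN_KINDS:
        return "ppi"
    if src_kind in GRN_REGULATOR_KINDS and tgt_kind in GRN_TARGET_KINDS:
        return f"{src_kind}_{_GRN_SUFFIX[tgt_kind]}"
    raise ValueError(f"no edge type connects kind {src_kind!r} to {tgt_kind!r}")


def _check_kinds(kinds: pd.Series) -> pd.Series:
    if kinds.index.has_duplicates:
        dups = kinds.index[kinds.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate node ids: {dups}")
    bad = sorted(set(kinds) - NODE_KINDS)
    if bad:
        raise ValueError(f"unknown node kinds: {bad}")
    return kinds.astype(str)


@dataclass
class ExpressionDataset:
    """Node-by-sample matrix of expression levels (log-intensity scale).

    ``values`` rows are node ids, columns are sample ids; ``kinds`` maps each
    node id to its kind.  miRNA rows must be non-negative so that the
    bilinear repression term −γ·m·g acts as a repression when γ ≥ 0.
    """

    values: pd.DataFrame
    kinds: pd.Series
    condition: str | None = None

    def __post_init__(self) -> None:
        self.kinds = _check_kinds(self.kinds)
        missing = self.values.index.difference(self.kinds.index)
        if len(missing):
            raise ValueError(f"nodes without a kind: {sorted(missing)[:5]}")
        self.kinds = self.kinds.reindex(self.values.index)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate node ids: {list(dups)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise ValueError("expression matrix must be numeric and finite")
        mirna = self.kinds[self.kinds == "mirna"].index
        if len(mirna) and (self.values.loc[mirna].to_numpy() < 0).any():
            raise ValueError("miRNA expression values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def node_ids(self) -> list[str]:
        return list(self.values.index)

    def series(self, node_id: str) -> np.ndarray:
        """Expression of one node across samples, as a float vector."""
        return self.values.loc[node_id].to_numpy(dtype=float)


@dataclass
class CandidateGWGEN:
    """Boolean hypothesis network: symmetric PPI pairs + directed GRN edges.

    ``equation_regulators``, when present, overrides the per-node candidate
    regulator list used by identification (set by the degree cap, which
    prunes per equation and may keep a symmetric PPI edge for one endpoint
    only).
    """

    kinds: pd.Series
    ppi: set[tuple[str, str]] = field(default_factory=set)
    grn: set[tuple[str, str]] = field(default_factory=set)
    equation_regulators: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        self.kinds = _check_kinds(self.kinds)
        self.validate()

    def validate(self) -> None:
        for a, b in self.ppi:
            if a >= b:
                raise ValueError(f"PPI pair not in canonical order: {(a, b)}")
            for n in (a, b):
                if n not in self.kinds.index:
                    raise ValueError(f"ppi edge references unknown node {n!r}")
                if self.kinds[n] not in PROTEIN_KINDS:
                    raise ValueError(f"ppi endpoint {n!r} has kind {self.kinds[n]!r}")
        for s, t in self.grn:
            for n in (s, t):
                if n not in self.kinds.index:
                    raise ValueError(f"grn edge references unknown node {n!r}")
            if s == t:
                raise ValueError(f"self-regulation is not allowed: {s!r}")
            edge_type_for(self.kinds[s], self.kinds[t])  # raises if incompatible

    # -- queries -----------------------------------------------------------
    def ppi_partners(self, node_id: str) -> list[str]:
        return sorted(b if a == node_id else a
                      for a, b in self.ppi if node_id in (a, b))

    def grn_regulators(self, target_id: str) -> list[str]:
        return sorted(s for s, t in self.grn if t == target_id)

    def regulators_for_equation(self, node_id: str) -> list[str]:
        """Candidate regulators entering ``node_id``'s regression equation."""
        if self.equation_regulators is not None and node_id in self.equation_regulators:
            return list(self.equation_regulators[node_id])
        if self.kinds[node_id] in PROTEIN_KINDS:
            return self.ppi_partners(node_id)
        return self.grn_regulators(node_id)

    @property
    def n_edges(self) -> int:
        return len(self.ppi) + len(self.grn)

    def edge_set(self) -> set[tuple[str, str, str]]:
        """All edges as ('ppi', a, b) / ('grn', src, tgt) triples."""
        out = {("ppi", a, b) for a, b in self.ppi}
        out |= {("grn", s, t) for s, t in self.grn}
        return out

    def copy(self) -> "CandidateGWGEN":
        return CandidateGWGEN(
            kinds=self.kinds.copy(),
            ppi=set(self.ppi),
            grn=set(self.grn),
            equation_regulators=(dict(self.equation_regulators)
                                 if self.equation_regulators is not None else None),
        )


@dataclass
class GroundTruthModel:
    """Planted generating model behind a synthetic expression dataset.

    ``coefficients[target][regulator]`` is the signed model coefficient of
    that regulator in the target's generating equation (miRNA-regulator
    entries are −γ ≤ 0).  ``basal`` holds the constant term ψ of every
    computed target.  Nodes in ``source_ids`` are drawn i.i.d. and have no
    generating equation.
    """

    kinds: pd.Series
    coefficients: dict[str, dict[str, float]]
    basal: dict[str, float]
    source_ids: frozenset[str]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.kinds = _check_kinds(self.kinds)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for tgt, regs in self.coefficients.items():
            tk = self.kinds[tgt]
            for src, coef in regs.items():
                if src == tgt:
                    raise ValueError(f"self-interaction in truth: {tgt!r}")
                sk = self.kinds[src]
                if tk in PROTEIN_KINDS:
                    if sk not in PROTEIN_KINDS:
                        raise ValueError(f"non-protein partner {src!r} for protein {tgt!r}")
                else:
                    edge_type_for(sk, tk)  # raises if kind-incompatible
                    if sk == "mirna" and coef > 0:
                        raise ValueError(
                            f"miRNA repression coefficient must be <= 0: {src!r}->{tgt!r}")

    def with_noise(self, noise_sd: float) -> "GroundTruthModel":
        return replace(self, noise_sd=float(noise_sd))

    def true_ppi_edges(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for tgt, regs in self.coefficients.items():
            if self.kinds[tgt] in PROTEIN_KINDS:
                out.update(ppi_pair(tgt, src) for src in regs)
        return out

    def true_grn_edges(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for tgt, regs in self.coefficients.items():
            if self.kinds[tgt] not in PROTEIN_KINDS:
                out.update((src, tgt) for src in regs)
        return out

    def edge_set(self) -> set[tuple[str, str, str]]:
        return ({("ppi", a, b) for a, b in self.true_ppi_edges()}
                | {("grn", s, t) for s, t in self.true_grn_edges()})

    @property
    def n_true_edges(self) -> int:
        return len(self.true_ppi_edges()) + len(self.true_grn_edges())


@dataclass
class NodeModel:
    """Identified regression model of one node: selected regulators,
    signed abilities, basal level, residual sum of squares and AIC."""

    node_id: str
    kind: str
    regulators: dict[str, float]
    basal: float
    rss: float
    n_samples: int
    aic: float

    @property
    def order(self) -> int:
        return len(self.regulators)

    def kind_orders(self, kinds: pd.Series) -> dict[str, int]:
        """Selected-regulator counts broken down by regulator kind."""
        out: dict[str, int] = {}
        for r in self.regulators:
            out[kinds[r]] = out.get(kinds[r], 0) + 1
        return out


@dataclass
class RealGWGEN:
    """Identified GWGEN: one NodeModel per equation-owning node."""

    kinds: pd.Series
    models: dict[str, NodeModel]

    def ppi_edges(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for m in self.models.values():
            if m.kind in PROTEIN_KINDS:
                out.update(ppi_pair(m.node_id, r) for r in m.regulators)
        return out

    def grn_edges(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for m in self.models.values():
            if m.kind not in PROTEIN_KINDS:
                out.update((r, m.node_id) for r in m.regulators)
        return out

    def edge_set(self) -> set[tuple[str, str, str]]:
        return ({("ppi", a, b) for a, b in self.ppi_edges()}
                | {("grn", s, t) for s, t in self.grn_edges()})

    @property
    def n_edges(self) -> int:
        return len(self.ppi_edges()) + len(self.grn_edges())

    def edge_table(self) -> pd.DataFrame:
        """Per-equation edge list with ability/basal/aic/order columns."""
        rows = []
        for nid in sorted(self.models):
            m = self.models[nid]
            for reg in sorted(m.regulators):
                rows.append({
                    "source_id": reg,
                    "target_id": nid,
                    "edge_type": edge_type_for(self.kinds[reg], self.kinds[nid]),
                    "ability": m.regulators[reg],
                    "basal": m.basal,
                    "aic": m.aic,
                    "order": m.order,
                })
        cols = ["source_id", "target_id", "edge_type", "ability", "basal", "aic", "order"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class CoreGWGEN:
    """Top-scoring subnetwork extracted by principal network projection."""

    nodes: pd.DataFrame  # index node_id; kind, score, score_downstream, score_upstream, rank
    edges: pd.DataFrame  # source_id, target_id, edge_type, ability
    provenance: dict = field(default_factory=dict)

    @property
    def node_set(self) -> set[str]:
        return set(self.nodes.index)

    def nodes_of_kind(self, kind: str) -> set[str]:
        return set(self.nodes.index[self.nodes["kind"] == kind])

    def edge_triples(self) -> set[tuple[str, str, str]]:
        out: set[tuple[str, str, str]] = set()
        for row in self.edges.itertuples(index=False):
            if row.edge_type == "ppi":
                out.add(("ppi",) + ppi_pair(row.source_id, row.target_id))
            else:
                out.add(("grn", row.source_id, row.target_id))
        return out
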