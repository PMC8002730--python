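"""TSV/CSV I/O for expression matrices, networks and drug catalogs, plus
the sample-count degree cap applied before identification."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CandidateGWGEN,
    EDGE_TYPES,
    ExpressionDataset,
    GroundTruthModel,
    NODE_KINDS,
    PROTEIN_KINDS,
    RealGWGEN,
    edge_type_for,
    ppi_pair,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# expression

def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """TSV with columns node_id, node_kind, then one column per sample."""
    out = dataset.values.copy()
    out.insert(0, "node_kind", dataset.kinds)
    out.insert(0, "node_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_expression(path: str | Path, condition: str | None = None) -> ExpressionDataset:
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "node_kind": str})
    for col in ("node_id", "node_kind"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["node_id"][df["node_id"].duplicated()]
    if len(dup):
        row = int(dup.index[0]) + 2  # header + 1-based
        raise ValueError(f"{path}:{row}: duplicated node_id {dup.iloc[0]!r}")
    bad_kind = df["node_kind"][~df["node_kind"].isin(NODE_KINDS)]
    if len(bad_kind):
        row = int(bad_kind.index[0]) + 2
        raise ValueError(f"{path}:{row}: unknown node_kind {bad_kind.iloc[0]!r}")
    sample_cols = [c for c in df.columns if c not in ("node_id", "node_kind")]
    body = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        r, c = next(zip(*np.where(body.isna().to_numpy())))
        raise ValueError(f"{path}:{int(r) + 2}: non-numeric value in column "
                         f"{sample_cols[int(c)]!r}")
    values = body.set_axis(df["node_id"], axis=0)
    kinds = pd.Series(df["node_kind"].to_numpy(), index=df["node_id"], dtype=str)
    return ExpressionDataset(values=values, kinds=kinds, condition=condition)


# ---------------------------------------------------------------------------
# networks

def write_network(net: CandidateGWGEN, path: str | Path,
                  truth: GroundTruthModel | None = None) -> None:
    """Edge-list TSV (source_id, target_id, edge_type); with ``truth``,
    adds an is_true 0/1 column marking the planted edges."""
    true_edges = truth.edge_set() if truth is not None else None
    rows = []
    for a, b in sorted(net.ppi):
        rec = {"source_id": a, "target_id": b, "edge_type": "ppi"}
        if true_edges is not None:
            rec["is_true"] = int(("ppi", a, b) in true_edges)
        rows.append(rec)
    for s, t in sorted(net.grn):
        rec = {"source_id": s, "target_id": t,
               "edge_type": edge_type_for(net.kinds[s], net.kinds[t])}
        if true_edges is not None:
            rec["is_true"] = int(("grn", s, t) in true_edges)
        rows.append(rec)
    cols = ["source_id", "target_id", "edge_type"]
    if true_edges is not None:
        cols.append("is_true")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, kinds: pd.Series) -> CandidateGWGEN:
    """Read an edge-list TSV against a known node-kind table.

    PPI rows are stored symmetrically regardless of input orientation;
    edges referencing unknown nodes or kind-incompatible edge types are
    rejected with their row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "target_id", "edge_type"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    ppi: set[tuple[str, str]] = set()
    grn: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        s, t, et = row.source_id, row.target_id, row.edge_type
        if et not in EDGE_TYPES:
            raise ValueError(f"{path}:{line}: unknown edge_type {et!r}")
        for n in (s, t):
            if n not in kinds.index:
                raise ValueError(f"{path}:{line}: edge references unknown node {n!r}")
        expected = edge_type_for(kinds[s], kinds[t])
        if expected != et:
            raise ValueError(
                f"{path}:{line}: edge_type {et!r} incompatible with kinds "
                f"({kinds[s]!r} -> {kinds[t]!r})")
        if et == "ppi":
            ppi.add(ppi_pair(s, t))
        else:
            grn.add((s, t))
    return CandidateGWGEN(kinds=kinds.copy(), ppi=ppi, grn=grn)


def write_identified_network(real: RealGWGEN, path: str | Path) -> None:
    """Per-equation edge list with ability, basal, aic and order columns."""
    real.edge_table().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# drug catalog

def read_drug_catalog(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = ["drug", "target", "connectivity_score", "ld50_mg_per_kg"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    from .drug_design import validate_drug_catalog
    validate_drug_catalog(df)
    return df[required]


def write_drug_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    catalog.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# degree cap

def apply_degree_cap(net: CandidateGWGEN, data: ExpressionDataset,
                     n_samples: int | None = None) -> CandidateGWGEN:
    """Cap every equation's candidate count below the sample number.

    For each node the regression has (k regulators + 1 basal) parameters;
    overfitting is avoided by requiring k + 1 < n_samples, i.e. keeping at
    most n_samples − 2 regulators.  Excess candidates are dropped by
    smallest |Pearson correlation| between the constructed regressor
    (p_i·p_j for PPI, the regulator series for TF/lncRNA, response·m for
    miRNA) and the response; ties break lexicographically by node id.

    The cap is applied per equation: a symmetric PPI edge may survive in
    one endpoint's equation and be dropped from the other's.  The returned
    network keeps an edge whenever at least one equation retains it and
    records per-equation regulator lists.
    """
    if n_samples is None:
        n_samples = data.n_samples
    if n_samples != data.n_samples:
        raise ValueError("n_samples does not match the expression data")
    if n_samples < 3:
        raise ValueError("need at least 3 samples to fit any regulator")
    missing = [n for n in net.kinds.index if n not in data.values.index]
    if missing:
        raise ValueError(f"nodes missing from expression data: {missing[:5]}")

    cap = n_samples - 2
    kept_eq: dict[str, tuple[str, ...]] = {}
    for node_id in sorted(net.kinds.index):
        if net.kinds[node_id] in PROTEIN_KINDS:
            regs = net.ppi_partners(node_id)
        else:
            regs = net.grn_regulators(node_id)
        if len(regs) <= cap:
            kept_eq[node_id] = tuple(regs)
            continue
        y = data.series(node_id)
        scores = []
        for r in regs:
            x = data.series(r)
            if net.kinds[node_id] in PROTEIN_KINDS or net.kinds[r] == "mirna":
                x = y * x  # bilinear constructed regressor
            sx, sy = np.std(x), np.std(y)
            c = 0.0 if sx == 0 or sy == 0 else abs(float(np.corrcoef(x, y)[0, 1]))
            scores.append((c, r))
        ranked = sorted(scores, key=lambda t: (-t[0], t[1]))
        kept_eq[node_id] = tuple(sorted(r for _, r in ranked[:cap]))
        logger.debug("degree cap at %s: kept %d of %d candidates",
                     node_id, cap, len(regs))

    ppi = {pair for pair in net.ppi
           if pair[1] in kept_eq.get(pair[0], ()) or pair[0] in kept_eq.get(pair[1], ())}
    grn = {(s, t) for s, t in net.grn if s in kept_eq.get(t, ())}
    return CandidateGWGEN(kinds=net.kinds.copy(), ppi=ppi, grn=grn,
                          equation_regulators=kept_eq)
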