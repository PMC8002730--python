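"""Compare two condition-specific core GWGENs (e.g. case vs control) into
common and distinctive node/edge sets, with per-kind overlap percentages
and per-node expression-direction labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CoreGWGEN, ExpressionDataset


@dataclass
class ComparisonReport:
    """Set algebra between two cores.

    ``overlap_pct[kind]['a']`` is 100·|kind-nodes of A ∩ B| / |kind-nodes
    of A| (the denominator is the named condition's own core); kinds with
    an empty denominator are absent from the mapping, not reported as 0.
    """

    common_nodes: set[str]
    only_a_nodes: set[str]
    only_b_nodes: set[str]
    common_edges: set[tuple[str, str, str]]
    only_a_edges: set[tuple[str, str, str]]
    only_b_edges: set[tuple[str, str, str]]
    overlap_pct: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "common_nodes": sorted(self.common_nodes),
            "only_a_nodes": sorted(self.only_a_nodes),
            "only_b_nodes": sorted(self.only_b_nodes),
            "common_edges": sorted(list(e) for e in self.common_edges),
            "only_a_edges": sorted(list(e) for e in self.only_a_edges),
            "only_b_edges": sorted(list(e) for e in self.only_b_edges),
            "overlap_pct": {k: dict(v) for k, v in sorted(self.overlap_pct.items())},
        }


def compare_cores(core_a: CoreGWGEN, core_b: CoreGWGEN) -> ComparisonReport:
    """Common/distinctive split of nodes and edges plus overlap percentages."""
    na, nb = core_a.node_set, core_b.node_set
    ea, eb = core_a.edge_triples(), core_b.edge_triples()
    kinds = sorted(set(core_a.nodes["kind"]) | set(core_b.nodes["kind"]))
    overlap: dict[str, dict[str, float]] = {}
    for kind in kinds:
        ka, kb = core_a.nodes_of_kind(kind), core_b.nodes_of_kind(kind)
        entry: dict[str, float] = {}
        if ka:
            entry["a"] = 100.0 * len(ka & kb) / len(ka)
        if kb:
            entry["b"] = 100.0 * len(ka & kb) / len(kb)
        if entry:
            overlap[kind] = entry
    return ComparisonReport(
        common_nodes=na & nb, only_a_nodes=na - nb, only_b_nodes=nb - na,
        common_edges=ea & eb, only_a_edges=ea - eb, only_b_edges=eb - ea,
        overlap_pct=overlap)


def direction_labels(core: CoreGWGEN, data_case: ExpressionDataset,
                     data_control: ExpressionDataset,
                     min_abs_diff: float = 0.0) -> dict[str, str]:
    """Label each core node 'up' or 'down' in case vs control by mean
    expression.

    A node is 'up' iff mean(case) − mean(control) > min_abs_diff (default
    0, so an exact tie is 'down'); nodes missing from either dataset are
    labelled 'unknown'.
    """
    if min_abs_diff < 0:
        raise ValueError("min_abs_diff must be >= 0")
    labels: dict[str, str] = {}
    for node in sorted(core.node_set):
        if node not in data_case.values.index or node not in data_control.values.index:
            labels[node] = "unknown"
            continue
        diff = float(np.mean(data_case.series(node)) - np.mean(data_control.series(node)))
        labels[node] = "up" if diff > min_abs_diff else "down"
    return labels
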