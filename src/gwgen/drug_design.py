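"""Signature-reversal drug filtering and multi-molecule assembly.

Two filters narrow a drug catalog: the *regulation-ability* filter keeps
drugs whose connectivity score (CMap-style, in [−1, 1]) opposes the
biomarker's direction — negative scores for upregulated targets, positive
for downregulated ones — above a magnitude threshold; the *toxicity*
filter keeps drugs whose predicted LD50 is at or above a bound (a higher
median lethal dose meaning lower acute toxicity).  A greedy weighted set
cover then assembles the smallest drug combination covering all biomarkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_ABS_SCORE = 0.5
DEFAULT_MIN_LD50 = 500.0

DIRECTIONS = ("up", "down")


def validate_drug_catalog(catalog: pd.DataFrame) -> None:
    scores = catalog["connectivity_score"].to_numpy(dtype=float)
    if ((scores < -1) | (scores > 1)).any():
        raise ValueError("connectivity scores must lie in [-1, 1]")
    ld50 = catalog["ld50_mg_per_kg"].to_numpy(dtype=float)
    if (ld50 <= 0).any():
        raise ValueError("LD50 values must be > 0")
    if catalog.duplicated(["drug", "target"]).any():
        dup = catalog[catalog.duplicated(["drug", "target"])].iloc[0]
        raise ValueError(f"duplicate (drug, target) pair: {dup['drug']!r}/{dup['target']!r}")


@dataclass
class MultiDrugProposal:
    """Greedy set-cover result: selected drugs, Boolean drug×target
    coverage matrix, per-selection justification and uncovered targets."""

    drugs: list[str]
    coverage: pd.DataFrame            # drugs × targets, 0/1
    records: pd.DataFrame             # drug, target, connectivity_score, ld50
    uncovered: list[str] = field(default_factory=list)


def filter_by_regulation(catalog: pd.DataFrame, signature: dict[str, str],
                         min_abs_score: float = DEFAULT_MIN_ABS_SCORE,
                         ) -> dict[str, pd.DataFrame]:
    """Per-target candidates whose score reverses the signature direction.

    An upregulated target keeps entries with score ≤ −min_abs_score; a
    downregulated one keeps score ≥ +min_abs_score.  Lists are sorted by
    |score| descending (ties by drug name).
    """
    if not 0 <= min_abs_score <= 1:
        raise ValueError("min_abs_score must be in [0, 1]")
    if not signature:
        raise ValueError("signature must be non-empty")
    bad = {t: d for t, d in signature.items() if d not in DIRECTIONS}
    if bad:
        raise ValueError(f"unknown signature directions: {bad}")
    validate_drug_catalog(catalog)
    out: dict[str, pd.DataFrame] = {}
    for target in sorted(signature):
        sub = catalog[catalog["target"] == target]
        if sub.empty:
            logger.warning("target %s absent from the drug catalog", target)
            out[target] = sub.copy()
            continue
        if signature[target] == "up":
            keep = sub["connectivity_score"] <= -min_abs_score
        else:
            keep = sub["connectivity_score"] >= min_abs_score
        sub = sub[keep].copy()
        sub["_abs"] = sub["connectivity_score"].abs()
        sub = sub.sort_values(["_abs", "drug"], ascending=[False, True],
                              kind="mergesort").drop(columns="_abs")
        out[target] = sub.reset_index(drop=True)
    return out


def filter_by_toxicity(candidates: dict[str, pd.DataFrame],
                       min_ld50: float = DEFAULT_MIN_LD50,
                       ) -> dict[str, pd.DataFrame]:
    """Keep candidates with predicted LD50 ≥ min_ld50 (closed bound)."""
    if min_ld50 < 0:
        raise ValueError("min_ld50 must be >= 0")
    return {t: df[df["ld50_mg_per_kg"] >= min_ld50].reset_index(drop=True)
            for t, df in candidates.items()}


def assemble_multidrug(candidates: dict[str, pd.DataFrame]) -> MultiDrugProposal:
    """Greedy weighted set cover over the filtered per-target candidates.

    Repeatedly picks the drug covering the most uncovered targets; ties
    break by larger summed |score| over newly covered targets, then larger
    LD50, then drug name.  Targets no drug can treat are reported as
    uncovered, not raised.
    """
    targets = sorted(candidates)
    cover_map: dict[str, dict[str, tuple[float, float]]] = {}
    for tgt, df in candidates.items():
        for row in df.itertuples(index=False):
            cover_map.setdefault(row.drug, {})[tgt] = (
                float(row.connectivity_score), float(row.ld50_mg_per_kg))

    uncovered = set(targets)
    selected: list[str] = []
    while uncovered:
        best = None
        for drug in sorted(cover_map):
            new = uncovered & set(cover_map[drug])
            if not new:
                continue
            gain = len(new)
            sum_abs = sum(abs(cover_map[drug][t][0]) for t in new)
            ld50 = max(cover_map[drug][t][1] for t in new)
            key = (gain, sum_abs, ld50)
            if best is None or key > best[0]:
                best = (key, drug, new)
        if best is None:
            break
        _, drug, new = best
        selected.append(drug)
        uncovered -= new

    coverage = pd.DataFrame(0, index=pd.Index(selected, name="drug"),
                            columns=pd.Index(targets, name="target"), dtype=int)
    rec_rows = []
    for drug in selected:
        for tgt, (score, ld50) in sorted(cover_map[drug].items()):
            coverage.loc[drug, tgt] = 1
            rec_rows.append({"drug": drug, "target": tgt,
                             "connectivity_score": score,
                             "ld50_mg_per_kg": ld50})
    records = pd.DataFrame(rec_rows, columns=["drug", "target",
                                              "connectivity_score", "ld50_mg_per_kg"])
    if uncovered:
        logger.warning("uncovered targets: %s", sorted(uncovered))
    return MultiDrugProposal(drugs=selected, coverage=coverage, records=records,
                             uncovered=sorted(uncovered))


def design_drugs(catalog: pd.DataFrame, signature: dict[str, str],
                 min_abs_score: float = DEFAULT_MIN_ABS_SCORE,
                 min_ld50: float = DEFAULT_MIN_LD50) -> MultiDrugProposal:
    """Both filters followed by greedy multi-molecule assembly."""
    cands = filter_by_regulation(catalog, signature, min_abs_score)
    cands = filter_by_toxicity(cands, min_ld50)
    return assemble_multidrug(cands)
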