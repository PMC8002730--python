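"""Synthetic GWGENs and expression data with known ground truth.

The generator plants a true multipartite network (PPI partners for target
proteins; TF/lncRNA/miRNA regulators for genes, target lncRNAs and target
miRNAs), buries it among decoy candidate edges, and simulates expression
samples that satisfy the generating equations *exactly* up to the drawn
noise term:

  protein   p = (ψ + θ) / (1 − Σ λ·p_partner)
  gene      g = (Σ α·t + Σ β·l + ψ + θ) / (1 + Σ γ·m)
  lncRNA    l = (Σ δ·t + Σ Γ·l + ψ + θ) / (1 + Σ τ·m)
  miRNA     m = (Σ υ·t + Σ σ·l + ψ + θ) / (1 + Σ ζ·m)

Nodes are split into a *source* layer (receptors, TFs, a designated half of
the plain proteins, and half of the lncRNAs/miRNAs), drawn i.i.d. from a
truncated log-normal, and a *target* layer computed from the closed forms
above — so refitting each equation on the simulated data reproduces the
planted coefficients with zero residual at noise 0.

Decoy edges attach only to computed targets: a candidate regressor on a
source node's equation shares a factor with the response and is therefore
statistically inseparable from signal, which would make exact recovery of
the planted structure ill-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    CandidateGWGEN,
    ExpressionDataset,
    GroundTruthModel,
    PROTEIN_KINDS,
    ppi_pair,
)

# Source-layer distribution: log-normal location 0, scale 0.5 on the log
# scale, truncated at ±2.5 sigma so regressor magnitudes are bounded.
LOG_SCALE = 0.5
LOG_TRUNC = 2.5
SOURCE_MAX = float(np.exp(LOG_TRUNC * LOG_SCALE))
SOURCE_MIN = float(np.exp(-LOG_TRUNC * LOG_SCALE))

# Regulatory-ability magnitudes are bounded away from zero so order
# selection is well-posed; the positive-λ budget keeps every protein
# denominator 1 − Σ λ·p at least 0.15 away from zero.
COEF_LOW, COEF_HIGH = 0.2, 1.0
POSITIVE_BUDGET = 0.85
STABILITY_FLOOR = 0.1
BASAL_LOW, BASAL_HIGH = 2.0, 6.0


@dataclass(frozen=True)
class _Layout:
    """Node ids grouped by kind and by generator role."""

    kinds: pd.Series
    protein_sources: tuple[str, ...]   # receptors + TFs + designated plain proteins
    protein_targets: tuple[str, ...]   # computed plain proteins (DAG-ordered)
    tfs: tuple[str, ...]
    lnc_sources: tuple[str, ...]
    lnc_targets: tuple[str, ...]
    mir_sources: tuple[str, ...]
    mir_targets: tuple[str, ...]
    genes: tuple[str, ...]

    @property
    def grn_sources(self) -> tuple[str, ...]:
        return tuple(sorted(self.tfs + self.lnc_sources + self.mir_sources))

    @property
    def grn_targets(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes + self.lnc_targets + self.mir_targets))

    @property
    def source_ids(self) -> frozenset[str]:
        return frozenset(self.protein_sources + self.lnc_sources + self.mir_sources)


def _node_layout(n_proteins: int, n_genes: int, n_mirnas: int, n_lncrnas: int) -> _Layout:
    for name, n in [("n_proteins", n_proteins), ("n_genes", n_genes),
                    ("n_mirnas", n_mirnas), ("n_lncrnas", n_lncrnas)]:
        if n < 1:
            raise ValueError(f"{name} must be >= 1, got {n}")
    n_tf = max(1, round(0.2 * n_proteins))
    n_rec = round(0.2 * n_proteins)
    while n_proteins - n_tf - n_rec < 2 and n_rec > 0:
        n_rec -= 1
    while n_proteins - n_tf - n_rec < 2 and n_tf > 1:
        n_tf -= 1
    n_plain = n_proteins - n_tf - n_rec
    tfs = tuple(f"TF{i:03d}" for i in range(n_tf))
    recs = tuple(f"REC{i:03d}" for i in range(n_rec))
    plain = [f"PRO{i:03d}" for i in range(n_plain)]
    n_src_plain = math.ceil(n_plain / 2)
    genes = tuple(f"GEN{i:04d}" for i in range(n_genes))
    lncs = [f"LNC{i:03d}" for i in range(n_lncrnas)]
    mirs = [f"MIR{i:03d}" for i in range(n_mirnas)]
    n_lnc_src = math.ceil(n_lncrnas / 2)
    n_mir_src = math.ceil(n_mirnas / 2)

    kinds = {}
    for t in tfs:
        kinds[t] = "tf"
    for r in recs:
        kinds[r] = "receptor"
    for p in plain:
        kinds[p] = "protein"
    for g in genes:
        kinds[g] = "gene"
    for l in lncs:
        kinds[l] = "lncrna"
    for m in mirs:
        kinds[m] = "mirna"
    return _Layout(
        kinds=pd.Series(kinds, dtype=str).sort_index(),
        protein_sources=tuple(sorted(recs + tfs + tuple(plain[:n_src_plain]))),
        protein_targets=tuple(plain[n_src_plain:]),
        tfs=tfs,
        lnc_sources=tuple(lncs[:n_lnc_src]),
        lnc_targets=tuple(lncs[n_lnc_src:]),
        mir_sources=tuple(mirs[:n_mir_src]),
        mir_targets=tuple(mirs[n_mir_src:]),
        genes=genes,
    )


# ---------------------------------------------------------------------------
# edge sampling

def _sample_true_edges(layout: _Layout, true_density: float,
                       rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Bernoulli(true_density) draw over every allowed source→target slot.

    Every computed protein target receives at least one source partner:
    a target with no regulators would be constant across samples, and a
    constant protein entering another equation's bilinear regressor p_i·p_j
    makes that regressor proportional to the response — a degenerate,
    unidentifiable configuration.
    """
    edges: list[tuple[str, str, str]] = []
    for tgt in layout.protein_targets:
        partners = [src for src in layout.protein_sources
                    if rng.random() < true_density]
        if not partners:
            partners = [layout.protein_sources[
                int(rng.integers(len(layout.protein_sources)))]]
        edges.extend(("ppi",) + ppi_pair(src, tgt) for src in partners)
    for tgt in layout.grn_targets:
        for src in layout.grn_sources:
            if rng.random() < true_density:
                edges.append(("grn", src, tgt))
    return edges


def _decoy_pool(layout: _Layout,
                taken: set[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    """Kind-respecting edges attached to computed targets and not yet used.

    PPI decoys connect two computed target proteins so that both incident
    equations carry an exact generating model and prune them.
    """
    pool: list[tuple[str, str, str]] = []
    tgts = layout.protein_targets
    for i, a in enumerate(tgts):
        for b in tgts[i + 1:]:
            e = ("ppi",) + ppi_pair(a, b)
            if e not in taken:
                pool.append(e)
    for tgt in layout.grn_targets:
        for src in layout.grn_sources:
            e = ("grn", src, tgt)
            if e not in taken:
                pool.append(e)
    return sorted(pool)


def _choose(pool: list, n: int, rng: np.random.Generator) -> list:
    if n > len(pool):
        raise ValueError(
            f"requested {n} edges but only {len(pool)} feasible slots remain; "
            "lower true_density/decoy_ratio or enlarge the network")
    idx = rng.choice(len(pool), size=n, replace=False) if n else []
    return [pool[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# coefficient assignment

def _signed_magnitudes(k: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(COEF_LOW, COEF_HIGH, size=k) * rng.choice([-1.0, 1.0], size=k)


def _assign_parameters(layout: _Layout, edges: list[tuple[str, str, str]],
                       rng: np.random.Generator,
                       ) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Draw abilities and basal levels for one condition's true edge set."""
    kinds = layout.kinds
    targets_of: dict[str, list[str]] = {}
    for kind, a, b in edges:
        if kind == "ppi":
            # the computed endpoint owns the generating term; for
            # target-target (DAG) pairs the later node owns it
            pt = set(layout.protein_targets)
            if a in pt and b in pt:
                owner, partner = (b, a)
            elif a in pt:
                owner, partner = (a, b)
            else:
                owner, partner = (b, a)
            targets_of.setdefault(owner, []).append(partner)
        else:
            targets_of.setdefault(b, []).append(a)

    coefficients: dict[str, dict[str, float]] = {}
    basal: dict[str, float] = {}
    protein_targets = set(layout.protein_targets)
    for tgt in sorted(set(layout.protein_targets) | set(layout.grn_targets)):
        regs = sorted(targets_of.get(tgt, []))
        coefs: dict[str, float] = {}
        if tgt in protein_targets:
            lam = _signed_magnitudes(len(regs), rng)
            # DAG partners (computed proteins) always repress: their values
            # are bounded only through their own equations, so a positive λ
            # could push the denominator 1 − Σλp toward zero.
            for i, r in enumerate(regs):
                if r in protein_targets:
                    lam[i] = -abs(lam[i])
            # cap the positive budget so 1 − Σ λ·p ≥ 1 − POSITIVE_BUDGET
            while True:
                pos = [i for i in range(len(regs))
                       if lam[i] > 0 and regs[i] not in protein_targets]
                if sum(lam[i] for i in pos) * SOURCE_MAX <= POSITIVE_BUDGET:
                    break
                imax = max(pos, key=lambda i: lam[i])
                lam[imax] = -lam[imax]
            coefs = {r: float(v) for r, v in zip(regs, lam)}
            psi = float(rng.uniform(BASAL_LOW, BASAL_HIGH))
        else:
            vals = []
            for r in regs:
                if kinds[r] == "mirna":
                    vals.append(-float(rng.uniform(COEF_LOW, COEF_HIGH)))
                else:
                    vals.append(float(_signed_magnitudes(1, rng)[0]))
            coefs = dict(zip(regs, vals))
            psi = float(rng.uniform(BASAL_LOW, BASAL_HIGH))
            if kinds[tgt] == "mirna":
                # keep the numerator non-negative for every source draw
                neg = sum(abs(c) for r, c in coefs.items() if kinds[r] != "mirna" and c < 0)
                psi = max(psi, neg * SOURCE_MAX + 0.5)
        coefficients[tgt] = coefs
        basal[tgt] = psi
    return coefficients, basal


# ---------------------------------------------------------------------------
# public generators

def generate_candidate_gwgen(
    n_proteins: int = 50,
    n_genes: int = 100,
    n_mirnas: int = 20,
    n_lncrnas: int = 5,
    true_density: float = 0.1,
    decoy_ratio: float = 2.0,
    seed: int = 0,
) -> tuple[CandidateGWGEN, GroundTruthModel]:
    """Plant a true GWGEN and bury it in a candidate network with decoys.

    The candidate network contains every true edge plus
    ``round(decoy_ratio * n_true)`` kind-respecting decoys.  Deterministic
    given ``seed``.
    """
    if not 0 < true_density <= 1:
        raise ValueError("true_density must be in (0, 1]")
    if decoy_ratio < 0:
        raise ValueError("decoy_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    layout = _node_layout(n_proteins, n_genes, n_mirnas, n_lncrnas)
    true_edges = _sample_true_edges(layout, true_density, rng)
    decoys = _choose(_decoy_pool(layout, set(true_edges)),
                     round(decoy_ratio * len(true_edges)), rng)
    coefficients, basal = _assign_parameters(layout, true_edges, rng)
    truth = GroundTruthModel(kinds=layout.kinds, coefficients=coefficients,
                             basal=basal, source_ids=layout.source_ids)
    candidate = _edges_to_candidate(layout, true_edges + decoys)
    return candidate, truth


def generate_condition_pair(
    shared_truth_fraction: float = 0.5,
    seed: int = 0,
    n_proteins: int = 50,
    n_genes: int = 100,
    n_mirnas: int = 20,
    n_lncrnas: int = 5,
    true_density: float = 0.1,
    decoy_ratio: float = 2.0,
) -> tuple[CandidateGWGEN, GroundTruthModel, GroundTruthModel]:
    """Two condition-specific truths below one shared candidate network.

    Both conditions have the same number of true edges; exactly
    ``round(shared_truth_fraction * n_edges)`` of them are common.
    Condition-distinctive PPI edges connect two computed target proteins
    (earlier node feeding the later one's equation) so that the other
    condition's identification prunes them exactly.
    """
    if not 0 <= shared_truth_fraction <= 1:
        raise ValueError("shared_truth_fraction must be in [0, 1]")
    if not 0 < true_density <= 1:
        raise ValueError("true_density must be in (0, 1]")
    if decoy_ratio < 0:
        raise ValueError("decoy_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    layout = _node_layout(n_proteins, n_genes, n_mirnas, n_lncrnas)

    base = _sample_true_edges(layout, true_density, rng)
    n_edges = len(base)
    n_common = round(shared_truth_fraction * n_edges)
    n_dist = n_edges - n_common

    # One PPI "anchor" edge per computed protein target must be common to
    # both conditions so the target is non-constant in each (see
    # _sample_true_edges); the shared fraction must leave room for them.
    anchors: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    pt = set(layout.protein_targets)
    for edge in sorted(base):
        kind, a, b = edge
        if kind != "ppi":
            continue
        owner = b if b in pt else a
        if owner not in seen:
            anchors.append(edge)
            seen.add(owner)
    if n_common < len(anchors):
        raise ValueError(
            f"shared_truth_fraction={shared_truth_fraction} yields only "
            f"{n_common} common edges, fewer than the {len(anchors)} anchor "
            "PPI edges needed to keep every computed protein non-constant "
            "in both conditions")
    rest = [e for e in sorted(base) if e not in set(anchors)]
    common = anchors + _choose(rest, n_common - len(anchors), rng)

    pool = _decoy_pool(layout, set(base))
    dist_a = _choose(pool, n_dist, rng)
    pool = [e for e in pool if e not in set(dist_a)]
    dist_b = _choose(pool, n_dist, rng)
    pool = [e for e in pool if e not in set(dist_b)]

    edges_a = sorted(common + dist_a)
    edges_b = sorted(common + dist_b)
    coef_a, basal_a = _assign_parameters(layout, edges_a, rng)
    coef_b, basal_b = _assign_parameters(layout, edges_b, rng)
    truth_a = GroundTruthModel(kinds=layout.kinds, coefficients=coef_a,
                               basal=basal_a, source_ids=layout.source_ids)
    truth_b = GroundTruthModel(kinds=layout.kinds, coefficients=coef_b,
                               basal=basal_b, source_ids=layout.source_ids)
    union = sorted(set(edges_a) | set(edges_b))
    decoys = _choose(pool, round(decoy_ratio * len(union)), rng)
    candidate = _edges_to_candidate(layout, union + decoys)
    return candidate, truth_a, truth_b


def _edges_to_candidate(layout: _Layout,
                        edges: list[tuple[str, str, str]]) -> CandidateGWGEN:
    ppi = {(a, b) for kind, a, b in edges if kind == "ppi"}
    grn = {(s, t) for kind, s, t in edges if kind == "grn"}
    return CandidateGWGEN(kinds=layout.kinds.copy(), ppi=ppi, grn=grn)


# ---------------------------------------------------------------------------
# simulation

def _truncated_lognormal(rng: np.random.Generator, size: int) -> np.ndarray:
    z = rng.normal(0.0, LOG_SCALE, size=size)
    for _ in range(100):
        bad = np.abs(z) > LOG_TRUNC * LOG_SCALE
        if not bad.any():
            break
        z[bad] = rng.normal(0.0, LOG_SCALE, size=int(bad.sum()))
    np.clip(z, -LOG_TRUNC * LOG_SCALE, LOG_TRUNC * LOG_SCALE, out=z)
    return np.exp(z)


def evaluate_model(truth: GroundTruthModel, sources: pd.DataFrame,
                   rng: np.random.Generator | None = None,
                   condition: str | None = None) -> ExpressionDataset:
    """Compute every target node from given source samples via the closed
    forms of the generating equations; draw noise from ``rng`` if the truth
    has ``noise_sd > 0``.

    Computed protein targets may themselves feed later protein targets, so
    proteins are evaluated in lexicographic (DAG) order.
    """
    n = sources.shape[1]
    sd = truth.noise_sd
    if sd > 0 and rng is None:
        raise ValueError("an rng is required when noise_sd > 0")
    values: dict[str, np.ndarray] = {s: sources.loc[s].to_numpy(dtype=float)
                                     for s in sources.index}
    kinds = truth.kinds
    targets = sorted(set(truth.coefficients) | set(truth.basal))
    protein_targets = [t for t in targets if kinds[t] in PROTEIN_KINDS]
    other_targets = [t for t in targets if kinds[t] not in PROTEIN_KINDS]

    for tgt in protein_targets:  # lexicographic order respects the DAG
        coefs = truth.coefficients.get(tgt, {})
        theta = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        denom = np.ones(n)
        for src, lam in sorted(coefs.items()):
            if src not in values:
                raise ValueError(f"regulator {src!r} of {tgt!r} not yet computed")
            denom = denom - lam * values[src]
        if np.min(np.abs(denom)) < STABILITY_FLOOR:
            raise RuntimeError(
                f"protein equation for {tgt!r} is near-singular "
                f"(min |1 - sum(lambda*p)| = {np.min(np.abs(denom)):.3g})")
        values[tgt] = (truth.basal[tgt] + theta) / denom

    for tgt in other_targets:
        coefs = truth.coefficients.get(tgt, {})
        theta = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        num = np.full(n, truth.basal[tgt], dtype=float)
        denom = np.ones(n)
        for src, c in sorted(coefs.items()):
            if kinds[src] == "mirna":
                denom = denom + (-c) * values[src]  # c = −γ ≤ 0
            else:
                num = num + c * values[src]
        if kinds[tgt] == "mirna" and sd > 0:
            # keep miRNA expression non-negative: redraw offending noise
            for _ in range(1000):
                bad = (num + theta) < 0
                if not bad.any():
                    break
                theta[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
            if ((num + theta) < 0).any():
                raise RuntimeError(
                    f"could not keep miRNA target {tgt!r} non-negative; "
                    "noise_sd is too large for its basal level")
        values[tgt] = (num + theta) / denom

    all_ids = sorted(set(kinds.index))
    missing = [i for i in all_ids if i not in values]
    if missing:
        raise ValueError(f"nodes with neither source draw nor equation: {missing[:5]}")
    mat = pd.DataFrame({c: [values[i][j] for i in all_ids] for j, c in
                        enumerate(f"S{j:04d}" for j in range(n))}, index=all_ids)
    return ExpressionDataset(values=mat, kinds=kinds.copy(), condition=condition)


def simulate_expression(truth: GroundTruthModel, n_samples: int, seed: int = 0,
                        condition: str | None = None) -> ExpressionDataset:
    """Draw source samples and evaluate all target equations.

    The returned dataset satisfies each generating equation exactly up to
    the drawn noise term; at ``noise_sd == 0`` refitting every equation
    yields zero residual.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    src_ids = sorted(truth.source_ids)
    sources = pd.DataFrame(
        {f"S{j:04d}": np.empty(len(src_ids)) for j in range(n_samples)},
        index=src_ids)
    for sid in src_ids:
        sources.loc[sid] = _truncated_lognormal(rng, n_samples)
    return evaluate_model(truth, sources, rng=rng, condition=condition)


def signal_sd(dataset: ExpressionDataset) -> float:
    """Standard deviation of all expression values (the 'signal scale' used
    to set relative noise levels)."""
    return float(np.std(dataset.values.to_numpy()))


# ---------------------------------------------------------------------------
# drug-catalog fixture

def make_drug_catalog_fixture(targets: list[str], seed: int = 0,
                              directions: dict[str, str] | None = None) -> pd.DataFrame:
    """Deterministic drug catalog exercising both drug filters.

    For every target the catalog contains a drug passing both filters, one
    failing the sign rule, one failing the |score| threshold and one failing
    the LD50 bound (at the default thresholds 0.5 / 500 mg/kg).  One
    broad-spectrum compound covers all targets with a strong
    signature-reversing score, so the greedy set cover selects exactly it.

    ``directions`` maps targets to 'up'/'down' (default: all 'up'); passing
    drugs score negatively for upregulated targets and positively for
    downregulated ones.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    rng = np.random.default_rng(seed)
    directions = directions or {}
    rows = []
    for tgt in sorted(set(targets)):
        rev = -1.0 if directions.get(tgt, "up") == "up" else 1.0
        jit = rng.uniform(0.0, 0.04, size=4)
        rows.append(("PanReverser", tgt, rev * (0.85 + jit[0]), 1200.0))
        rows.append((f"Mono-{tgt}", tgt, rev * (0.78 + jit[1]), 700.0))
        rows.append((f"WrongWay-{tgt}", tgt, -rev * (0.70 + jit[2]), 900.0))
        rows.append((f"Toxic-{tgt}", tgt, rev * (0.90 + jit[3]), 40.0))
        rows.append(("WeakAll", tgt, rev * 0.20, 1000.0))
    cat = pd.DataFrame(rows, columns=["drug", "target", "connectivity_score",
                                      "ld50_mg_per_kg"])
    return cat.sort_values(["drug", "target"], ignore_index=True)
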