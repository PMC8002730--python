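"""End-to-end orchestration: simulate → cap → identify → project → compare
→ filter drugs, with a JSON manifest for provenance.

Every stage writes its artifact as TSV/JSON so that each output is a valid
input to the next stage's reader, and a rerun with the same configuration
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .comparison import compare_cores, direction_labels
from .datatypes import GroundTruthModel
from .drug_design import (
    DEFAULT_MIN_ABS_SCORE,
    DEFAULT_MIN_LD50,
    design_drugs,
)
from .identification import DEFAULT_LOG_BASE, DEFAULT_VARIANCE_FLOOR, identify_gwgen
from .netio import (
    apply_degree_cap,
    read_drug_catalog,
    write_drug_catalog,
    write_expression,
    write_identified_network,
    write_network,
)
from .pnp import (
    DEFAULT_ENERGY_THRESHOLD,
    DEFAULT_TOP_K,
    extract_core,
    principal_network_projection,
)
from .synthetic import (
    generate_condition_pair,
    make_drug_catalog_fixture,
    simulate_expression,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Knobs of the synthetic two-condition study."""

    outdir: str = "gwgen_run"
    seed: int = 0
    n_proteins: int = 50
    n_genes: int = 100
    n_mirnas: int = 20
    n_lncrnas: int = 5
    true_density: float = 0.1
    decoy_ratio: float = 2.0
    shared_truth_fraction: float = 0.5
    n_samples: int = 80
    noise_sd: float = 0.0
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD
    top_k: int = DEFAULT_TOP_K
    aic_variance_floor: float = DEFAULT_VARIANCE_FLOOR
    aic_log_base: float = DEFAULT_LOG_BASE
    min_abs_score: float = DEFAULT_MIN_ABS_SCORE
    min_ld50: float = DEFAULT_MIN_LD50
    n_biomarkers: int = 5
    biomarkers: list[str] | None = None
    catalog_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.energy_threshold <= 1:
            raise ValueError("energy_threshold must be in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if not 0 <= self.min_abs_score <= 1:
            raise ValueError("min_abs_score must be in [0, 1]")
        if self.min_ld50 < 0:
            raise ValueError("min_ld50 must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole synthetic study; returns the manifest dictionary.

    Output files (all under ``config.outdir``): candidate network with
    planted-truth flags, per-condition expression, identified networks,
    projection scores, core networks, a comparison report and the filtered
    multi-molecule drug proposal, plus ``manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    candidate, truth_a, truth_b = generate_condition_pair(
        shared_truth_fraction=config.shared_truth_fraction, seed=config.seed,
        n_proteins=config.n_proteins, n_genes=config.n_genes,
        n_mirnas=config.n_mirnas, n_lncrnas=config.n_lncrnas,
        true_density=config.true_density, decoy_ratio=config.decoy_ratio)
    truth_a = truth_a.with_noise(config.noise_sd)
    truth_b = truth_b.with_noise(config.noise_sd)
    data = {
        "a": simulate_expression(truth_a, config.n_samples, seed=config.seed + 1,
                                 condition="a"),
        "b": simulate_expression(truth_b, config.n_samples, seed=config.seed + 2,
                                 condition="b"),
    }
    write_network(candidate, out / "candidate_network.tsv")
    write_network(candidate, out / "truth_a.tsv", truth=truth_a)
    write_network(candidate, out / "truth_b.tsv", truth=truth_b)

    cores = {}
    for cond in ("a", "b"):
        write_expression(data[cond], out / f"expression_{cond}.tsv")
        capped = apply_degree_cap(candidate, data[cond])
        real = identify_gwgen(capped, data[cond],
                              variance_floor=config.aic_variance_floor,
                              log_base=config.aic_log_base)
        write_identified_network(real, out / f"identified_{cond}.tsv")
        result = principal_network_projection(real, threshold=config.energy_threshold)
        core = extract_core(real, result, top_k=config.top_k)
        core.nodes.to_csv(out / f"core_{cond}_nodes.tsv", sep="\t",
                          float_format=_FLOAT_FMT)
        core.edges.to_csv(out / f"core_{cond}_edges.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FMT)
        cores[cond] = core
        logger.info("condition %s: %d identified edges, core of %d nodes "
                    "(rank %d)", cond, real.n_edges, len(core.nodes), result.rank)

    report = compare_cores(cores["a"], cores["b"])
    labels = direction_labels(cores["a"], data["a"], data["b"])
    (out / "comparison.json").write_text(
        json.dumps({**report.to_dict(), "directions": labels},
                   indent=2, sort_keys=True) + "\n")
    node_rows = []
    for node in sorted(cores["a"].node_set | cores["b"].node_set):
        member = ("common" if node in report.common_nodes
                  else "a" if node in report.only_a_nodes else "b")
        node_rows.append({"node_id": node, "membership": member,
                          "direction": labels.get(node, "unknown")})
    pd.DataFrame(node_rows).to_csv(out / "comparison_nodes.tsv", sep="\t", index=False)

    if config.biomarkers:
        biomarkers = list(config.biomarkers)
    else:
        genes = cores["a"].nodes[cores["a"].nodes["kind"] == "gene"]
        biomarkers = list(genes.index[:config.n_biomarkers])
    signature = {b: labels.get(b, "up") for b in biomarkers}
    if config.catalog_path:
        catalog = read_drug_catalog(config.catalog_path)
    else:
        catalog = make_drug_catalog_fixture(biomarkers, seed=config.seed + 3,
                                            directions=signature)
        write_drug_catalog(catalog, out / "drug_catalog.csv")
    proposal = design_drugs(catalog, signature,
                            min_abs_score=config.min_abs_score,
                            min_ld50=config.min_ld50)
    proposal.records.to_csv(out / "drug_proposal.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
    proposal.coverage.to_csv(out / "drug_coverage.tsv", sep="\t")

    artifacts = sorted(p.name for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": {"name": "gwgen", "version": __version__},
        "libraries": {"numpy": np.__version__, "scipy": scipy.__version__,
                      "pandas": pd.__version__},
        "config": config.to_dict(),
        "signature": signature,
        "selected_drugs": proposal.drugs,
        "uncovered_targets": proposal.uncovered,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
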