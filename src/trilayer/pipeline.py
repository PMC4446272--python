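"""Pipeline configuration and orchestration.

Runs, per timepoint: differential expression -> preranked enrichment on
the forward and reversed t-ranking -> direction classification ->
regulon enrichment and clustering -> phenotype correlation -> layered
network assembly and topology.  Every stage result is written as plain
TSV (plus GraphML/SIF for the network) under ``out_dir/<timepoint>/``,
and a run manifest with parameters, versions and output checksums is
written at the root.  Given a config and seed the run is bit-for-bit
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .diffexpr import ExpressionMatrix, moderated_ttest
from .gsea import GseaConfig, classify_direction, gsea_preranked, rank_genes
from .netbuild import (
    NetworkConfig,
    build_network,
    physiology_layer,
    process_layer,
    regulator_layer,
    topology_stats,
)
from .physiology import correlate_parameters
from .regulators import cluster_regulators, regulon_enrichment

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression: str
    samples: str
    process_gmt: str
    regulon_gmt: str
    physiology: str
    out_dir: str
    timepoints: list | None = None  # default: every timepoint in samples
    prior_df: float = 4.0
    de_fdr_cutoff: float = 0.05
    min_size: int = 15
    max_size: int = 500
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.05
    rho_cutoff: float = 0.8
    similarity_method: str = "overlap"
    coefficient_cutoff: float = 0.5
    physiology_process_cutoff: float = 0.3
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def validate_paths(self) -> None:
        for key in ("expression", "samples", "process_gmt", "regulon_gmt", "physiology"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"{key} file not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(base: int, index: int) -> int:
    return (base * 1000003 + index) % (2**31 - 1)


def write_regulator_table(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["de_targets"] = [";".join(t) for t in out["de_targets"]]
    out.to_csv(path, sep="\t", index=False)


def read_regulator_table(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t")
    out["de_targets"] = [
        tuple(t.split(";")) if isinstance(t, str) and t else ()
        for t in out["de_targets"]
    ]
    return out


def run_timepoint(
    expr: ExpressionMatrix,
    processes: dict,
    regulons: dict,
    physio: pd.DataFrame,
    cfg: PipelineConfig,
    seed_offset: int = 0,
) -> dict:
    """All five stages for one timepoint's expression matrix (in memory)."""
    t0 = time.perf_counter()
    de = moderated_ttest(expr, prior_df=cfg.prior_df)
    n_de = int((de["fdr"] < cfg.de_fdr_cutoff).sum())
    log.info("de: %d genes tested, %d at FDR<%g", len(de), n_de, cfg.de_fdr_cutoff)

    ranked = rank_genes(de)
    gsea_cfg = GseaConfig(
        min_size=cfg.min_size,
        max_size=cfg.max_size,
        weight_exponent=cfg.weight_exponent,
        n_permutations=cfg.n_permutations,
        seed=_stage_seed(cfg.seed, seed_offset),
        statistic="pos",
    )
    fwd = gsea_preranked(ranked, processes, gsea_cfg)
    rev = gsea_preranked(
        ranked.reversed(),
        processes,
        dataclasses.replace(gsea_cfg, seed=_stage_seed(cfg.seed, seed_offset + 1)),
    )
    classified = classify_direction(fwd, rev, alpha=cfg.alpha)
    log.info(
        "gsea: %d sets, %d significant at p<%g",
        len(classified), int(classified["significant"].sum()), cfg.alpha,
    )

    regs = cluster_regulators(
        regulon_enrichment(de, regulons, fdr_cutoff=cfg.de_fdr_cutoff, alpha=cfg.alpha)
    )
    corr = correlate_parameters(
        expr, physio, rho_cutoff=cfg.rho_cutoff, alpha=cfg.alpha
    )
    log.info(
        "physiology: %d linked parameters, %d gene links",
        corr["parameter"].nunique(), len(corr),
    )

    net_cfg = NetworkConfig(
        node_p_cutoff=cfg.alpha,
        coefficient_cutoff=cfg.coefficient_cutoff,
        physiology_process_cutoff=cfg.physiology_process_cutoff,
        similarity_method=cfg.similarity_method,
    )
    net = build_network(
        process_layer(classified, processes, de.index, p_cutoff=cfg.alpha),
        regulator_layer(regs, p_cutoff=cfg.alpha),
        physiology_layer(corr),
        net_cfg,
    )
    topo, summary = (
        topology_stats(net) if net.number_of_nodes() else (pd.DataFrame(), {})
    )
    log.info("timepoint done in %.1fs", time.perf_counter() - t0)
    return {
        "de": de,
        "enrichment": classified,
        "regulators": regs,
        "physiology": corr,
        "network": net,
        "topology": topo,
        "summary": summary,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline from files per the config; write outputs.

    Returns ``{timepoint: stage-result dict}``; every table is also
    written under ``out_dir/<timepoint>/`` along with GraphML/SIF
    exports and a deterministic ``manifest.json`` at the root.
    """
    logging.getLogger("trilayer").setLevel(cfg.log_level)
    cfg.validate_paths()
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    expression = tio.read_expression(cfg.expression)
    samples = tio.read_samples(cfg.samples)
    em_all = ExpressionMatrix(expression, samples)
    processes = tio.read_gmt(cfg.process_gmt)
    regulons = tio.read_gmt(cfg.regulon_gmt)
    physio_all = tio.read_physiology(cfg.physiology)
    timepoints = cfg.timepoints or em_all.timepoints()

    results: dict[str, dict] = {}
    outputs: list[Path] = []
    for idx, tp in enumerate(timepoints):
        log.info("=== timepoint %s ===", tp)
        em = em_all.subset(tp)
        if "timepoint" in physio_all.columns:
            physio = physio_all[physio_all["timepoint"] == tp].drop(
                columns="timepoint"
            )
        else:
            physio = physio_all
        res = run_timepoint(
            em, processes, regulons, physio, cfg, seed_offset=2 * idx
        )
        results[tp] = res

        tp_dir = out_root / tp
        tp_dir.mkdir(exist_ok=True)
        res["de"].to_csv(tp_dir / "de.tsv", sep="\t", index_label="gene")
        res["enrichment"].to_csv(tp_dir / "enrichment.tsv", sep="\t", index=False)
        write_regulator_table(res["regulators"], tp_dir / "regulators.tsv")
        res["physiology"].to_csv(
            tp_dir / "physiology_correlations.tsv", sep="\t", index=False
        )
        tio.export_network(res["network"], "graphml", tp_dir / "network.graphml")
        tio.export_network(res["network"], "sif", tp_dir / "network.sif")
        tio.export_network(res["network"], "tsv", tp_dir / "network_edges.tsv")
        res["topology"].to_csv(tp_dir / "topology.tsv", sep="\t", index=False)
        outputs += sorted(tp_dir.iterdir())

    manifest = {
        "trilayer_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "timepoints": list(timepoints),
        "checksums": {
            str(p.relative_to(out_root)): _sha256(p) for p in outputs
        },
    }
    (out_root / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return results
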