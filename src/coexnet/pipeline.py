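"""End-to-end orchestration: ingest -> network -> modules -> interpretation.

``run_pipeline`` drives every stage from a single config, writes all
artifacts under an output directory, and records a manifest (parameters,
package version, input hashes, chosen beta, QC warnings) sufficient to
reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd

from coexnet import export, ingest, interpret, modules, netcore
from coexnet.types import CountMatrix, ModulePartition

log = logging.getLogger("coexnet")


def _pkg_version() -> str:
    import coexnet

    return coexnet.__version__


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; defaults are the standard ones.

    ``beta=None`` selects the soft threshold from the scale-free
    criterion over ``beta_grid``; a fixed integer skips the sweep.
    """

    counts_path: str | None = None
    meta_path: str | None = None
    annotation_path: str | None = None
    external_clustering_path: str | None = None
    out_dir: str = "results/pipeline"

    beta: int | None = 12
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    target_r2: float = 0.9
    mode: str = "unsigned"
    n_bins: int = 10
    min_module_size: int = 40
    merge_cut_height: float = 0.25
    edge_threshold: float = 0.20
    p_weak: float = 0.05
    p_strong: float = 1e-5
    median_threshold: float = 10
    outlier_z: float = -2.5
    n_perm: int = 999
    seed: int = 0
    log_level: str = "INFO"


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    expression: Any
    correlation: Any
    adjacency: Any
    tom: Any
    dendrogram: Any
    partition_unmerged: ModulePartition
    partition: ModulePartition
    eigengenes: Any
    scale_free: Any
    enrichment: Any = None
    concordance: Any = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    cfg: PipelineConfig,
    counts: CountMatrix | None = None,
    annotations: interpret.AnnotationTable | None = None,
    external: interpret.ExternalClustering | None = None,
) -> PipelineResult:
    """Execute the full analysis and write artifacts + manifest.

    Inputs may be given in memory (``counts`` etc.) or as paths in the
    config. Any stage failure aborts with the stage name in the message.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": _pkg_version(),
        "parameters": asdict(cfg),
        "input_hashes": {},
        "warnings": [],
    }

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("ingest")
        if counts is None:
            counts = ingest.read_counts(cfg.counts_path, cfg.meta_path)
            manifest["input_hashes"]["counts"] = _hash_file(cfg.counts_path)
            manifest["input_hashes"]["meta"] = _hash_file(cfg.meta_path)
        em = ingest.normalize(
            counts, median_threshold=cfg.median_threshold, outlier_z=cfg.outlier_z
        )
        manifest["qc_report"] = {
            k: v for k, v in em.qc_report.items() if k != "removed_genes"
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'ingest' failed: {exc}") from exc

    try:
        stage("network")
        r = netcore.correlation_matrix(em)
        if r.fallback_genes:
            manifest["warnings"].append(
                f"{len(r.fallback_genes)} genes used median-centered Pearson fallback"
            )
        if cfg.beta is None:
            sft = netcore.pick_soft_threshold(
                r, cfg.beta_grid, target_r2=cfg.target_r2, mode=cfg.mode, n_bins=cfg.n_bins
            )
            beta = sft.chosen_beta
            if not sft.reached_target:
                manifest["warnings"].append(
                    f"no beta reached R^2 >= {cfg.target_r2}; using max-R^2 beta {beta}"
                )
        else:
            beta = int(cfg.beta)
            sft = None
        a = netcore.adjacency(r, beta=beta, mode=cfg.mode)
        k = netcore.connectivity(a)
        r2, slope = netcore.scale_free_fit(k.to_numpy(), n_bins=cfg.n_bins)
        manifest["chosen_beta"] = beta
        manifest["scale_free_r_squared"] = r2
        manifest["scale_free_slope"] = slope
        t = netcore.tom(a)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'network' failed: {exc}") from exc

    try:
        stage("modules")
        dend = modules.average_linkage(t.diss)
        part0 = modules.dynamic_tree_cut(
            dend, t.diss, min_module_size=cfg.min_module_size
        )
        if part0.n_modules == 0:
            manifest["warnings"].append("no modules detected; all genes grey")
            part, eg = part0, None
        else:
            part, eg = modules.merge_modules(
                part0, em, merge_cut_height=cfg.merge_cut_height
            )
        manifest["n_modules_unmerged"] = part0.n_modules
        manifest["n_modules_merged"] = part.n_modules
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'modules' failed: {exc}") from exc

    enrichment = concordance = None
    try:
        stage("interpret")
        if annotations is None and cfg.annotation_path:
            feats = pd.read_csv(cfg.annotation_path, sep="\t", index_col=0).astype(bool)
            annotations = interpret.AnnotationTable(features=feats)
            manifest["input_hashes"]["annotations"] = _hash_file(cfg.annotation_path)
        if external is None and cfg.external_clustering_path:
            ext_df = pd.read_csv(cfg.external_clustering_path, sep="\t", index_col=0)
            external = interpret.ExternalClustering(labels=ext_df.iloc[:, 0])
            manifest["input_hashes"]["external"] = _hash_file(
                cfg.external_clustering_path
            )
        if annotations is not None and part.n_modules > 0:
            enrichment = interpret.score_conditions(part, annotations)
        if external is not None and part.n_modules > 0:
            concordance = interpret.concordance_null(
                part, external, n_perm=cfg.n_perm, seed=cfg.seed
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'interpret' failed: {exc}") from exc

    try:
        stage("export")
        export.write_expression(em, out / "expression.tsv")
        export.write_partition(part0, out / "modules_unmerged.tsv")
        export.write_partition(part, out / "modules_merged.tsv")
        if eg is not None:
            export.write_eigengenes(eg, out / "eigengenes.tsv")
        (out / "dendrogram.nwk").write_text(export.to_newick(dend))
        if sft is not None:
            export.write_table(sft.table, out / "soft_threshold_sweep.tsv")
        for mod in part.modules:
            edges, nodes = export.export_edge_list(
                r, part, mod, threshold=cfg.edge_threshold
            )
            edges.to_csv(out / f"edges_{mod}.tsv", sep="\t", index=False,
                         float_format=export.FLOAT_FMT)
        if enrichment is not None:
            export.write_table(enrichment.scores, out / "enrichment_scores.tsv")
            enrichment.detail.to_csv(
                out / "enrichment_detail.tsv", sep="\t", index=False,
                float_format=export.FLOAT_FMT,
            )
        if concordance is not None:
            (out / "concordance.json").write_text(
                json.dumps(concordance.to_dict(), indent=2)
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'export' failed: {exc}") from exc

    return PipelineResult(
        expression=em,
        correlation=r,
        adjacency=a,
        tom=t,
        dendrogram=dend,
        partition_unmerged=part0,
        partition=part,
        eigengenes=eg,
        scale_free=(r2, slope),
        enrichment=enrichment,
        concordance=concordance,
        manifest=manifest,
    )
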