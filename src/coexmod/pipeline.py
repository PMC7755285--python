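"""End-to-end orchestration of the co-expression analysis.

Stages, in order: gene filter → log transform → soft-power selection →
adjacency → TOM → average-linkage clustering → tree cut → eigengene merge →
color naming → target-module selection → kME/connectivity statistics → hub
screen → enrichment → term intersection.  Every stage logs its parameters
and dimensions; all outputs are TSV plus a JSON manifest with SHA-256
checksums, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import data_io, enrichment, hubs, modules, network
from .data_io import ExpressionMatrix

log = logging.getLogger("coexmod")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one flat record.

    ``expression`` / ``sample_sheet`` point at the input tables.  The target
    sample set for module selection is either ``target_samples`` (explicit
    ids) or the samples of the last ``target_n_stages`` stages by stage_day.
    GMT inputs are (path, namespace) pairs.
    """

    expression: str
    sample_sheet: str | None = None
    out_dir: str = "coexmod_out"
    # gene filter
    min_value: float = 1.0
    min_fraction: float = 0.5
    min_mad: float = 0.0
    # transform
    log2: bool = True
    # network
    power: int | str = "auto"
    network_type: str = "unsigned"
    r2_cut: float = 0.8
    block_size: int = network.DEFAULT_BLOCK_SIZE
    # module detection
    min_module_size: int = 50
    merge_similarity: float = 0.85
    cut_method: str = "dynamic_hybrid"
    cut_height: float = 0.995
    deep_split: int = 2
    # target module + hub screen
    target_samples: list[str] = field(default_factory=list)
    target_n_stages: int = 2
    k_min: float = 900.0
    kme_min: float = 0.9
    k_quantile: float | None = None
    # enrichment
    gmt_files: list[tuple[str, str]] = field(default_factory=list)
    select_go: list[str] = field(default_factory=list)
    select_pathway: list[str] = field(default_factory=list)
    pathway_min: int = 3
    alpha: float = 0.05
    seed: int = 0


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _target_sample_set(cfg: PipelineConfig, x: ExpressionMatrix) -> list[str]:
    if cfg.target_samples:
        return list(cfg.target_samples)
    days = x.sample_meta["stage_day"]
    if days.isna().any():
        raise PipelineError(
            "target-module stage: no target_samples given and stage_day metadata "
            "is incomplete"
        )
    last = sorted(days.unique())[-cfg.target_n_stages:]
    return list(days.index[days.isin(last)])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {}, "files": {}}

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        log.info("%s: %s", name, ", ".join(f"{k}={v}" for k, v in info.items()))

    try:
        x = data_io.read_expression(cfg.expression, sample_sheet=cfg.sample_sheet)
        stage("read", genes=x.shape[0], samples=x.shape[1])

        x, rec = data_io.filter_genes(x, cfg.min_value, cfg.min_fraction, cfg.min_mad)
        stage("filter", kept=rec.n_kept, dropped=rec.n_dropped)
        if cfg.log2:
            x = data_io.log_transform(x)
            stage("log_transform", base=2, pseudocount=1)

        if cfg.power == "auto":
            power, fit_table = network.pick_soft_threshold(
                x, r2_cut=cfg.r2_cut, network_type=cfg.network_type,
                block_size=cfg.block_size,
            )
            fit_path = os.path.join(cfg.out_dir, "scale_free_fit.tsv")
            fit_table.to_csv(fit_path, sep="\t", index=False, float_format="%.6g")
            manifest["files"]["scale_free_fit"] = fit_path
            flagged = bool(fit_table["plateau_fallback"].any())
            stage("pick_power", power=power, plateau_fallback=flagged)
        else:
            power = int(cfg.power)
            stage("pick_power", power=power, plateau_fallback=False)

        corr = network.correlation_matrix(x, block_size=cfg.block_size)
        adj = network.soft_adjacency(corr, power, cfg.network_type)
        k = network.connectivity(adj)
        tom = network.tom_similarity(adj, block_size=cfg.block_size)
        stage("network", power=power, type=cfg.network_type, genes=len(tom.gene_ids))

        dissim = 1.0 - tom.values
        np.fill_diagonal(dissim, 0.0)
        dend = modules.average_linkage_cluster(dissim, tom.gene_ids)
        part = modules.cut_tree(
            dend, dissim, min_size=cfg.min_module_size, method=cfg.cut_method,
            cut_height=cfg.cut_height, deep_split=cfg.deep_split,
        )
        stage("cut_tree", modules=len(part.labels),
              unassigned=sum(m == modules.UNASSIGNED for m in part.assignment.values()))

        part, me = modules.merge_close_modules(x, part, cfg.merge_similarity)
        part = modules.assign_colors(part)
        me.values.columns = [part.colors[m] for m in me.values.columns]
        sizes = part.sizes()
        stage("merge_modules", modules=len(part.labels),
              sizes={part.colors[m]: int(sizes[m]) for m in sizes.index})

        targets = _target_sample_set(cfg, x)
        target_module, ranking = hubs.select_target_module(me, targets)
        stage("target_module", module=target_module, n_target_samples=len(targets))

        stats = hubs.kme_with_p(x, me)
        stats.connectivity = k
        stats.module = pd.Series(
            {g: part.colors[m] for g, m in part.assignment.items()}, name="module"
        ).loc[stats.kme.index]
        screen = hubs.screen_hubs(
            stats, target_module, k_min=cfg.k_min, kme_min=cfg.kme_min,
            k_quantile=cfg.k_quantile,
        )
        stage("hub_screen", module=target_module, k_threshold=screen.k_threshold,
              kme_threshold=screen.kme_threshold, **screen.venn_counts())

        enr_table = None
        intersection = None
        readable = [(p, ns) for p, ns in cfg.gmt_files if os.path.exists(p)]
        missing = [p for p, _ in cfg.gmt_files if not os.path.exists(p)]
        if missing:
            log.warning("enrichment: missing GMT file(s) %s", missing)
        if readable and screen.hubs:
            ann = data_io.AnnotationSet({})
            for path, ns in readable:
                ann.update(data_io.read_gmt(path, namespace=ns))
            universe = set(x.gene_ids)
            enr = enrichment.hypergeom_enrich(screen.hubs, ann, universe, cfg.alpha)
            enr_table = enr.table
            stage("enrichment", terms=len(enr_table),
                  significant=int((enr_table["adjusted_p"] <= cfg.alpha).sum()))
            if cfg.select_go or cfg.select_pathway:
                report = enrichment.intersect_terms(
                    enr, cfg.select_go, cfg.select_pathway, cfg.pathway_min
                )
                intersection = report
                stage("intersection", final_genes=report.final_genes)
        elif cfg.gmt_files:
            stage("enrichment", skipped=True)

        written = data_io.write_results(
            part, me, stats.to_frame(), screen, enr_table, cfg.out_dir
        )
        if intersection is not None:
            ipath = os.path.join(cfg.out_dir, "intersection.tsv")
            intersection.gene_term_counts.assign(
                nominated=[g in intersection.final_genes
                           for g in intersection.gene_term_counts.index]
            ).to_csv(ipath, sep="\t")
            written["intersection"] = ipath
        rpath = os.path.join(cfg.out_dir, "target_module_ranking.tsv")
        ranking.to_csv(rpath, sep="\t", index=False, float_format="%.6g")
        written["target_module_ranking"] = rpath
        manifest["files"].update(written)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage name context
        done = list(manifest["stages"])
        stage_name = done[-1] if done else "read"
        raise PipelineError(f"pipeline failed after stage {stage_name!r}: {e}") from e

    manifest["files"] = {
        name: {"path": p, "sha256": _sha256(p)} for name, p in manifest["files"].items()
    }
    mpath = os.path.join(cfg.out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
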