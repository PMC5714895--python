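"""End-to-end orchestration: normalize -> DE -> cluster -> infer -> consensus.

A single :class:`PipelineConfig` (loadable from YAML) names the inputs and
all stage settings.  One global seed is expanded into per-stage seeds by a
fixed counter scheme, ``stage_seed = (global_seed * 100 + offset) % 2**31``
with documented offsets, so stages are reproducible yet statistically
independent.  Every run writes a manifest (seeds, input hashes, stage
timings) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .clustering import ClusteringConfig, fit_fixed_k, select_k, transform_profiles
from .consensus import (
    ConsensusConfig,
    add_membership_edges,
    call_edges,
    classify_edges,
    export_network,
    network_summary,
)
from .diffexp import (
    DEThresholds,
    de_tf_set,
    de_union,
    export_de_tables,
    import_de_tables,
    run_all_contrasts,
)
from .enrichment import enrich_modules
from .expression_io import (
    ExpressionMatrix,
    average_replicates,
    fpkm,
    load_annotation,
    normalize_counts,
    read_counts_with_design,
    read_design,
    write_matrix,
)
from .inference import METHODS, build_regulator_module_matrix, run_all_methods
from .validation import overlap_counts, read_ortholog_map, read_reference_network

STAGE_SEED_OFFSETS = {"cluster": 1, "genie3": 2, "tigress": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 100 + STAGE_SEED_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    counts: str = ""
    design: str = ""
    lengths: str = ""
    tfs: str = ""
    go_map: str = ""
    de_tables: str = ""  # optional import path bypassing the internal DE test
    ref_network: str = ""  # optional validation inputs
    orthologs: str = ""
    outdir: str = "modnet_out"
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    de: DEThresholds = field(default_factory=DEThresholds)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    fixed_k: int | None = None
    enrichment_background: str = "all_annotated"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("de", DEThresholds), ("clustering", ClusteringConfig), ("consensus", ConsensusConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in STAGE_SEED_OFFSETS},
        "config": cfg.to_dict(),
        "inputs": {},
        "timings_s": {},
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))

    def timed(stage: str):
        t0 = time.perf_counter()

        def done() -> None:
            manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        return done

    try:
        for name in ("counts", "design", "lengths", "tfs", "go_map"):
            p = getattr(cfg, name)
            if p:
                manifest["inputs"][name] = {"path": p, "sha256_16": _hash_file(p)}
        # --- normalize
        done = timed("normalize")
        design = read_design(cfg.design)
        em = read_counts_with_design(cfg.counts, design)
        ann = load_annotation(cfg.tfs or None, cfg.go_map or None, cfg.lengths or None)
        norm = normalize_counts(em)
        fpkm_m = fpkm(em, ann)
        fpkm_avg = average_replicates(fpkm_m, design)
        write_matrix(fpkm_avg, outdir / "fpkm_avg.tsv", float_format="%.6g")
        done()

        # --- differential expression
        done = timed("de")
        if cfg.de_tables:
            tables = import_de_tables(cfg.de_tables, design, cfg.de)
        else:
            tables = run_all_contrasts(norm, design, cfg.de)
        export_de_tables(tables, outdir / "de_tables.tsv")
        union = de_union(tables)
        tfs_de = de_tf_set(tables, ann)
        (outdir / "de_union.txt").write_text("\n".join(sorted(union)) + "\n")
        (outdir / "de_tfs.txt").write_text("\n".join(sorted(tfs_de)) + "\n")
        if not union:
            raise RuntimeError("no differentially expressed genes; nothing to cluster")
        done()

        # --- clustering
        done = timed("cluster")
        de_expr = ExpressionMatrix(fpkm_avg.data.loc[sorted(union)], scale=fpkm_avg.scale)
        X = transform_profiles(de_expr, cfg.clustering.input_transform)
        cl_seed = stage_seed(cfg.seed, "cluster")
        if cfg.fixed_k:
            ms = fit_fixed_k(X, cfg.fixed_k, seed=cl_seed, n_restarts=cfg.clustering.n_restarts)
        else:
            cl_cfg = ClusteringConfig(
                k_grid=cfg.clustering.k_grid,
                n_restarts=cfg.clustering.n_restarts,
                max_iter=cfg.clustering.max_iter,
                seed=cl_seed,
                input_transform=cfg.clustering.input_transform,
            )
            ms = select_k(X, cl_cfg)
        ms.assignment.rename("module_id").to_csv(outdir / "modules.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame(
            {"k": list(ms.bic_by_k), "bic": list(ms.bic_by_k.values())}
        ).to_csv(outdir / "bic.tsv", sep="\t", index=False)
        done()

        # --- regulator-module matrix + inference
        done = timed("infer")
        tf_expr = X.loc[[g for g in sorted(tfs_de) if g in X.index]]
        M = build_regulator_module_matrix(tf_expr, ms.module_means)
        M.data.to_csv(outdir / "rm_matrix.tsv", sep="\t", index_label="row_id")
        scores = run_all_methods(
            M,
            methods=cfg.methods,
            seed=stage_seed(cfg.seed, "genie3"),
        )
        scores_dir = outdir / "scores"
        scores_dir.mkdir(exist_ok=True)
        for name, sm in scores.items():
            sm.long().to_csv(scores_dir / f"{name}.tsv", sep="\t", index=False)
        done()

        # --- consensus + classification
        done = timed("consensus")
        net = call_edges(list(scores.values()), cfg.consensus)
        net = add_membership_edges(net, ms)
        net = classify_edges(net, tables, design)
        export_network(net, outdir / "network.tsv", fmt="tsv_edgelist")
        export_network(net, outdir / "network.graphml", fmt="graphml")
        summary = network_summary(net)
        done()

        # --- enrichment
        done = timed("enrich")
        if ann.go_map:
            enr = enrich_modules(ms, ann, cfg.enrichment_background, cfg.de.enrichment_alpha)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        done()

        # --- optional validation against a reference network
        if cfg.ref_network and cfg.orthologs:
            done = timed("validate")
            ref = read_reference_network(cfg.ref_network)
            om = read_ortholog_map(cfg.orthologs)
            report = overlap_counts(net, ms, ref, om)
            report.matched_edges.to_csv(outdir / "overlap_edges.tsv", sep="\t", index=False)
            summary["validation"] = {
                "tf_module_overlaps": report.tf_module_overlaps,
                "tf_gene_overlaps": report.tf_gene_overlaps,
                "tf_gene_overlaps_ref_space": report.tf_gene_overlaps_ref_space,
            }
            done()

        summary["selected_k"] = ms.K
        summary["n_de_genes"] = len(union)
        summary["n_de_tfs"] = len(tfs_de)
        summary["n_contrasts"] = len(tables)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:
        manifest["failed"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def report(outdir: str | Path) -> str:
    """Human-readable markdown summary of a completed run."""
    outdir = Path(outdir)
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {outdir}; did the run complete?")
    summary = json.loads(summary_path.read_text())
    lines = ["# modnet run report", ""]
    lines.append(f"- DE genes (union over contrasts): {summary['n_de_genes']}")
    lines.append(f"- DE transcription factors: {summary['n_de_tfs']}")
    lines.append(f"- contrasts tested: {summary['n_contrasts']}")
    lines.append(f"- selected K: {summary['selected_k']}")
    lines.append(
        f"- consensus edges: {summary['n_edges']} between "
        f"{summary['n_distinct_tfs']} TFs and {summary['n_distinct_modules']} modules"
    )
    lines.append(
        f"- candidate universe: {summary['candidate_universe']} pairs "
        f"({100 * summary['fraction_of_universe']:.4f}% retained)"
    )
    lines.append("- edge categories: " + ", ".join(
        f"{k}={v}" for k, v in summary["category_counts"].items()
    ))
    bic_path = outdir / "bic.tsv"
    if bic_path.exists():
        bic = pd.read_csv(bic_path, sep="\t")
        lines.append("")
        lines.append("## BIC by K")
        lines.append(bic.to_string(index=False))
    enr_path = outdir / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        top = enr.sort_values("padj").head(10)
        lines.append("")
        lines.append("## Top enriched GO terms")
        lines.append(top.to_string(index=False))
    if "validation" in summary:
        v = summary["validation"]
        lines.append("")
        lines.append(
            f"## Reference-network overlap: {v['tf_module_overlaps']} TF-module, "
            f"{v['tf_gene_overlaps']} TF-gene pairs"
        )
    return "\n".join(lines) + "\n"
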