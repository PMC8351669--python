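"""End-to-end per-tissue orchestration of the analysis stages.

The stages run in method order — preprocess (depth filter, low-count filter,
size factors + VST, outlier removal, PCA), segmented regression with a
permutation-calibrated adjusted-R2 cutoff, co-expression network and module
analysis, gene-list integration, over-representation analysis, and the
enrichment map — writing every stage's table plus a machine-readable
``summary.json``.  Stage outputs are pure functions of (inputs, config,
seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, enrichmap, integrate, network, preprocess, trendy

log = logging.getLogger("agingnet")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, in one place.

    Per-tissue entries (``min_per_segment``, ``r2_cutoff``, ``soft_power``,
    ``deep_split``) may be "auto": the minimum age-group size, the
    permutation-calibrated cutoff, and the scale-free criterion then decide.
    """

    min_library_size: float = preprocess.DEFAULT_MIN_LIBRARY_SIZE
    zk_threshold: float = preprocess.DEFAULT_ZK_THRESHOLD
    low_count: int = preprocess.DEFAULT_LOW_COUNT
    min_age_months: int = 3  # drops developmental samples via metadata
    n_top_pca: int = preprocess.DEFAULT_N_TOP_PCA
    max_k: int = trendy.DEFAULT_MAX_K
    min_per_segment: int | str = "auto"
    r2_cutoff: float | str = "auto"
    n_perm: int = trendy.DEFAULT_N_PERM
    pass_fraction: float = trendy.DEFAULT_PASS_FRACTION
    slope_alpha: float = trendy.DEFAULT_SLOPE_ALPHA
    soft_power: int | str = "auto"
    min_module_size: int = network.DEFAULT_MIN_MODULE_SIZE
    merge_height: float = network.DEFAULT_MERGE_HEIGHT
    deep_split: int = network.DEFAULT_DEEP_SPLIT
    module_r_min: float = network.DEFAULT_R_MIN
    module_fdr: float = network.DEFAULT_FDR_ALPHA
    mmgs_min: float = network.DEFAULT_MMGS_MIN
    mmgs_alpha: float = network.DEFAULT_MMGS_ALPHA
    hub_gs: float = network.DEFAULT_HUB_GS
    hub_mm: float = network.DEFAULT_HUB_MM
    ora_min_size: int = enrich.DEFAULT_MIN_SET_SIZE
    ora_max_size: int = enrich.DEFAULT_MAX_SET_SIZE
    ora_alpha: float = enrich.DEFAULT_ALPHA
    map_cutoff: float = enrichmap.DEFAULT_SIMILARITY_CUTOFF
    map_metric: str = enrichmap.DEFAULT_METRIC
    map_inflation: float = enrichmap.DEFAULT_INFLATION
    # sex-associated modules enter integration only when listed here (the
    # judgement that a sex module shows a time trend is a config decision)
    trended_sex_modules: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def study_defaults_for(tissue: str) -> dict:
    """Per-tissue constants used by the original study on GSE132040."""
    return {
        "min_per_segment": trendy.STUDY_MIN_PER_SEGMENT.get(tissue, "auto"),
        "r2_cutoff": trendy.STUDY_R2_CUTOFFS.get(tissue, "auto"),
        "soft_power": network.STUDY_POWERS.get(tissue, "auto"),
        "deep_split": 4 if tissue == "liver" else 2,
    }


# ---------------------------------------------------------------------------
# Stage functions (in-memory)
# ---------------------------------------------------------------------------

def preprocess_stage(
    counts: preprocess.CountMatrix,
    samples: preprocess.SampleTable,
    tissue: str,
    cfg: PipelineConfig,
) -> dict:
    """QC + normalization: returns the VST matrix, QC report and PCA."""
    meta = samples.table
    keep_ids = meta.loc[
        (meta["tissue"] == tissue) & (meta["age_months"] >= cfg.min_age_months),
        "sample_id",
    ]
    keep_ids = [s for s in counts.sample_ids if s in set(keep_ids)]
    if not keep_ids:
        raise ValueError(f"no samples for tissue {tissue!r}")
    cm = counts.subset_samples(keep_ids)

    cm, depth_report = preprocess.filter_samples_by_depth(cm, cfg.min_library_size)
    meta_kept = samples.aligned_to(cm.sample_ids)
    min_group = int(meta_kept.groupby("age_months").size().min())

    def _normalize(cm_in):
        filtered = preprocess.filter_low_count_genes(
            cm_in, cfg.low_count, min_samples=min_group
        )
        sf = preprocess.estimate_size_factors(filtered)
        return filtered, preprocess.vst_transform(filtered, sf)

    filtered, expr = _normalize(cm)
    qc = preprocess.detect_outlier_samples(expr, cfg.zk_threshold)
    outliers = list(qc.table.loc[qc.table["outlier"], "sample_id"])
    if outliers:
        log.info("dropping %d outlier samples: %s", len(outliers), outliers)
        cm = cm.subset_samples([s for s in cm.sample_ids if s not in set(outliers)])
        filtered, expr = _normalize(cm)
    scores, var_pct = preprocess.pca_top_variable(
        expr, min(cfg.n_top_pca, expr.n_genes)
    )
    qc_table = depth_report.table.merge(
        qc.table[["sample_id", "z_k", "outlier"]], on="sample_id", how="left",
        suffixes=("_depth", ""),
    )
    return {
        "counts": filtered,
        "expr": expr,
        "qc": qc_table,
        "pca_scores": scores,
        "pca_var_pct": var_pct,
        "min_group_size": min_group,
        "meta": samples.aligned_to(expr.sample_ids),
    }


def trendy_stage(expr, meta, cfg: PipelineConfig, min_group: int) -> dict:
    """Segmented fits, cutoff calibration, dynamic-gene calls, summaries."""
    t = meta["age_months"].to_numpy(dtype=float)
    sex = meta["sex_code"].to_numpy(dtype=float)
    min_seg = min_group if cfg.min_per_segment == "auto" else int(cfg.min_per_segment)
    fits = trendy.fit_segmented_all(
        expr.values, t, sex, expr.gene_ids,
        max_k=cfg.max_k, min_per_segment=min_seg, slope_alpha=cfg.slope_alpha,
    )
    if cfg.r2_cutoff == "auto":
        cutoff = trendy.permutation_r2_cutoff(
            expr.values, t, sex,
            n_perm=cfg.n_perm, pass_fraction=cfg.pass_fraction,
            max_k=cfg.max_k, min_per_segment=min_seg, seed=cfg.seed,
        )
    else:
        cutoff = float(cfg.r2_cutoff)
    calls, n_sel, pct = trendy.select_top_dynamic(fits, cutoff, cfg.slope_alpha)
    selected_ids = {c.gene_id for c in calls if c.is_top_dynamic}
    summary = trendy.summarize_breakpoints(fits, selected_ids)
    return {
        "fits": fits,
        "calls": calls,
        "cutoff": cutoff,
        "n_dynamic": n_sel,
        "pct_dynamic": pct,
        "selected_ids": selected_ids,
        "breakpoint_summary": summary,
    }


def network_stage(expr, meta, cfg: PipelineConfig) -> dict:
    """Co-expression network, modules, trait statistics, hubs."""
    keep = expr.values.std(axis=1) > 0
    expr_nz = expr.subset_genes(keep)
    cor = network.bicor_matrix(expr_nz.values)
    if cfg.soft_power == "auto":
        _, beta = network.pick_soft_threshold(cor, expr_nz.n_samples)
    else:
        beta = int(cfg.soft_power)
    A = network.adjacency_signed(cor, beta)
    tom = network.tom_similarity(A)
    modules = network.detect_modules(
        tom, expr_nz.values, expr_nz.gene_ids,
        min_size=cfg.min_module_size, deep_split=cfg.deep_split,
        merge_height=cfg.merge_height, sample_ids=expr_nz.sample_ids,
    )
    traits = pd.DataFrame(
        {
            "age": meta["age_months"].to_numpy(dtype=float),
            "sex": meta["sex_code"].to_numpy(dtype=float),
        },
        index=expr_nz.sample_ids,
    )
    if modules.eigengenes.empty:
        return {"modules": modules, "beta": beta, "module_trait": pd.DataFrame(),
                "gene_stats": {}, "retained": {}, "hubs": {}}
    assoc = network.module_trait_association(
        modules.eigengenes, traits, cfg.module_r_min, cfg.module_fdr
    )
    gene_stats: dict[str, pd.DataFrame] = {}
    retained: dict[str, list[str]] = {}
    hubs: dict[str, dict[str, list[str]]] = {}
    for trait in ("age", "sex"):
        sel_modules = list(assoc.loc[(assoc["trait"] == trait) & assoc["selected"], "module"])
        if not sel_modules:
            gene_stats[trait] = pd.DataFrame()
            retained[trait] = []
            hubs[trait] = {}
            continue
        gstats, mstats = network.gene_module_stats(
            expr_nz.values, expr_nz.gene_ids, modules.labels,
            modules.eigengenes[sel_modules], traits[trait].to_numpy(),
            cfg.mmgs_min, cfg.mmgs_alpha,
        )
        kept = list(mstats.loc[mstats["retained"], "module"])
        gene_stats[trait] = gstats
        retained[trait] = kept
        hubs[trait] = network.hub_genes(gstats, kept, cfg.hub_gs, cfg.hub_mm)
    return {
        "modules": modules,
        "beta": beta,
        "module_trait": assoc,
        "gene_stats": gene_stats,
        "retained": retained,
        "hubs": hubs,
    }


def integrate_stage(trendy_ids: set[str], net: dict, modules, cfg: PipelineConfig) -> dict:
    """Per-module overlap reports and the combined per-tissue signature."""
    reports: dict[str, integrate.OverlapReport] = {}
    signature: set[str] = set()
    considered: list[tuple[str, str]] = []
    for module in net["retained"].get("age", []):
        considered.append(("age", module))
    for module in net["retained"].get("sex", []):
        if module in cfg.trended_sex_modules:
            considered.append(("sex", module))
    for trait, module in considered:
        module_genes = set(modules.members(module))
        hub = set(net["hubs"][trait].get(module, []))
        rep = integrate.intersect_gene_sets(trendy_ids, module_genes, hub)
        reports[f"{trait}:{module}"] = rep
        signature |= rep.signature
    return {"reports": reports, "signature": signature}


def run_tissue_pipeline(
    counts: preprocess.CountMatrix,
    samples: preprocess.SampleTable,
    gene_sets: enrich.GeneSetCollection,
    tissue: str,
    cfg: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Run every stage for one tissue; optionally persist all outputs."""
    cfg = cfg or PipelineConfig()
    stage = "preprocess"
    try:
        pre = preprocess_stage(counts, samples, tissue, cfg)
        stage = "trendy"
        tr = trendy_stage(pre["expr"], pre["meta"], cfg, pre["min_group_size"])
        stage = "network"
        net = network_stage(pre["expr"], pre["meta"], cfg)
        stage = "integrate"
        ig = integrate_stage(tr["selected_ids"], net, net["modules"], cfg)
        stage = "enrich"
        universe = set(pre["expr"].gene_ids)
        enr = enrich.ora(
            ig["signature"], universe, gene_sets,
            cfg.ora_min_size, cfg.ora_max_size, cfg.ora_alpha,
        )
        stage = "enrichmap"
        sig_rows = enr[enr["significant"]] if len(enr) else enr
        term_sets = {
            tid: gene_sets.members(tid) & universe for tid in sig_rows.get("term_id", [])
        }
        tg = enrichmap.build_term_graph(sig_rows, term_sets, cfg.map_cutoff, cfg.map_metric)
        enrichmap.mcl_cluster(tg, cfg.map_inflation)
        metas, meta_edges = (
            enrichmap.collapse_to_meta(tg) if tg.clusters else ([], pd.DataFrame())
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r} for {tissue!r}: {exc}") from exc

    n_modules = len(net["modules"].module_names)
    summary = {
        "tissue": tissue,
        "samples_kept": pre["expr"].n_samples,
        "genes_kept": pre["expr"].n_genes,
        "trendy_cutoff": round(float(tr["cutoff"]), 6),
        "trendy_genes": int(tr["n_dynamic"]),
        "trendy_pct": tr["pct_dynamic"],
        "soft_power": int(net["beta"]),
        "modules": n_modules,
        "selected_age_modules": net["retained"].get("age", []),
        "selected_sex_modules": net["retained"].get("sex", []),
        "hub_genes": sorted(
            {g for trait in net["hubs"] for hs in net["hubs"][trait].values() for g in hs}
        ),
        "signature_size": len(ig["signature"]),
        "significant_terms": int(sig_rows.shape[0]) if len(enr) else 0,
        "meta_nodes": len(metas),
    }
    result = {
        "preprocess": pre, "trendy": tr, "network": net, "integrate": ig,
        "enrichment": enr, "term_graph": tg, "meta_nodes": metas,
        "meta_edges": meta_edges, "summary": summary,
    }
    if out_dir is not None:
        _write_outputs(result, tissue, Path(out_dir), cfg)
    return result


def _write_outputs(result: dict, tissue: str, out: Path, cfg: PipelineConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pre, tr, net = result["preprocess"], result["trendy"], result["network"]
    pre["qc"].to_csv(out / "qc_report.tsv", sep="\t", index=False)
    trendy.fits_to_frame(tr["fits"]).to_csv(out / "trendy_fits.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in tr["calls"]],
            "is_top_dynamic": [c.is_top_dynamic for c in tr["calls"]],
            "cutoff": [c.cutoff_used for c in tr["calls"]],
            "trend": [c.overall_trend for c in tr["calls"]],
        }
    ).to_csv(out / "top_dynamic.tsv", sep="\t", index=False)
    bs = tr["breakpoint_summary"]
    with open(out / "breakpoint_summary.json", "w") as fh:
        json.dump(
            {
                "histogram": {str(k): v for k, v in bs.histogram.items()},
                "median_breakpoint": bs.median_breakpoint,
                "fraction_before_reference": bs.fraction_before_reference,
                "fraction_per_k": {str(k): v for k, v in bs.fraction_per_k.items()},
                "monotonic_fraction": bs.monotonic_fraction,
            },
            fh, indent=1,
        )
    modules = net["modules"]
    modules.labels.rename("module").rename_axis("gene_id").reset_index().to_csv(
        out / "modules.tsv", sep="\t", index=False
    )
    if not modules.eigengenes.empty:
        modules.eigengenes.rename_axis("sample_id").to_csv(
            out / "module_eigengenes.tsv", sep="\t"
        )
    if len(net["module_trait"]):
        net["module_trait"].to_csv(out / "module_trait.tsv", sep="\t", index=False)
    hub_rows = [
        {"trait": trait, "module": m, "gene_id": g}
        for trait in net["hubs"] for m, gs in net["hubs"][trait].items() for g in gs
    ]
    pd.DataFrame(hub_rows, columns=["trait", "module", "gene_id"]).to_csv(
        out / "hubs.tsv", sep="\t", index=False
    )
    with open(out / "intersections.json", "w") as fh:
        json.dump(
            {
                key: integrate.regions_to_json(rep.regions)
                for key, rep in result["integrate"]["reports"].items()
            },
            fh, indent=1,
        )
    with open(out / f"signature_{tissue}.txt", "w") as fh:
        fh.write("\n".join(sorted(result["integrate"]["signature"])) + "\n")
    result["enrichment"].to_csv(out / f"enrichment_{tissue}.tsv", sep="\t", index=False)
    tg = result["term_graph"]
    if tg.graph.number_of_nodes():
        enrichmap.write_term_graph(
            tg, out / "term_graph.graphml", out / "term_graph_edges.tsv"
        )
        pd.DataFrame(
            [{"term_id": t, "cluster": c} for t, c in sorted(tg.clusters.items())]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "cluster_id": m.cluster_id, "label": m.label, "n_nodes": m.n_nodes,
                "summary_fdr": m.summary_fdr,
            }
            for m in result["meta_nodes"]
        ],
        columns=["cluster_id", "label", "n_nodes", "summary_fdr"],
    ).to_csv(out / "meta_nodes.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result["summary"], fh, indent=1, sort_keys=True)
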