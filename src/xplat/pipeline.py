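"""End-to-end pipeline: simulate/load -> normalize -> ratios -> statistics.

Driven by a YAML (or dict) config with one global seed. Synthetic mode
generates the three-platform bundle; file mode reads matrices and a sample
sheet produced elsewhere. Every stage writes its tables under the output
directory and the run ends with a machine-readable ``summary.json``
mirroring the variance-component, replicate-distance and enrichment
comparisons.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import anova as anova_mod
from . import cluster as cluster_mod
from . import enrichment as enr_mod
from . import preprocess as pre_mod
from . import rmsd as rmsd_mod
from . import snr as snr_mod
from .core import ExpressionMatrix, StudyDesign, read_design, read_expression_tsv, write_expression_tsv
from .ontology import GoDag, read_obo_and_annotation
from .pvca import pvca as run_pvca
from .simulate import default_truth, make_synthetic_godag, make_three_platform_bundle

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "synthetic": {
        "n_genes": 4000,
        "de_fraction": 0.1,
        "effect_size": 2.0,
        "variance_fractions": {"moa": 0.4, "chemical": 0.3, "route": 0.05, "residual": 0.25},
    },
    "low_count_threshold": 214,
    "pvca_threshold": 0.5876,
    "fdr": 0.01,
    "enrichment_fdr": 0.05,
    "enrichment_min_genes": 5,
    "snr": {"min_snr": 3.0, "r_min": 0.64, "alpha": 1e-4, "min_size": 5},
    "stages": {"pvca": True, "rmsd": True, "snr": True, "anova": True,
               "cluster": True, "enrich": True},
}


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _merge_config(user: dict[str, Any]) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _load_inputs(cfg: dict[str, Any]) -> tuple[dict[str, dict], StudyDesign, GoDag | None, Any]:
    """Returns (per-platform raw inputs, design, ontology, id_map)."""
    if "platform_files" in cfg:
        design = read_design(cfg["design"])
        platforms: dict[str, dict] = {}
        for name, entry in cfg["platform_files"].items():
            if "counts" in entry:
                mat = read_expression_tsv(entry["counts"], "counts", name)
            else:
                mat = read_expression_tsv(entry["matrix"], "log2norm", name)
            lengths = None
            if "lengths" in entry:
                lengths = pd.read_csv(entry["lengths"], sep="\t", index_col=0).iloc[:, 0]
            platforms[name] = {"matrix": mat, "lengths": lengths}
        dag = None
        if "ontology" in cfg:
            ont = cfg["ontology"]
            dag = read_obo_and_annotation(ont["obo"], ont.get("annotation"),
                                          ont.get("universe"))
        id_map = None
        if "id_map" in cfg:
            from .core import read_id_map
            id_map = read_id_map(cfg["id_map"])
        return platforms, design, dag, id_map

    syn = cfg["synthetic"]
    truth = default_truth(syn["n_genes"], seed=int(cfg["seed"]),
                          de_fraction=syn["de_fraction"],
                          effect_size=syn["effect_size"],
                          variance_fractions=syn["variance_fractions"])
    bundle = make_three_platform_bundle(truth, n_genes=syn["n_genes"])
    platforms = {
        "microarray": {"matrix": bundle.microarray, "lengths": None},
        "rnaseq": {"matrix": bundle.rnaseq_counts, "lengths": bundle.rnaseq_lengths},
        "temposeq": {"matrix": bundle.temposeq_counts, "lengths": None},
    }
    dag = make_synthetic_godag(list(bundle.base_log2.gene_ids), truth)
    return platforms, bundle.design, dag, bundle.id_map


def _normalize(name: str, entry: dict, cfg: dict[str, Any]) -> ExpressionMatrix:
    mat = entry["matrix"]
    if mat.scale == "log2norm":
        return mat
    if entry.get("lengths") is not None:
        return pre_mod.magic_index_matrix(mat, entry["lengths"])
    filtered = pre_mod.filter_low_count_genes(mat, cfg["low_count_threshold"])
    return pre_mod.cpm_log2(filtered)


def run_pipeline(config: str | Path | dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run the configured stages for every platform and write a report bundle.

    Raises on any stage failure, naming the stage; partial outputs written
    before the failure are retained. Returns the summary dict (also written
    to ``summary.json``).
    """
    if not isinstance(config, dict):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    summary: dict[str, Any] = {"seed": cfg["seed"], "parameters": {
        k: cfg[k] for k in ("low_count_threshold", "pvca_threshold", "fdr",
                            "enrichment_fdr", "enrichment_min_genes", "snr")}}

    stage = "load"
    try:
        platforms, design, dag, id_map = _load_inputs(cfg)
        design.table.to_csv(out / "design.csv", index=False)

        ratios: dict[str, ExpressionMatrix] = {}
        varying: dict[str, list[str]] = {}
        enrich_tables: dict[str, pd.DataFrame] = {}
        for name, entry in platforms.items():
            pdir = out / name
            pdir.mkdir(exist_ok=True)
            psum: dict[str, Any] = {}

            stage = f"{name}:normalize"
            norm = _normalize(name, entry, cfg)
            write_expression_tsv(norm, pdir / "normalized.tsv")
            psum["n_genes"] = norm.n_genes

            stage = f"{name}:log2_ratio"
            ratio = pre_mod.log2_ratio(norm, design)
            write_expression_tsv(ratio, pdir / "log2_ratio.tsv")
            ratios[name] = ratio

            if stages["pvca"]:
                stage = f"{name}:pvca"
                res = run_pvca(ratio, design, threshold=cfg["pvca_threshold"])
                psum["pvca"] = {"k": res.k,
                                "weighted_average_proportions": res.weighted_average_proportions}
                (pdir / "pvca.json").write_text(json.dumps(_jsonable({
                    "eigenvalues": res.eigenvalues, "k": res.k,
                    "per_pc_proportions": res.per_pc_proportions.to_dict(),
                    "weighted_average_proportions": res.weighted_average_proportions,
                }), indent=2))

            if stages["rmsd"]:
                stage = f"{name}:rmsd"
                rs = rmsd_mod.summarize_rmsd(ratio, design)
                rs.pairwise.to_csv(pdir / "rmsd_pairs.tsv", sep="\t", index=False)
                psum["rmsd"] = {"platform_rmsd": rs.platform_rmsd,
                                "avg_chemical_rmsd": rs.avg_chemical_rmsd,
                                "moa_rmsd": rs.moa_rmsd}

            if stages["snr"]:
                stage = f"{name}:snr"
                table = snr_mod.snr_table(ratio, design)
                table.to_csv(pdir / "snr.tsv", sep="\t")
                pats = snr_mod.extract_patterns(ratio, design, seed=int(cfg["seed"]),
                                                **cfg["snr"])
                psum["snr"] = {"n_patterns": len(pats.patterns),
                               "average_snr": pats.average_snr,
                               "pattern_sizes": [len(p.member_genes) for p in pats.patterns]}

            if stages["anova"]:
                stage = f"{name}:anova"
                res = anova_mod.fit_moa_anova(ratio, design)
                res.table.to_csv(pdir / "anova.tsv", sep="\t")
                genes = anova_mod.select_moa_varying(res, cfg["fdr"])
                varying[name] = genes
                psum["anova"] = {"n_moa_varying": len(genes),
                                 "fdr": cfg["fdr"],
                                 "df": [res.df_moa, res.df_chem]}

                if stages["cluster"] and genes:
                    stage = f"{name}:cluster"
                    sub = cluster_mod.standardize_genes(ratio.subset_genes(genes))
                    hc = cluster_mod.hcluster(sub, axis="samples", k=len(design.moas))
                    (pdir / "dendrogram.nwk").write_text(hc.newick)
                    agree = cluster_mod.moa_agreement(hc.labels, design)
                    scores, evr = cluster_mod.pca_projection(sub)
                    scores.to_csv(pdir / "pca_scores.tsv", sep="\t")
                    psum["cluster"] = {
                        "overall_purity": agree.overall_purity,
                        "outlier_chemicals": agree.outlier_chemicals,
                        "pca_explained": list(evr),
                    }

                if stages["enrich"] and dag is not None and genes and id_map is not None:
                    stage = f"{name}:enrich"
                    mapping = id_map.for_platform(name)
                    clusters = sorted({mapping[g] for g in genes if g in mapping})
                    table = enr_mod.enrich(clusters, dag,
                                           min_genes=cfg["enrichment_min_genes"])
                    table.to_csv(pdir / "enrichment.tsv", sep="\t", index=False)
                    enrich_tables[name] = table
                    psum["enrichment"] = {
                        "n_significant": int((table["q"] < cfg["enrichment_fdr"]).sum())}

            summary[name] = psum

        cross: dict[str, Any] = {}
        if len(ratios) > 1 and id_map is not None and varying:
            stage = "cross:merge"
            union = set()
            for name, genes in varying.items():
                mapping = id_map.for_platform(name)
                union |= {mapping[g] for g in genes if g in mapping}
            mats = []
            for name, ratio in ratios.items():
                mapping = id_map.for_platform(name)
                keep = [g for g in ratio.gene_ids if mapping.get(g) in union]
                mats.append(ratio.subset_genes(keep))
            merged = pre_mod.merge_platforms_by_cluster_id(mats, id_map,
                                                           platforms=list(ratios))
            write_expression_tsv(merged, out / "merged_log2_ratio.tsv")
            cross["n_shared_cluster_ids"] = merged.n_genes
            if stages["cluster"]:
                stage = "cross:cluster"
                std = cluster_mod.standardize_genes(merged)
                hc = cluster_mod.hcluster(std, axis="samples", k=len(design.moas))
                (out / "merged_dendrogram.nwk").write_text(hc.newick)
                scores, evr = cluster_mod.pca_projection(std)
                cross["pca_explained"] = list(evr)
        if len(enrich_tables) > 1:
            stage = "cross:fe_concordance"
            try:
                corr = enr_mod.fe_concordance(enrich_tables, cfg["enrichment_fdr"])
                cross["fe_concordance"] = {f"{a}|{b}": r for (a, b), r in corr.items()}
            except ValueError as exc:
                warnings.warn(f"FE concordance skipped: {exc}")
            stage = "cross:gostag"
            try:
                pmat = enr_mod.gostag_pmatrix(enrich_tables, cfg["enrichment_fdr"])
                pmat.to_csv(out / "gostag_pmatrix.tsv", sep="\t")
                gres = enr_mod.gostag_cluster(pmat, dag)
                cross["gostag_clusters"] = [
                    {"label": c["label_name"], "label_term": c["label_term"],
                     "n_terms": len(c["terms"])} for c in gres.clusters]
            except ValueError as exc:
                warnings.warn(f"enrichment-profile clustering skipped: {exc}")
        if cross:
            summary["cross_platform"] = cross
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    return summary
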