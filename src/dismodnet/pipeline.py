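"""End-to-end pipeline: DE filtering -> disease PPI modules -> disease-miRNA
prediction -> biomarker screening -> validation arithmetic.

``run_pipeline`` consumes a :class:`~dismodnet.config.PipelineConfig` plus a
manifest of input paths and writes one TSV/JSON artefact per stage into an
output directory.  All tables are deterministically sorted (score
descending, then symbol ascending), so identical config + seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import biomarker as bm
from . import de as de_mod
from . import mirna as mi
from . import ppi as ppi_mod
from . import validation as val
from .config import PipelineConfig
from .io import read_de_table, read_edge_list, read_gene_list, write_gene_list, write_table

log = logging.getLogger("dismodnet")

MANIFEST_KEYS = ("de_tables", "ppi_edges", "mti_sources", "disease_genes", "tf_genes")


def _require(manifest: dict, key: str):
    if key not in manifest:
        raise KeyError(f"manifest is missing required entry '{key}'")
    return manifest[key]


def run_de_stage(config: PipelineConfig, de_specs, disease_genes: set[str]):
    """Filter, collapse and union the DE tables; partition HDEG/ODEG."""
    filtered = []
    for spec in de_specs:
        path, kind = (spec["path"], spec.get("kind", "auto")) if isinstance(spec, dict) \
            else (spec, "auto")
        table = read_de_table(path)
        if kind == "auto":
            kind = "proteomics" if "FC" in table.columns and "logFC" not in table.columns \
                else "microarray"
        if kind == "microarray":
            f = de_mod.filter_microarray(table, config.de_fdr_max, config.de_abs_logfc_min)
        elif kind == "proteomics":
            f = de_mod.filter_proteomics(table, config.prot_abs_fc_min, config.prot_p_max)
        else:
            raise ValueError(f"unknown DE table kind {kind!r}")
        filtered.append(de_mod.collapse_probes(f))
    union = de_mod.union_and_partition(filtered, disease_genes)
    log.info("DE union: %d genes (%d HDEG, %d ODEG)",
             len(union.symbols), len(union.hdegs), len(union.odegs))
    return filtered, union


def run_ppi_stage(config: PipelineConfig, reference_edges, union):
    """Build the disease network, sweep the density grid, select by AUC and
    call modules and candidate genes."""
    graph = ppi_mod.build_disease_network(reference_edges, union)
    topo = ppi_mod.topology(graph)
    runs = ppi_mod.cluster_grid(graph, config.density_grid, cp_min=config.cp_min,
                                min_size=config.min_cluster_size,
                                aggregate=config.sscore_aggregate,
                                universe=config.roc_universe)
    best = ppi_mod.select_density(runs)
    modules, candidates = ppi_mod.call_modules_and_candidates(best, graph,
                                                              fdr_max=config.module_fdr_max)
    log.info("PPI network: %d nodes / %d edges; selected density %.1f (AUC %.3f); "
             "%d significant modules, %d candidate genes",
             graph.number_of_nodes(), graph.number_of_edges(),
             best.density_threshold, best.auc, len(modules), len(candidates))
    return graph, topo, runs, best, modules, candidates


def run_mirna_stage(config: PipelineConfig, mti_edges: dict[str, set], query_genes: set[str],
                    disease_genes: set[str]):
    """Bicluster each MTI source, score miRNAs and call predictions."""
    mtis = {name: mi.build_mti(edges, query_genes, source_name=name)
            for name, edges in sorted(mti_edges.items())}
    mrms = {name: mi.mark_sub_mrms(
                mi.bicluso_bicluster(mti, sim_min=config.sim_min,
                                     density_threshold=0.5,
                                     attach_ratio=config.attach_ratio),
                disease_genes)
            for name, mti in mtis.items()}
    scores = mi.relevance_scores(mrms, mtis, disease_genes,
                                 normalize_by=config.trs_normalize_by)
    predicted = mi.predict_mirnas(scores, trs_min=config.trs_min)
    log.info("miRNA stage: %s MRMs per source; %d scored, %d predicted",
             {n: len(v) for n, v in mrms.items()}, len(scores), len(predicted))
    return mtis, mrms, scores, predicted


def run_pipeline(config: PipelineConfig, manifest: dict, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle; returns the JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    disease_genes = read_gene_list(_require(manifest, "disease_genes"))
    tf_genes = read_gene_list(_require(manifest, "tf_genes"))
    de_specs = _require(manifest, "de_tables")
    ppi_path = _require(manifest, "ppi_edges")
    mti_paths = _require(manifest, "mti_sources")

    filtered, union = run_de_stage(config, de_specs, disease_genes)
    union_df = pd.DataFrame(
        sorted(({"symbol": s, "class": "HDEG" if s in union.hdegs else "ODEG"}
                for s in union.symbols), key=lambda r: r["symbol"]))
    write_table(out / "de_union.tsv", union_df)

    ref_edges, _ = read_edge_list(ppi_path)
    graph, topo, runs, best, modules, candidates = run_ppi_stage(config, ref_edges, union)
    with open(out / "topology.json", "w") as fh:
        json.dump(topo.to_dict(), fh, indent=1, sort_keys=True)
    write_table(out / "auc_by_density.tsv", pd.DataFrame(
        [{"density": r.density_threshold, "total_cluster": r.total_cluster,
          "max_size": r.max_size, "avg_size": round(r.avg_size, 3),
          "significant": r.significant_count, "auc": round(r.auc, 6)} for r in runs]))
    write_table(out / "modules.tsv", pd.DataFrame(
        [{"cluster": i + 1, "members": ",".join(sorted(c.members)),
          "size": len(c), "density": round(c.density, 4),
          "p": c.p_value, "adj_p": c.adj_p}
         for i, c in enumerate(sorted(modules, key=lambda c: (c.adj_p, sorted(c.members))))]))
    write_gene_list(out / "candidates.txt", candidates)

    mti_edges = {}
    for name, path in sorted(mti_paths.items()):
        edges, _ = read_edge_list(path, directed=True)
        mti_edges[name] = edges
    query = disease_genes | candidates
    mtis, mrms, scores, predicted = run_mirna_stage(config, mti_edges, query, disease_genes)
    for name, blist in mrms.items():
        write_table(out / f"mrms_{name}.tsv", pd.DataFrame(
            [{"mirnas": ",".join(sorted(b.mirnas)), "genes": ",".join(sorted(b.genes)),
              "fill": round(b.fill, 4), "is_sub_mrm": b.is_sub_mrm}
             for b in sorted(blist, key=lambda b: (-len(b.mirnas), sorted(b.mirnas)))]))
    src_names = sorted(mtis)
    write_table(out / "scores.tsv", pd.DataFrame(
        [{"mirna": s.mirna,
          **{f"RS_{n}": s.rs[n] for n in src_names},
          **{f"C_{n}": s.c[n] for n in src_names},
          **{f"E_{n}": s.e[n] for n in src_names},
          "TRS": round(s.trs, 6)}
         for s in sorted(scores, key=lambda s: (-s.trs, s.mirna))]))
    write_gene_list(out / "predicted_mirnas.txt", [s.mirna for s in predicted])

    union_net = bm.build_reference_network(list(mtis.values()))
    records = bm.nsr_tfp(union_net, tf_genes)
    screened = bm.screen(records, {s.mirna for s in predicted},
                         alpha=config.biomarker_alpha)
    write_table(out / "biomarkers.tsv", pd.DataFrame(
        [{"mirna": r.mirna, "out_degree": r.out_degree, "NSR": r.nsr,
          "p_NSR": round(r.p_nsr, 6), "TFP_count": r.tfp_count,
          "TFP_pct": round(r.tfp_pct, 6), "p_TFP": round(r.p_tfp, 6),
          "is_candidate": r.is_candidate} for r in screened]))

    report = {
        "de": {"n_tables": len(filtered), "union_size": len(union.symbols),
               "n_hdeg": len(union.hdegs), "n_odeg": len(union.odegs)},
        "ppi": {"n_nodes": graph.number_of_nodes(), "n_edges": graph.number_of_edges(),
                "selected_density": best.density_threshold, "auc": best.auc,
                "n_significant_modules": len(modules), "n_candidates": len(candidates)},
        "mirna": {"n_mrms": {n: len(v) for n, v in mrms.items()},
                  "n_sub_mrms": {n: sum(b.is_sub_mrm for b in v) for n, v in mrms.items()},
                  "n_predicted": len(predicted)},
        "biomarker": {"n_screened": len(screened),
                      "n_biomarkers": sum(r.is_candidate for r in screened)},
    }
    if len(predicted) >= 2:
        k = min(10, len(predicted))
        try:
            report["mirna"]["attachment_ratio_top%d" % k] = mi.attachment_ratio(
                predicted, k, union_net.edges, disease_genes)
        except ValueError:
            pass
    if "curated_genes" in manifest:
        curated = read_gene_list(manifest["curated_genes"])
        n_universe = int(manifest.get("universe_size", graph.number_of_nodes()))
        k_cur = len(curated & set(graph.nodes))
        x, pct = val.match_rate(candidates, curated) if candidates else (0, 0.0)
        report["validation"] = {
            "n_matched": x, "match_pct": pct,
            "p_hypergeom": val.hypergeom_tail(n_universe, k_cur, len(candidates), x)
            if candidates and k_cur else 1.0,
            "expansion_pct": val.expansion_rate(len(candidates), len(curated))
            if curated else None,
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
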