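"""End-to-end orchestration of the per-dataset analysis and the
cross-dataset integration, with persisted stage outputs and an audit log."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import coexnet, integrate, io, module_select, ppi, preprocess, quantify
from .config import PipelineConfig

log = logging.getLogger("wpcna")


def run_dataset(
    config: PipelineConfig,
    dataset: str,
    outdir: str | Path,
    *,
    matrix: pd.DataFrame | None = None,
    peptides: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
    disease_set: set[str] | None = None,
) -> Path:
    """quantify (optional) -> preprocess -> network/modules -> selection.

    Inputs may be passed in memory or referenced by path in
    ``config.inputs`` (keys: ``{dataset}_matrix`` or ``{dataset}_peptides``,
    ``{dataset}_design``, ``disease_set``).  Returns the result directory.
    """
    if dataset not in ("invitro", "biopsy"):
        raise ValueError("dataset must be 'invitro' or 'biopsy'")
    outdir = Path(outdir) / dataset
    outdir.mkdir(parents=True, exist_ok=True)

    if peptides is None and f"{dataset}_peptides" in config.inputs:
        peptides = io.read_peptides(config.inputs[f"{dataset}_peptides"])
    if matrix is None and f"{dataset}_matrix" in config.inputs:
        matrix = io.read_matrix(config.inputs[f"{dataset}_matrix"])
    if design is None:
        design = io.read_design(config.inputs[f"{dataset}_design"])
    if disease_set is None and "disease_set" in config.inputs:
        disease_set = set().union(*io.read_gene_sets(config.inputs["disease_set"]).values())

    if peptides is not None:
        matrix = quantify.quantify(peptides)
        log.info("%s: %d proteins after Hi3 quantification", dataset, len(matrix))
    if matrix is None:
        raise ValueError(f"no matrix or peptide input for dataset {dataset}")

    if dataset == "invitro":
        matrix, report = preprocess.normalize_invitro(matrix, design)
    else:
        matrix, report = preprocess.normalize_biopsy(matrix)
    matrix = preprocess.standardize_decimals(matrix, config.preprocess.decimals)
    if f"{dataset}_id_map" in config.inputs:
        id_map_df = pd.read_csv(config.inputs[f"{dataset}_id_map"], sep="\t")
        id_map = dict(zip(id_map_df.iloc[:, 0], id_map_df.iloc[:, 1].astype(int)))
        matrix = preprocess.drop_ambiguous_ids(matrix, id_map)
        log.info("%s: %d proteins with a unique UniProt ID", dataset, len(matrix))
    matrix = preprocess.filter_missing(matrix, config.preprocess.max_missing_fraction)
    log.info("%s: %d proteins after missingness filter", dataset, len(matrix))

    params = coexnet.NetworkParams(
        power=config.network.power,
        min_cluster_size=config.network.min_cluster_size,
        deep_split=config.network.deep_split,
        pam_respects_dendro=config.network.pam_respects_dendro,
        merge_cut_height=config.network.merge_cut_height,
        kme_threshold=config.network.kme_threshold,
    )
    scan = coexnet.soft_threshold_report(matrix, [1, 2, 3, 4, 5, 6, 8, 10])
    pd.DataFrame(
        [(r.power, r.scale_free_r2, r.slope, r.mean_connectivity) for r in scan],
        columns=["power", "scale_free_r2", "slope", "mean_connectivity"],
    ).to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)

    adjacency = coexnet.signed_adjacency(matrix, params.power)
    diss = coexnet.tom_dissimilarity(adjacency)
    tree = coexnet.cluster_tree(diss)
    (outdir / "dendrogram.nwk").write_text(
        io.linkage_to_newick(tree, list(matrix.index)) + "\n"
    )
    partition = coexnet.dynamic_cut(tree, diss, params)
    eigengenes = coexnet.module_eigengenes(matrix, partition)
    partition, eigengenes = coexnet.merge_modules(
        matrix, partition, eigengenes, params.merge_cut_height
    )
    kme, weighted = coexnet.module_membership(
        matrix, eigengenes, partition, params.kme_threshold
    )
    sizes = partition[partition != coexnet.GREY].value_counts()
    log.info("%s: %d modules, sizes %s", dataset, len(sizes), sizes.to_dict())

    contrasts = module_select.eigengene_contrast(eigengenes, design, matrix, partition)
    selected = module_select.select_affected(
        contrasts, config.selection.effect_threshold, config.selection.pca_threshold
    )

    io.write_matrix(matrix, outdir / "matrix.tsv")
    partition.rename("color").to_csv(outdir / "partition.tsv", sep="\t", header=True)
    io.write_matrix(eigengenes.eigengenes, outdir / "eigengenes.tsv")
    io.write_matrix(kme, outdir / "kme.tsv")
    report.to_frame().to_csv(outdir / "normalization.tsv", sep="\t", index=False)
    io.write_json(
        {
            "scheme": report.scheme,
            "reference_set_size": report.reference_set_size,
            "targets": report.targets,
            "common_set_sizes": report.common_set_sizes,
        },
        outdir / "normalization.json",
    )
    io.write_json(
        {
            "dataset": dataset,
            "n_proteins": int(len(matrix)),
            "module_sizes": {m: int(n) for m, n in sizes.items()},
            "n_weighted": len(weighted),
            "weighted": sorted(weighted),
            "selected_modules": selected,
            "contrasts": [
                {
                    "module": c.module,
                    "effect": None if pd.isna(c.effect) else round(float(c.effect), 6),
                    "pca_separation": None
                    if pd.isna(c.pca_separation)
                    else round(float(c.pca_separation), 6),
                }
                for c in contrasts
            ],
            "normalization": {
                "scheme": report.scheme,
                "reference_set_size": report.reference_set_size,
            },
            "params": config.to_dict(),
        },
        outdir / "report.json",
    )
    if disease_set:
        counts = module_select.annotate_disease(partition, weighted, disease_set)
        counts.to_csv(outdir / "disease_counts.tsv", sep="\t")
    return outdir


def run_integration(
    config: PipelineConfig,
    dir_a: str | Path,
    dir_b: str | Path,
    outdir: str | Path,
    *,
    edges: list[tuple[str, str]] | None = None,
    disease_set: set[str] | None = None,
) -> dict:
    """Combine two completed per-dataset result directories: overlap and
    weighted sets, log2FC tables, the PPI hub analysis, and a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    for tag, d in (("a", Path(dir_a)), ("b", Path(dir_b))):
        rpt = d / "report.json"
        if not rpt.exists():
            raise FileNotFoundError(f"missing upstream artifact: {rpt}")
        with open(rpt) as fh:
            results[tag] = json.load(fh)
        results[tag]["partition"] = pd.read_csv(
            d / "partition.tsv", sep="\t", index_col=0
        )["color"].to_dict()
        results[tag]["matrix"] = io.read_matrix(d / "matrix.tsv")
        results[tag]["design"] = io.read_design(
            config.inputs[f"{results[tag]['dataset']}_design"]
        )

    if edges is None and "ppi_edges" in config.inputs:
        edges = io.read_edge_list(config.inputs["ppi_edges"])
    if disease_set is None and "disease_set" in config.inputs:
        disease_set = set().union(*io.read_gene_sets(config.inputs["disease_set"]).values())

    a, b = results["a"], results["b"]
    integration = integrate.overlap_datasets(
        set(a["partition"]),
        set(b["partition"]),
        set(a["weighted"]),
        set(b["weighted"]),
        a["partition"],
        b["partition"],
    )
    report: dict = {"integration": integration.summary()}

    for tag, res in results.items():
        if res["dataset"] == "invitro":
            fc = integrate.log2fc_invitro(res["matrix"], res["design"])
        else:
            fc = integrate.log2fc_biopsy(res["matrix"], res["design"])
        io.write_matrix(fc, outdir / f"log2fc_{res['dataset']}.tsv")

    high = {
        res["dataset"]: integrate.high_expression_filter(
            res["matrix"], config.integrate.high_expression_floor
        )
        for res in results.values()
    }
    report["high_expression"] = {k: sorted(v) for k, v in high.items()}

    if edges is not None:
        graph = ppi.build_induced_network(edges, integration.weighted_either)
        graph, n_orphans = ppi.remove_orphans(graph)
        hubs = ppi.find_hubs(graph, config.ppi.hub_min_degree)
        if disease_set:
            ppi.flag_disease_nodes(graph, disease_set)
            report["ppi_disease_pct_query"] = ppi.disease_percentage(
                integration.weighted_either, disease_set
            )
            report["ppi_disease_pct_nodes"] = graph.graph.get("disease_pct")
        report["ppi"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_orphans_removed": n_orphans,
            "hubs": hubs,
        }
        ppi.node_table(graph, hubs).to_csv(outdir / "ppi_nodes.tsv", sep="\t", index=False)

    io.write_json(report, outdir / "integration.json")
    return report
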