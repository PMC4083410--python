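"""End-to-end orchestration: simulate (optional) -> load -> overlap ->
variant/length/selection contrasts -> network proximity -> repurposing ML,
with TSV outputs and a markdown report mirroring the summary tables."""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from . import ml, network as net, overlap as ovl, synthetic, variants as var
from .types import DiseaseGeneMap

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "overlap", "variants", "network", "repurpose")


@dataclass
class RunConfig:
    """Resolved run settings; echoed as YAML into the output directory."""

    out_dir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # input paths; any missing input is synthesised by the simulate stage
    gwas_table: str | None = None
    drug_table: str | None = None
    network_path: str | None = None
    vcf_path: str | None = None
    annotation_path: str | None = None
    alias_table: str | None = None
    locus_map: str | None = None
    # thresholds
    common_af_threshold: float = 0.05
    min_targets: int = 10
    min_gwas: int = 10
    probability_threshold: float = 0.5
    genome_size: int = 20_000
    split_merged_diseases: bool = False
    verified_only: bool = False
    # synthetic scale (used only when inputs are missing)
    sim_nodes: int = 2000
    sim_diseases: int = 30
    sim_universe: int = 900
    sim_proximity_bias: float = synthetic.STRONG_PROXIMITY_BIAS
    sim_individuals: int = 100
    # ML settings
    rf_trees: int = 50
    cv_folds: int = 10
    max_ml_diseases: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def simulate_inputs(config: RunConfig) -> dict[str, str]:
    """Generate the four input files at the configured scale and return
    their paths (network edge list, GWAS/drug tables, VCF, annotation)."""
    out = Path(config.out_dir) / "simulated"
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    graph, net_manifest = synthetic.gen_network(
        config.sim_nodes, model="preferential_attachment", seed=seed
    )
    rio.write_network(graph, out / "network.tsv")
    net_manifest.to_yaml(out / "network.manifest.yaml")

    import numpy as np

    rng = np.random.default_rng(seed + 1)
    nodes = sorted(graph.nodes)
    universe = {str(g) for g in rng.choice(nodes, size=min(config.sim_universe, len(nodes)), replace=False)}

    maps: list[DiseaseGeneMap] = []
    for i in range(config.sim_diseases):
        dm, dm_manifest = synthetic.gen_disease(
            graph,
            n_gwas=int(rng.integers(10, 41)),
            n_targets=int(rng.integers(10, 36)),
            proximity_bias=config.sim_proximity_bias,
            seed=seed + 100 + i,
            disease=f"synthetic disease {i:02d}",
            target_pool=universe,
        )
        maps.append(dm)
        dm_manifest.to_yaml(out / f"disease_{i:02d}.manifest.yaml")
    rio.write_disease_gene_map(maps, out / "gwas.tsv", out / "drugs.tsv")

    gwas_all = set().union(*(m.gwas_genes for m in maps))
    class_genes = {
        "drug_target": sorted(universe),
        "gwas_reported": sorted(gwas_all - universe),
        "all": sorted(set(nodes) - universe - gwas_all),
    }
    annotation, ann_manifest = synthetic.gen_annotation(class_genes, seed=seed + 2)
    rio.write_annotation(annotation, out / "annotation.tsv")
    ann_manifest.to_yaml(out / "annotation.manifest.yaml")

    tables = []
    for offset, (label, members) in enumerate(sorted(class_genes.items())):
        total_rate, common_rate = synthetic.DEFAULT_RATES[label]
        tab, v_manifest = synthetic.gen_variants(
            members,
            annotation["protein_length"],
            rate_per_residue=total_rate,
            common_fraction=common_rate / total_rate,
            n_individuals=config.sim_individuals,
            seed=seed + 1000 + offset,
        )
        tables.append(tab.df)
    combined = synthetic.VariantTable(pd.concat(tables, ignore_index=True))
    synthetic.write_vcf(combined, out / "variants.vcf", config.sim_individuals, seed=seed + 4)

    return {
        "gwas_table": str(out / "gwas.tsv"),
        "drug_table": str(out / "drugs.tsv"),
        "network_path": str(out / "network.tsv"),
        "vcf_path": str(out / "variants.vcf"),
        "annotation_path": str(out / "annotation.tsv"),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns a dict of key results.

    Every stage writes its TSVs under ``out_dir``; the resolved config and
    seed are echoed to ``config.yaml``; a markdown report summarises the
    per-stage tables.  A stage failure raises after logging the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": config.seed}
    report: list[str] = ["# Pipeline report", f"\nSeed: {config.seed}\n"]

    needs_network = bool({"network", "repurpose"} & set(config.stages))
    needs_variants = "variants" in config.stages
    inputs_missing = not (config.gwas_table and config.drug_table) or (
        needs_network and not config.network_path
    ) or (needs_variants and not config.annotation_path)
    if "simulate" in config.stages or inputs_missing:
        log.info("stage simulate")
        paths = simulate_inputs(config)
        for key, value in paths.items():
            if getattr(config, key) is None:
                setattr(config, key, value)

    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    maps, _ = rio.load_disease_gene_map(
        config.gwas_table, config.drug_table,
        alias_table=config.alias_table, split_merged=config.split_merged_diseases,
    )
    graph = None
    if config.network_path and (needs_network or "simulate" in config.stages):
        graph, _ = rio.load_network(config.network_path)
    annotation = rio.load_annotation(config.annotation_path) if config.annotation_path else None

    target_universe = set().union(*(m.target_genes for m in maps)) if maps else set()
    gwas_union = set().union(*(m.gwas_genes for m in maps)) if maps else set()

    if "overlap" in config.stages:
        log.info("stage overlap")
        summary = ovl.compute_overlap(
            maps, verified_only=config.verified_only, genome_size=config.genome_size
        )
        if config.locus_map:
            expanded = ovl.expand_candidates_by_locus(maps, rio.load_locus_map(config.locus_map))
            exp_summary = ovl.compute_overlap(expanded, genome_size=config.genome_size)
            exp_summary.to_frame().to_csv(out / "overlap_locus_expanded.tsv", sep="\t", index=False)
            results["overlap_expanded_total"] = exp_summary.total_observed
        summary.to_frame().to_csv(out / "overlap.tsv", sep="\t", index=False)
        results["overlap"] = summary
        report += [
            "## Overlap of GWAS genes and drug targets\n",
            f"- diseases: {summary.n_diseases}",
            f"- observed overlap instances: {summary.total_observed}",
            f"- unique overlapping genes: {summary.unique_overlapping_genes}",
            f"- expected under the random model: {summary.total_expected:.2f}",
            f"- mean observed per disease: {summary.mean_observed:.2f}\n",
        ]

    if "variants" in config.stages and annotation is not None:
        log.info("stage variants")
        classes = var.GeneClassAssignment(
            {"drug_target": target_universe, "gwas_reported": gwas_union}
        )
        rows = []
        density_by_class = {}
        if config.vcf_path:
            vtable, _ = rio.load_variants(config.vcf_path)
            universe_genes = set(annotation.index)
            for label in ("drug_target", "gwas_reported", "all"):
                dens = var.snp_density(
                    vtable, annotation, classes.members(label, universe_genes),
                    common_threshold=config.common_af_threshold, label=label,
                )
                density_by_class[label] = dens
                rows.append((label, len(dens.per_gene_all),
                             dens.density_all_nonsyn, dens.density_common_nonsyn))
            dens_df = pd.DataFrame(
                rows, columns=["class", "n_genes", "density_all_nonsyn", "density_common_nonsyn"]
            )
            if {"drug_target", "gwas_reported"} <= set(density_by_class):
                dtest = var.compare_gene_classes(
                    density_by_class["drug_target"].per_gene_common.values,
                    density_by_class["gwas_reported"].per_gene_common.values,
                )
                results["density_p_target_vs_gwas"] = dtest.pvalue
            dens_df.to_csv(out / "snp_density.tsv", sep="\t", index=False)
            results["density"] = dens_df

        length = var.longest_transcript_contrast(annotation, gwas_union, target_universe)
        pd.DataFrame(
            [("gwas_reported", length.mean_length_a, length.median_length_a),
             ("drug_target", length.mean_length_b, length.median_length_b)],
            columns=["class", "mean_longest_transcript", "median_longest_transcript"],
        ).to_csv(out / "transcript_length.tsv", sep="\t", index=False)
        results["length"] = length

        dnds_rows = []
        for ortho in ("mouse", "chimp"):
            for res in var.dnds_contrast(annotation, classes, ortholog=ortho):
                dnds_rows.append((ortho, res.label, res.n, res.mean_dnds,
                                  res.p_vs_all, res.p_vs_gwas))
        dnds_df = pd.DataFrame(
            dnds_rows,
            columns=["ortholog", "class", "n_genes", "mean_dnds", "p_vs_all", "p_vs_gwas"],
        )
        dnds_df.to_csv(out / "dnds.tsv", sep="\t", index=False)
        results["dnds"] = dnds_df
        report += [
            "## Variant, length and selection contrasts\n",
            f"- transcript length (GWAS vs targets): means "
            f"{length.mean_length_a:.0f} vs {length.mean_length_b:.0f}, "
            f"p = {length.test.pvalue:.3g}\n",
        ]

    if "network" in config.stages:
        log.info("stage network")
        gwas_mapped = gwas_union & set(graph.nodes)
        targets_mapped = target_universe & set(graph.nodes)
        prof_rows = []
        if targets_mapped:
            for desc, queries in (
                ("gwas_to_nearest_target", gwas_mapped),
                ("all_to_nearest_target", set(graph.nodes)),
            ):
                prof = net.distance_to_set(graph, queries, targets_mapped, desc)
                prof_rows.append((desc, len(prof.distances), prof.mean_distance,
                                  len(prof.unreachable)))
            enr1 = net.neighbor_enrichment(graph, gwas_mapped, targets_mapped, order=1)
            enr2 = net.neighbor_enrichment(graph, gwas_mapped, targets_mapped, order=2)
            deg = net.degree_contrast(graph, targets_mapped)
            pd.DataFrame(
                prof_rows, columns=["profile", "n_reachable", "mean_distance", "n_unreachable"]
            ).to_csv(out / "distance_profiles.tsv", sep="\t", index=False)
            pd.DataFrame(
                [(e.order, e.neighborhood_size, e.neighborhood_fraction,
                  e.background_fraction, e.fold_enrichment) for e in (enr1, enr2)],
                columns=["order", "neighborhood_size", "neighborhood_fraction",
                         "background_fraction", "fold_enrichment"],
            ).to_csv(out / "neighbor_enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = (enr1, enr2)
            results["degree_p"] = deg.test.pvalue
            report += [
                "## Network proximity\n",
                f"- target fold enrichment in GWAS first neighbors: {enr1.fold_enrichment:.2f}",
                f"- in second neighbors: {enr2.fold_enrichment:.2f}",
                f"- degree contrast p (targets vs all): {deg.test.pvalue:.3g}\n",
            ]

    if "repurpose" in config.stages:
        log.info("stage repurpose")
        eligible = ml.eligible_diseases(maps, graph, config.min_targets, config.min_gwas)
        if config.max_ml_diseases:
            eligible = eligible[: config.max_ml_diseases]
        universe_mapped = target_universe & set(graph.nodes)
        target_diseases: dict[str, tuple[str, ...]] = {}
        for dm in maps:
            for g in dm.target_genes:
                target_diseases[g] = tuple(sorted(set(target_diseases.get(g, ())) | {dm.disease}))
        metric_rows = []
        by_disease = {m.disease: m for m in maps}
        for disease in eligible:
            dm = by_disease[disease]
            matrix = ml.build_feature_matrix(
                graph, dm.gwas_genes, universe_mapped, dm.target_genes
            )
            cfg = ml.RFConfig(trees=config.rf_trees, folds=config.cv_folds, seed=config.seed)
            metrics = ml.metacost_train_evaluate(matrix, cfg, disease=disease)
            cands = ml.rank_repurposing_candidates(
                metrics, matrix, config.probability_threshold, target_diseases
            )
            slug = "".join(c if c.isalnum() else "_" for c in disease)
            pd.DataFrame(
                [(c.gene, c.probability, ";".join(c.already_target_for)) for c in cands],
                columns=["gene", "probability", "already_target_for"],
            ).to_csv(out / f"candidates_{slug}.tsv", sep="\t", index=False)
            matrix.features.assign(is_target=matrix.labels).to_csv(
                out / f"features_{slug}.tsv", sep="\t"
            )
            metric_rows.append(
                (disease, len(matrix.gwas_genes), int(matrix.labels.sum()),
                 metrics.true_positive_rate, metrics.false_positive_rate,
                 metrics.precision, metrics.recall, metrics.roc_area, metrics.f_measure)
            )
        metrics_df = pd.DataFrame(
            metric_rows,
            columns=["disease", "n_gwas_mapped", "n_targets_mapped", "tp_rate", "fp_rate",
                     "precision", "recall", "roc_area", "f_measure"],
        )
        metrics_df.to_csv(out / "ml_metrics.tsv", sep="\t", index=False)
        results["ml_metrics"] = metrics_df
        report += ["## Repurposing classifier (10-fold CV)\n",
                   metrics_df.to_string(index=False), ""]

    (out / "report.md").write_text("\n".join(report), encoding="utf-8")
    return results
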