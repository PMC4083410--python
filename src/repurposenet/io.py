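"""Readers and writers for the tabular formats the pipeline consumes.

All tables are tab-delimited UTF-8 with a header row.  Variant input is
VCF 4.x read through cyvcf2; networks are two-column edge lists or SIF.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from cyvcf2 import VCF

from .types import (
    DiseaseGeneMap,
    LocusMap,
    VariantRecord,
    VariantTable,
    normalize_disease,
    normalize_gene_id,
)

log = logging.getLogger(__name__)


@dataclass
class LoadReport:
    """Counts of records dropped or merged during a load."""

    dropped_unmapped_genes: int = 0
    self_loops_removed: int = 0
    duplicate_edges_removed: int = 0
    sites_skipped_no_genotypes: int = 0
    merged_disease_rows: int = 0
    notes: list[str] = field(default_factory=list)


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping raw gene tokens to canonical IDs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: alias table needs two columns (raw, canonical)")
    raw_col, canon_col = df.columns[:2]
    return {
        normalize_gene_id(r): normalize_gene_id(c)
        for r, c in zip(df[raw_col], df[canon_col])
        if pd.notna(r) and pd.notna(c)
    }


def _canonical(raw: str, alias: dict[str, str] | None) -> str | None:
    """Map a raw token to its canonical GeneID; None if unmappable."""
    tok = normalize_gene_id(raw)
    if not tok:
        return None
    if alias is None:
        return tok
    return alias.get(tok)  # unmapped IDs are dropped, never guessed


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def load_disease_gene_map(
    gwas_table: str | Path,
    drug_table: str | Path,
    alias_table: str | Path | None = None,
    split_merged: bool = False,
) -> tuple[list[DiseaseGeneMap], LoadReport]:
    """Join a disease->GWAS-gene table with a disease->drug->target table.

    Returns one :class:`DiseaseGeneMap` per disease present in BOTH tables.
    Duplicate disease rows are merged by set union.  ``split_merged`` treats
    a "A/B" trait label as two disease units sharing its gene sets.
    """
    alias = load_alias_table(alias_table) if alias_table is not None else None
    report = LoadReport()

    gwas = pd.read_csv(gwas_table, sep="\t", dtype=str)
    _require_columns(gwas, ["disease", "gene"], gwas_table)
    drugs = pd.read_csv(drug_table, sep="\t", dtype=str)
    _require_columns(drugs, ["disease", "drug", "target"], drug_table)
    has_verified = "verified" in drugs.columns

    def disease_keys(label: str) -> list[tuple[str, str]]:
        label = str(label)
        parts = label.split("/") if split_merged else [label]
        return [(normalize_disease(p), normalize_gene_id(p)) for p in parts if p.strip()]

    gwas_sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    seen_rows: set[tuple[str, str]] = set()
    for _, row in gwas.iterrows():
        gene = _canonical(row["gene"], alias)
        if gene is None:
            report.dropped_unmapped_genes += 1
            continue
        for key, name in disease_keys(row["disease"]):
            if (key, gene) in seen_rows and key in gwas_sets:
                report.merged_disease_rows += 1
            seen_rows.add((key, gene))
            names.setdefault(key, name)
            gwas_sets.setdefault(key, set()).add(gene)

    drug_sets: dict[str, set[str]] = {}
    target_sets: dict[str, set[str]] = {}
    verified_sets: dict[str, set[str]] = {}
    for _, row in drugs.iterrows():
        gene = _canonical(row["target"], alias)
        if gene is None:
            report.dropped_unmapped_genes += 1
            continue
        for key, name in disease_keys(row["disease"]):
            names.setdefault(key, name)
            drug_sets.setdefault(key, set()).add(normalize_gene_id(row["drug"]))
            target_sets.setdefault(key, set()).add(gene)
            if has_verified and str(row.get("verified", "")).strip().lower() in {"yes", "y", "true", "1"}:
                verified_sets.setdefault(key, set()).add(gene)

    maps = [
        DiseaseGeneMap(
            disease=names[key],
            gwas_genes=gwas_sets[key],
            drugs=drug_sets.get(key, set()),
            target_genes=target_sets.get(key, set()),
            verified_targets=verified_sets.get(key, set()),
        )
        for key in sorted(gwas_sets)
        if key in target_sets  # diseases present in both tables
    ]
    log.info("loaded %d diseases (%d unmapped gene tokens dropped)",
             len(maps), report.dropped_unmapped_genes)
    return maps, report


def write_disease_gene_map(
    maps: list[DiseaseGeneMap], gwas_table: str | Path, drug_table: str | Path
) -> None:
    """Inverse of :func:`load_disease_gene_map` (drug rows repeat per target)."""
    grows = [(m.disease, g) for m in maps for g in sorted(m.gwas_genes)]
    pd.DataFrame(grows, columns=["disease", "gene"]).to_csv(gwas_table, sep="\t", index=False)
    drows = []
    for m in maps:
        if not m.target_genes:
            continue  # no target rows to carry; disease drops from the join anyway
        drug_list = sorted(m.drugs) or ["NA"]
        targets = sorted(m.target_genes)
        for t in targets:
            drows.append((m.disease, drug_list[0], t,
                          "Yes" if t in m.verified_targets else "No"))
        for extra in drug_list[1:]:
            drows.append((m.disease, extra, targets[0], "No"))
    pd.DataFrame(drows, columns=["disease", "drug", "target", "verified"]).to_csv(
        drug_table, sep="\t", index=False
    )


def load_network(edge_list: str | Path) -> tuple[nx.Graph, LoadReport]:
    """Load an undirected, unweighted, deduplicated gene network.

    Accepts a two-column TSV (with or without header) or a three-column SIF
    (``a  interaction  b``).  Self-loops are discarded and counted.
    """
    report = LoadReport()
    graph = nx.Graph()
    path = Path(edge_list)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                a, b = parts
            elif len(parts) >= 3:
                a, b = parts[0], parts[2]  # SIF: source, relation, target
            else:
                raise ValueError(f"{path}:{lineno}: unreadable edge line {line!r}")
            a, b = normalize_gene_id(a), normalize_gene_id(b)
            if lineno == 1 and {a.lower(), b.lower()} & {"gene_a", "source", "node1", "gene1"}:
                continue  # header row
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene token")
            if a == b:
                report.self_loops_removed += 1
                continue
            if graph.has_edge(a, b):
                report.duplicate_edges_removed += 1
                continue
            graph.add_edge(a, b)
    if report.self_loops_removed:
        log.info("removed %d self-loops from %s", report.self_loops_removed, path)
    return graph, report


def write_network(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def load_variants(
    vcf: str | Path,
    nonsyn_filter: str = "NSYN",
    gene_tag: str = "GENE",
    alias_table: str | Path | None = None,
) -> tuple[VariantTable, LoadReport]:
    """Extract non-synonymous sites from a VCF with per-sample genotypes.

    A site is kept when INFO carries the ``nonsyn_filter`` flag and a gene
    under ``gene_tag``.  The allele frequency is the alternate allele count
    over the called allele count (ploidy 2; half-missing genotypes contribute
    only their called alleles to numerator and denominator).
    """
    alias = load_alias_table(alias_table) if alias_table is not None else None
    report = LoadReport()
    records: list[VariantRecord] = []
    reader = VCF(str(vcf))
    try:
        for var in reader:
            if var.INFO.get(nonsyn_filter) is None:
                continue
            gene_raw = var.INFO.get(gene_tag)
            if gene_raw is None:
                continue
            gene = _canonical(str(gene_raw), alias)
            if gene is None:
                report.dropped_unmapped_genes += 1
                continue
            alt = called = 0
            for gt in var.genotypes:  # [allele0, allele1, phased]
                for allele in gt[:-1]:
                    if allele >= 0:
                        called += 1
                        if allele > 0:
                            alt += 1
            if called == 0:
                report.sites_skipped_no_genotypes += 1
                log.info("skipping %s:%s — no called genotypes", var.CHROM, var.POS)
                continue
            records.append(
                VariantRecord(
                    gene=gene,
                    key=f"{var.CHROM}:{var.POS}:{var.REF}:{','.join(var.ALT)}",
                    alt_allele_count=alt,
                    total_allele_count=called,
                )
            )
    finally:
        reader.close()
    return VariantTable(records), report


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV: gene, protein_length, longest_transcript_length,
    dnds_mouse, dnds_chimp (the latter two optional; blanks stay missing)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "protein_length", "longest_transcript_length"], path)
    df["gene"] = df["gene"].map(normalize_gene_id)
    df = df.set_index("gene")
    for col in ("dnds_mouse", "dnds_chimp"):
        if col not in df.columns:
            df[col] = float("nan")
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=True)


def load_locus_map(path: str | Path) -> LocusMap:
    """Locus TSV: locus_id, gene, and optionally disease."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["locus_id", "gene"], path)
    loci: dict[str, set[str]] = {}
    disease_loci: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        gene = normalize_gene_id(row["gene"])
        if not gene or pd.isna(row["gene"]):
            raise ValueError(f"{path}: locus {row['locus_id']!r} row with empty gene")
        loci.setdefault(str(row["locus_id"]), set()).add(gene)
        if "disease" in df.columns and pd.notna(row["disease"]):
            disease_loci.setdefault(normalize_disease(row["disease"]), set()).add(str(row["locus_id"]))
    return LocusMap(loci=loci, disease_loci=disease_loci)
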