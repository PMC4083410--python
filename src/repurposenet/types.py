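"""Shared domain types.

Gene identifiers are plain normalized string tokens; collections of genes
are python sets.  Tabular payloads (variants, annotations, features) are
pandas objects so the statistical stages can operate on them directly.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

_WS = re.compile(r"\s+")


def normalize_gene_id(raw: str) -> str:
    """Collapse whitespace and strip a raw gene token.

    Idempotent: ``normalize_gene_id(normalize_gene_id(x)) == normalize_gene_id(x)``.
    """
    return _WS.sub(" ", str(raw).strip())


def normalize_disease(raw: str) -> str:
    """Matching key for disease labels: whitespace-collapsed, case-insensitive."""
    return _WS.sub(" ", str(raw).strip()).casefold()


@dataclass
class DiseaseGeneMap:
    """Per-disease GWAS reported genes and drug-target genes.

    ``m = len(gwas_genes)`` and ``n = len(target_genes)`` are the counts the
    random-overlap null model is built from.
    """

    disease: str
    gwas_genes: set[str] = field(default_factory=set)
    drugs: set[str] = field(default_factory=set)
    target_genes: set[str] = field(default_factory=set)
    verified_targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.verified_targets <= self.target_genes:
            raise ValueError(
                f"{self.disease!r}: verified_targets must be a subset of target_genes"
            )

    @property
    def m(self) -> int:
        return len(self.gwas_genes)

    @property
    def n(self) -> int:
        return len(self.target_genes)


@dataclass
class VariantRecord:
    """One non-synonymous variant site with genotype-derived allele frequency."""

    gene: str
    key: str
    alt_allele_count: int
    total_allele_count: int

    def __post_init__(self) -> None:
        if self.total_allele_count <= 0:
            raise ValueError(f"{self.key}: total_allele_count must be > 0")
        if not 0 <= self.alt_allele_count <= self.total_allele_count:
            raise ValueError(f"{self.key}: alt allele count outside [0, total]")

    @property
    def allele_frequency(self) -> float:
        return self.alt_allele_count / self.total_allele_count


class VariantTable:
    """Collection of :class:`VariantRecord` backed by a DataFrame.

    Columns: gene, key, alt_allele_count, total_allele_count, allele_frequency.
    """

    COLUMNS = ["gene", "key", "alt_allele_count", "total_allele_count", "allele_frequency"]

    def __init__(self, records: Iterable[VariantRecord] | pd.DataFrame = ()) -> None:
        if isinstance(records, pd.DataFrame):
            df = records.copy()
            if "allele_frequency" not in df.columns and len(df):
                df["allele_frequency"] = df.alt_allele_count / df.total_allele_count
            for col in self.COLUMNS:
                if col not in df.columns:
                    df[col] = pd.Series(dtype=float)
            self.df = df[self.COLUMNS].reset_index(drop=True)
        else:
            rows = [
                (r.gene, r.key, r.alt_allele_count, r.total_allele_count, r.allele_frequency)
                for r in records
            ]
            self.df = pd.DataFrame(rows, columns=self.COLUMNS)

    def __len__(self) -> int:
        return len(self.df)

    def dedup(self) -> "VariantTable":
        """Drop duplicate records for the same site key (first kept)."""
        return VariantTable(self.df.drop_duplicates(subset="key"))

    def for_genes(self, genes: set[str]) -> "VariantTable":
        return VariantTable(self.df[self.df.gene.isin(genes)])


@dataclass
class LocusMap:
    """Locus key -> candidate genes in linkage disequilibrium with the marker."""

    loci: dict[str, set[str]] = field(default_factory=dict)
    # disease -> locus keys mapped for that disease
    disease_loci: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, genes in self.loci.items():
            if not genes:
                raise ValueError(f"locus {key!r} has no candidate genes")

    def genes_for_disease(self, disease: str) -> set[str]:
        out: set[str] = set()
        for key in self.disease_loci.get(normalize_disease(disease), set()):
            out |= self.loci[key]
        return out


def make_annotation(
    genes: Iterable[str],
    protein_length: Mapping[str, float] | pd.Series,
    longest_transcript_length: Mapping[str, float] | pd.Series,
    dnds_mouse: Mapping[str, float] | pd.Series | None = None,
    dnds_chimp: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble a gene annotation table (index: gene).

    Missing dN/dS stays NaN — never coerced to 0.  Lengths must be strictly
    positive for every annotated gene.
    """
    idx = pd.Index([normalize_gene_id(g) for g in genes], name="gene")
    df = pd.DataFrame(index=idx)
    df["protein_length"] = pd.Series(protein_length).reindex(idx)
    df["longest_transcript_length"] = pd.Series(longest_transcript_length).reindex(idx)
    df["dnds_mouse"] = pd.Series(dnds_mouse).reindex(idx) if dnds_mouse is not None else float("nan")
    df["dnds_chimp"] = pd.Series(dnds_chimp).reindex(idx) if dnds_chimp is not None else float("nan")
    for col in ("protein_length", "longest_transcript_length"):
        bad = df[col].dropna() <= 0
        if bad.any():
            raise ValueError(f"{col} must be strictly positive; offending genes: "
                             f"{list(df[col].dropna()[bad].index[:5])}")
    return df
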