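"""GWAS-gene / drug-target overlap and the random null model.

For a disease with m GWAS reported genes and n drug-target genes drawn
from a genome of G genes, the expected overlap under independent random
draws is m*n/G (G defaults to 20,000 protein-coding genes).  The summary
total is the sum of the per-disease expectations.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd

from .types import DiseaseGeneMap, LocusMap, normalize_disease

DEFAULT_GENOME_SIZE = 20_000


def expected_random_overlap(m: int, n: int, genome_size: int = DEFAULT_GENOME_SIZE) -> float:
    """Expected chance overlap of an m-gene and an n-gene set: m*n/G."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if m < 0 or n < 0:
        raise ValueError("set sizes must be non-negative")
    return m * n / genome_size


@dataclass
class OverlapRecord:
    disease: str
    m: int
    n: int
    observed_overlap: int
    expected_overlap: float
    overlapping_genes: set[str] = field(default_factory=set)


@dataclass
class OverlapSummary:
    records: list[OverlapRecord]
    total_observed: int
    total_expected: float
    mean_observed: float
    unique_overlapping_genes: int
    n_diseases: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.disease, r.m, r.n, r.observed_overlap, r.expected_overlap,
             ";".join(sorted(r.overlapping_genes)))
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=["disease", "n_gwas_genes", "n_drug_targets",
                     "observed_overlap", "expected_overlap", "overlapping_genes"],
        )


def compute_overlap(
    maps: list[DiseaseGeneMap],
    verified_only: bool = False,
    genome_size: int = DEFAULT_GENOME_SIZE,
    n_diseases: int | None = None,
) -> OverlapSummary:
    """Per-disease intersection of GWAS genes with drug targets, plus the
    random-model expectation.

    ``n_diseases`` overrides the denominator of ``mean_observed`` when a
    table row stands for several merged disease units (a curated table may
    publish fewer rows than disease units); default is the record count.
    The unique gene count deduplicates overlapping genes across diseases.
    """
    records: list[OverlapRecord] = []
    union: set[str] = set()
    for dm in maps:
        targets = dm.verified_targets if verified_only else dm.target_genes
        inter = dm.gwas_genes & targets
        records.append(
            OverlapRecord(
                disease=dm.disease,
                m=dm.m,
                n=len(targets),
                observed_overlap=len(inter),
                expected_overlap=expected_random_overlap(dm.m, len(targets), genome_size),
                overlapping_genes=inter,
            )
        )
        union |= inter
    total = sum(r.observed_overlap for r in records)
    denom = n_diseases if n_diseases is not None else len(records)
    return OverlapSummary(
        records=records,
        total_observed=total,
        total_expected=sum(r.expected_overlap for r in records),
        mean_observed=total / denom if denom else 0.0,
        unique_overlapping_genes=len(union),
        n_diseases=denom,
    )


def expand_candidates_by_locus(
    maps: list[DiseaseGeneMap], loci: LocusMap
) -> list[DiseaseGeneMap]:
    """Replace each disease's GWAS set with its union with all genes in the
    disease's linkage-disequilibrium loci (candidate expansion).

    Gene counts are monotonically non-decreasing; diseases without loci are
    returned unchanged (deep-copied).
    """
    out: list[DiseaseGeneMap] = []
    for dm in maps:
        dm2 = copy.deepcopy(dm)
        dm2.gwas_genes = dm.gwas_genes | loci.genes_for_disease(normalize_disease(dm.disease))
        out.append(dm2)
    return out
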