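"""Packaged reference data.

``table1_overlap.tsv`` transcribes the published per-disease summary of
GWAS reported genes vs drug targets (84 table rows standing for 88 disease
units once merged trait rows are counted separately; the published per-
disease means use the 88 denominator).  The final 'Mean' row is carried
verbatim but excluded from data rows.

Because the underlying gene lists are not deposited, :func:`table1_disease_
gene_maps` expands the counts into deterministic synthetic gene sets that
reproduce every printed margin: per-disease set sizes, the per-disease
overlap column, and the cross-disease sharing pattern in which three
overlapping genes are each drug targets for two different diseases (23
overlap instances over 20 unique genes).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import DiseaseGeneMap

#: Disease units behind the printed rows (merged trait rows count separately).
TABLE1_N_DISEASES = 88

# overlap-instance slots that reuse an earlier slot's gene: three genes are
# drug targets for two diseases each, so 23 instances -> 20 unique genes.
_SHARED_SLOTS = {20: 0, 21: 1, 22: 2}


def load_table1() -> pd.DataFrame:
    """The packaged overlap table, data rows only (no 'Mean' row)."""
    ref = resources.files("repurposenet.data") / "table1_overlap.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df = df[df.disease != "Mean"].reset_index(drop=True)
    for col in ("n_drugs", "n_gwas_genes", "n_drug_targets", "overlap_same_disease"):
        df[col] = df[col].astype(int)
    return df


def _slug(disease: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in disease)


def table1_disease_gene_maps() -> list[DiseaseGeneMap]:
    """Deterministic gene-set expansion of the overlap table.

    Overlap slot j (enumerated in table row order) is filled with the shared
    pool gene ``OVLkk``; the three designated late slots reuse the first
    three pool genes, which lands the reused genes in three distinct
    diseases.  Non-overlapping positions are filled with disease-scoped
    filler tokens, so |gwas|, |targets| and |gwas & targets| match the
    printed columns row by row.
    """
    df = load_table1()
    maps: list[DiseaseGeneMap] = []
    slot = 0
    pool: list[str] = []
    for row in df.itertuples():
        overlap_genes: set[str] = set()
        for _ in range(row.overlap_same_disease):
            if slot in _SHARED_SLOTS:
                gene = pool[_SHARED_SLOTS[slot]]
            else:
                gene = f"OVL{len(pool):02d}"
                pool.append(gene)
            overlap_genes.add(gene)
            slot += 1
        slug = _slug(row.disease)
        gwas = overlap_genes | {
            f"{slug}__gwas{i:03d}" for i in range(row.n_gwas_genes - len(overlap_genes))
        }
        targets = overlap_genes | {
            f"{slug}__tgt{i:03d}" for i in range(row.n_drug_targets - len(overlap_genes))
        }
        drugs = {f"{slug}__drug{i:03d}" for i in range(row.n_drugs)}
        maps.append(
            DiseaseGeneMap(
                disease=row.disease, gwas_genes=gwas, drugs=drugs, target_genes=targets
            )
        )
    return maps
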