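"""SNP-density, transcript-length and dN/dS contrasts between gene classes.

Densities are per-gene counts of non-synonymous sites divided by protein
length in residues; "common" sites are those with allele frequency strictly
above the threshold (default 5%).  Class contrasts use the two-sample
Mann-Whitney rank-sum test (exact on small samples, normal approximation
with tie/continuity correction otherwise); p-values are reported raw.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import VariantTable

log = logging.getLogger(__name__)

COMMON_AF_THRESHOLD = 0.05
SMALL_SAMPLE = 8  # per-sample size below which the exact null is enumerated


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    warning: str | None = None


@dataclass
class DensityResult:
    """Per-gene nsSNP densities for one gene class and their means."""

    label: str
    per_gene_all: pd.Series          # all-nsSNP density, indexed by gene
    per_gene_common: pd.Series       # common-nsSNP density, indexed by gene
    density_all_nonsyn: float
    density_common_nonsyn: float
    excluded_no_length: int = 0
    pooled: bool = False


@dataclass
class GeneClassAssignment:
    """Gene class membership: every gene belongs to 'all'; the named classes
    (drug_target, gwas_reported, hgmd, ...) are independent overlays."""

    classes: dict[str, set[str]] = field(default_factory=dict)

    def members(self, label: str, universe: set[str]) -> set[str]:
        if label == "all":
            return set(universe)
        return self.classes.get(label, set()) & universe


def snp_density(
    variants: VariantTable,
    annotation: pd.DataFrame,
    genes: set[str],
    common_threshold: float = COMMON_AF_THRESHOLD,
    label: str = "",
    pooled: bool = False,
) -> DensityResult:
    """Per-gene nsSNP densities for ``genes``: sites/protein_length, with a
    common-variant density restricted to AF > ``common_threshold``.

    Genes with no variants get density 0; genes with no protein length are
    excluded (counted).  ``pooled`` reports total sites / total residues
    instead of the unweighted per-gene mean.
    """
    lengths = annotation["protein_length"].dropna()
    usable = sorted(g for g in genes if g in lengths.index)
    excluded = len(genes) - len(usable)
    if excluded:
        log.info("snp_density(%s): excluded %d genes lacking protein length", label, excluded)

    table = variants.dedup().for_genes(set(usable)).df
    n_all = table.groupby("gene").size()
    n_common = table[table.allele_frequency > common_threshold].groupby("gene").size()
    idx = pd.Index(usable, name="gene")
    length_vec = lengths.reindex(idx)
    per_all = (n_all.reindex(idx).fillna(0) / length_vec).astype(float)
    per_common = (n_common.reindex(idx).fillna(0) / length_vec).astype(float)

    if pooled:
        total_len = float(length_vec.sum())
        mean_all = float(n_all.reindex(idx).fillna(0).sum() / total_len) if total_len else 0.0
        mean_common = float(n_common.reindex(idx).fillna(0).sum() / total_len) if total_len else 0.0
    else:
        mean_all = float(per_all.mean()) if len(per_all) else 0.0
        mean_common = float(per_common.mean()) if len(per_common) else 0.0

    return DensityResult(
        label=label,
        per_gene_all=per_all,
        per_gene_common=per_common,
        density_all_nonsyn=mean_all,
        density_common_nonsyn=mean_common,
        excluded_no_length=excluded,
        pooled=pooled,
    )


def compare_gene_classes(
    values_a, values_b, paired: bool = False
) -> TestResult:
    """Two-sided rank test for a location shift between two gene classes.

    Unpaired (default): Mann-Whitney U, exact when both samples are small
    and tie-free.  ``paired`` switches to the Wilcoxon signed-rank test on
    matched values (samples must then have equal length).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    warning = None
    if min(a.size, b.size) < 2:
        warning = "small-sample: fewer than 2 observations in a class"
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length samples")
        if np.allclose(a, b):
            return TestResult(0.0, 1.0, a.size, b.size, warning)
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue), a.size, b.size, warning)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any shift
        return TestResult(a.size * b.size / 2.0, 1.0, a.size, b.size, warning)
    method = "exact" if (max(a.size, b.size) <= SMALL_SAMPLE and not _has_ties(a, b)) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input warnings on degenerate samples
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), a.size, b.size, warning)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


@dataclass
class LengthContrast:
    log_lengths_a: pd.Series
    log_lengths_b: pd.Series
    mean_length_a: float
    mean_length_b: float
    median_length_a: float
    median_length_b: float
    test: TestResult


def longest_transcript_contrast(
    annotation: pd.DataFrame, class_a: set[str], class_b: set[str], paired: bool = False
) -> LengthContrast:
    """Longest-transcript length distributions for two classes plus a rank
    test; lengths are also reported on the log10 scale for plotting."""
    lengths = annotation["longest_transcript_length"].dropna()
    la = lengths[lengths.index.isin(class_a)]
    lb = lengths[lengths.index.isin(class_b)]
    test = compare_gene_classes(la.values, lb.values, paired=paired)
    return LengthContrast(
        log_lengths_a=np.log10(la),
        log_lengths_b=np.log10(lb),
        mean_length_a=float(la.mean()),
        mean_length_b=float(lb.mean()),
        median_length_a=float(la.median()),
        median_length_b=float(lb.median()),
        test=test,
    )


@dataclass
class DndsClassResult:
    label: str
    n: int
    mean_dnds: float
    p_vs_all: float | None
    p_vs_gwas: float | None


def dnds_contrast(
    annotation: pd.DataFrame,
    classes: GeneClassAssignment,
    ortholog: str = "chimp",
    gwas_label: str = "gwas_reported",
) -> list[DndsClassResult]:
    """Per-class mean dN/dS for one ortholog pair ('mouse' or 'chimp') with
    Mann-Whitney tests of each class against all genes and against the GWAS
    class.  Genes missing the requested ratio are excluded; classes left
    with fewer than 2 annotated genes are skipped with a warning."""
    if ortholog not in {"mouse", "chimp"}:
        raise ValueError("ortholog must be 'mouse' or 'chimp'")
    col = f"dnds_{ortholog}"
    ratios = annotation[col].dropna()
    universe = set(ratios.index)
    all_vals = ratios.values
    gwas_vals = ratios[ratios.index.isin(classes.members(gwas_label, universe))].values

    results = [DndsClassResult("all", len(all_vals), float(np.mean(all_vals)), None, None)]
    for label in classes.classes:
        vals = ratios[ratios.index.isin(classes.members(label, universe))].values
        if vals.size < 2:
            log.warning("dnds_contrast: class %r has <2 annotated genes; skipped", label)
            continue
        p_all = compare_gene_classes(vals, all_vals).pvalue
        p_gwas = None
        if label != gwas_label and gwas_vals.size >= 2:
            p_gwas = compare_gene_classes(vals, gwas_vals).pvalue
        results.append(DndsClassResult(label, vals.size, float(np.mean(vals)), p_all, p_gwas))
    return results
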