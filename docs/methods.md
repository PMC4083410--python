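# Methods

## Scope and model

`repurposenet` asks how much of the druggable genome genome-wide
association studies rediscover, why the direct overlap is small, and
whether the protein-interaction-network context of a disease's GWAS genes
is enough to recover (and extend) its known drug targets. The pipeline has
four statistical stages over shared domain objects (per-disease gene sets,
an undirected interaction network, a non-synonymous variant table, and a
per-gene annotation table), plus a synthetic-data generator that emulates
all four inputs so every stage is testable without external downloads.

### Overlap and the random null

For a disease with `m` GWAS reported genes and `n` drug-target genes, the
expected chance overlap under independent draws from a genome of `G` genes
is `m·n/G`, with `G = 20,000` by default (configurable). Summary totals sum
the per-disease expectations; the deduplicated overlapping-gene count
collapses genes that are targets for several diseases. The packaged
per-disease table reproduces the published margins: 23 observed overlap
instances, 20 unique genes, mean 0.26 per disease unit (88 units behind 84
printed rows), expected total 5.62. Locus expansion replaces a disease's
reported genes by the union with all genes in its linkage-disequilibrium
loci; the locus→gene map is an input, never computed from genotypes.

### Variant, length and selection contrasts

Per-gene non-synonymous SNP density is the deduplicated site count divided
by protein length in residues; the *common* density keeps sites with
allele frequency strictly above 5%. Allele frequencies come from diploid
genotypes: alternate allele count over called allele count (half-missing
genotypes contribute only their called alleles). Class contrasts (drug
targets vs GWAS reported vs all genes) use the two-sample Mann-Whitney
rank-sum test — exact by enumeration when both samples have ≤ 8
observations and no ties, otherwise the normal approximation with tie and
continuity corrections; p-values are reported raw (no multiple-testing
correction, matching how such contrasts are conventionally tabulated).
Class means are unweighted per-gene averages, with a pooled
(total-sites/total-residues) mode available. Transcript-length contrasts
compare longest-transcript lengths (log10 scale retained for plotting);
dN/dS contrasts run separately for human–mouse and human–chimpanzee
ortholog ratios, excluding genes whose ratio is missing (missing is never
coerced to 0).

### Network proximity

The interaction network is undirected, unweighted, deduplicated and
self-loop free. All-pairs distances use repeated breadth-first search,
which is exact on unweighted graphs and memory-safe at the ~11k-node scale
of curated functional-interaction maps; a dense numpy min-plus
Floyd-Warshall engine is retained purely as an independent verification
route and is checked to agree exactly on random graphs. Distance-to-set
profiles report each query gene's shortest distance to the nearest member
of a reference set; unreachable queries appear as a separate histogram bin
and never enter means. Neighborhood enrichment compares the fraction of a
gene class among the order-1 (direct neighbors, seeds excluded) or order-2
(shortest distance exactly 2) neighborhood of a seed set against the
network-wide class fraction; a uniform permutation null (mean fold → 1) is
provided because degree structure can inflate raw folds, and a degree
contrast (class vs all nodes, rank-sum) quantifies that confounder.
Linker subnetworks keep both gene sets plus any gene on a path of length
≤ `max_intermediates + 1` between two distinct kept genes.

### Repurposing classifier

Candidates are the drug-target universe mapped to the network — the
restricted task is ranking *existing* targets for a new disease, which
sidesteps the extreme imbalance of scoring the whole genome. Each
candidate gene gets `3 + N` features: GWAS first-neighbor count, degree,
count of GWAS genes at shortest distance exactly 2, and one
common-neighbor score per mapped GWAS gene (Jaccard index of neighbor
sets, 0 when both sets are empty), in sorted gene-ID column order.
Training is cost-sensitive: within each of 10 stratified CV folds, a
MetaCost step estimates class probabilities with 10 bagged unrestricted
CART trees and relabels each training point to the class minimising
expected cost under C(false negative) = cost_ratio, C(false positive) = 1,
with cost_ratio defaulting to #negatives/#positives; a random forest with
I = 50 trees and K = ⌊√(3+N)⌋ features per split is then fit on the
relabeled fold. Out-of-fold probabilities yield threshold-0.5 confusion
metrics, the ROC area, and the repurposing ranking: label-negative genes
with probability ≥ 0.5, descending, ties broken by gene ID. Fold
assignment, bagging and forests all derive from one run seed, and rows are
canonicalised by gene ID so metrics are invariant to input row order.
Unrestricted trees (rather than K-restricted ones) in the MetaCost bags
matter: restricted trees produce noisy probability estimates that
mislabel clean negatives even on perfectly separable data.

## Synthetic data: what it emulates, what it does not

Generator defaults are the study conditions the contrasts are tested
under:

| quantity | drug targets | GWAS genes | all genes |
|---|---|---|---|
| all-nsSNP density (/residue) | 0.0155 | 0.0171 | 0.0171 |
| common-nsSNP density (/residue) | 0.00169 | 0.00221 | 0.00214 |
| transcript-length median (bases, log-normal, σ=1) | 60,000 | 110,000 | 60,000 |
| dN/dS mean, human–chimp (gamma, shape 4) | 0.33 | 0.36 | 0.44 |
| dN/dS mean, human–mouse | 0.18 | 0.19 | 0.22 |

Variant counts are Poisson(rate × protein length); a planted fraction of
sites draws an allele count strictly above the 5% threshold. Protein
lengths are log-normal (median 450 residues, σ=0.6). The gamma shape 4
keeps the dN/dS coefficient of variation at 0.5, tight enough that
catalog-scale class sizes separate the planted means reliably; σ=1 on log
transcript length reflects the order-of-magnitude spread of real
transcripts. Networks are preferential-attachment by default (scale-free
degree profile), with planted-module and fixed-edge-count models for
structural tests. A disease is planted by taking a breadth-first ball of
GWAS genes around a random node and sampling targets with weight
exp(−bias·d) where d is distance to the nearest GWAS gene; bias 0 is
uniform sampling and bias 8 (the strong-coupling regime) puts essentially
all targets adjacent to GWAS genes.

The planted-disease classifier benchmark uses a 2000-node network with
edges_per_node = 3, 20 GWAS genes, 30 positives in a 900-gene universe,
bias 8. The edge density is calibrated so the GWAS set's first-neighbor
shell covers ~15% of the network — comparable, relative to network size,
with a 20-gene set's shell in the real ~11k-node functional-interaction
map; denser toy graphs make the shell relatively much larger and the
planted task structurally harder than the strongly coupled diseases this
regime emulates. Under these conditions the cross-validated ROC area is
≈ 0.9 on typical seeds.

What the generator does *not* emulate: linkage-disequilibrium structure
(variant sites are independent), real sequence content, correlated
annotation errors, overlapping gene classes (each gene has one generating
class), or hub-biased target placement. Passing recovery tests therefore
show the estimators detect the planted effects at realistic sizes — not
that real catalogs are free of the confounders the generator omits.

## Numerical and design choices

- "Common" means allele frequency strictly greater than 0.05.
- Exact rank-sum p-values: two-sided = min(1, 2·min(P(U≤u), P(U≥u))),
  verified against exhaustive enumeration; all-constant pooled input
  returns p = 1.
- Gene IDs are normalized string tokens (whitespace collapse); alias
  mapping drops unmapped IDs rather than guessing. Disease labels match
  case-insensitively after whitespace collapse; merged "A/B" trait rows
  are one disease unit unless `split_merged` is set.
- Where several splicing forms exist the annotation keeps one protein per
  gene; generated tables draw a single deterministic length per gene.
- Seeds: every stochastic component (generators, folds, bags, forests)
  derives from one run seed; generator manifests record planted structure
  and an edge checksum so outputs are reproducible byte-for-byte.
- Degenerate inputs: empty reference sets, single-class training folds,
  and classes with < 2 annotated genes raise or warn explicitly rather
  than returning silent zeros.

## Problem sizes used in the test suite

Contrast-recovery runs use 100 seeded cohorts at the variant-analysis
scale (1249 target / 3550 GWAS genes); classifier checks use 100 planted
diseases at the benchmark geometry plus 50 label-shuffled nulls; engine
cross-checks use 100 random graphs (≤ 50 nodes) for distances and 20
(≤ 20 nodes) for common-neighbor scores. Pipeline smoke and determinism
tests run a reduced bundle (300 nodes, 3 diseases) chosen for fast
iteration.

## Known limitations

- The MetaCost bag count (10) and its base learner are conventions; the
  procedure's published description fixes neither.
- Second-neighbor enrichment vanishes in the bias-8 limit (all planted
  targets are first neighbors), so the order-2 statistic is only
  informative at moderate bias.
- The unpaired rank-sum default for length contrasts departs from a
  "paired" description that is not well-defined for unequal class sizes;
  a signed-rank option exists for genuinely matched designs.
- Fold enrichment uses a uniform background; the degree-preserving
  permutation null is available but not the default.
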