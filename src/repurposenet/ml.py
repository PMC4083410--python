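"""Network-feature classifier for drug-target repurposing.

Each candidate gene (a member of the drug-target universe mapped to the
network) is described by 3+N features: its count of GWAS first neighbors,
its degree, its count of GWAS genes at shortest distance exactly 2, and one
common-neighbor (Jaccard) score against each of the disease's N mapped GWAS
genes.  A cost-sensitive random forest — MetaCost relabeling of the
training fold followed by a forest with I trees and K features per split —
is evaluated by stratified 10-fold cross-validation; out-of-fold
probabilities rank non-target genes as repurposing candidates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .types import DiseaseGeneMap

BASE_FEATURES = ["gwas_first_neighbors", "degree", "gwas_second_neighbors"]


def common_neighbor_score(network: nx.Graph, gene_a: str, gene_b: str) -> float:
    """Jaccard index of the two genes' neighbor sets: |Na∩Nb| / |Na∪Nb|.

    Symmetric; defined as 0 when both neighbor sets are empty.
    """
    for g in (gene_a, gene_b):
        if g not in network:
            raise ValueError(f"gene {g!r} not in network")
    na, nb = set(network[gene_a]), set(network[gene_b])
    union = na | nb
    if not union:
        return 0.0
    return len(na & nb) / len(union)


@dataclass
class FeatureMatrix:
    """Feature table (rows: candidate genes; columns: 3+N features) with
    boolean labels marking known targets for the focal disease."""

    features: pd.DataFrame
    labels: pd.Series
    gwas_genes: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def build_feature_matrix(
    network: nx.Graph,
    gwas_genes: set[str],
    universe: set[str],
    focal_targets: set[str],
) -> FeatureMatrix:
    """Assemble the 3+N feature matrix over the drug-target universe.

    GWAS genes and universe members not mapped to the network are dropped;
    common-neighbor columns follow sorted GWAS gene-ID order so the layout
    is stable across runs.
    """
    gwas = sorted(g for g in gwas_genes if g in network)
    rows = sorted(g for g in universe if g in network)
    if not gwas:
        raise ValueError("no GWAS genes mapped to the network (N = 0)")
    if not rows:
        raise ValueError("no universe genes mapped to the network")

    nodes = sorted(network.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(network, nodelist=nodes, format="csr", dtype=np.int64)
    r_idx = np.array([index[g] for g in rows])
    g_idx = np.array([index[g] for g in gwas])

    adj_rows = adj[r_idx]
    degree = np.asarray(adj_rows.sum(axis=1)).ravel()
    first = np.asarray(adj_rows[:, g_idx].sum(axis=1)).ravel()

    # genes at shortest distance exactly 2: a 2-step walk exists, no edge, not self
    two_step = adj_rows @ adj
    reach2 = (two_step > 0).astype(np.int8)
    reach2 = reach2 - reach2.multiply(adj_rows > 0)
    reach2 = reach2.tolil()
    for k, i in enumerate(r_idx):
        reach2[k, i] = 0
    reach2 = reach2.tocsr()
    second = np.asarray(reach2[:, g_idx].sum(axis=1)).ravel()

    common = np.asarray((adj_rows @ adj[:, g_idx].todense()))
    deg_all = np.asarray(adj.sum(axis=1)).ravel()
    union = degree[:, None] + deg_all[g_idx][None, :] - common
    with np.errstate(invalid="ignore", divide="ignore"):
        jaccard = np.where(union > 0, common / np.maximum(union, 1), 0.0)

    data = np.column_stack([first, degree, second, jaccard]).astype(float)
    columns = BASE_FEATURES + [f"cn__{g}" for g in gwas]
    features = pd.DataFrame(data, index=pd.Index(rows, name="gene"), columns=columns)
    labels = pd.Series([g in focal_targets for g in rows], index=features.index, name="is_target")
    return FeatureMatrix(features=features, labels=labels, gwas_genes=tuple(gwas))


@dataclass
class RFConfig:
    """Random-forest and cross-validation settings.

    ``features_per_split`` (K) defaults to floor(sqrt(3+N)); ``cost_ratio``
    defaults to #negatives/#positives so false negatives on the minority
    (known-target) class are penalised proportionally.
    """

    trees: int = 50
    features_per_split: int | None = None
    cost_ratio: float | None = None
    folds: int = 10
    seed: int = 0
    metacost_bags: int = 10

    def resolved_k(self, n_features: int) -> int:
        k = self.features_per_split if self.features_per_split is not None else int(
            math.floor(math.sqrt(n_features))
        )
        if not 1 <= k <= n_features:
            raise ValueError(f"features_per_split {k} outside [1, {n_features}]")
        return k


@dataclass
class CVMetrics:
    true_positive_rate: float
    false_positive_rate: float
    precision: float
    recall: float
    roc_area: float
    f_measure: float
    probabilities: pd.Series = field(repr=False, default=None)
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # tp, fp, tn, fn


def metacost_relabel(
    X: np.ndarray, y: np.ndarray, cost_ratio: float, n_bags: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """MetaCost relabeling: estimate class probabilities with a bagged
    ensemble of (unrestricted) decision trees, then assign each training
    point the class that minimises expected cost under C(FN)=cost_ratio,
    C(FP)=1.

    Predicting negative costs p_pos*cost_ratio; predicting positive costs
    p_neg; a point is relabeled positive iff p_pos*cost_ratio > p_neg.
    """
    if len(np.unique(y)) < 2:
        return y.copy()
    bagger = BaggingClassifier(
        estimator=DecisionTreeClassifier(),
        n_estimators=n_bags,
        random_state=int(rng.integers(2**31 - 1)),
    )
    bagger.fit(X, y)
    proba = bagger.predict_proba(X)
    p_pos = proba[:, list(bagger.classes_).index(True)]
    return p_pos * cost_ratio > (1.0 - p_pos)


def metacost_train_evaluate(
    matrix: FeatureMatrix, config: RFConfig, disease: str = ""
) -> CVMetrics:
    """Stratified k-fold CV of the MetaCost random forest; out-of-fold
    probabilities are aggregated into threshold-0.5 confusion metrics and
    the ROC area."""
    # canonical gene-ID order: metrics are invariant to the caller's row order
    features = matrix.features.sort_index()
    labels = matrix.labels.reindex(features.index)
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy(dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(f"{disease or 'disease'}: need >=2 positives and >=2 negatives")
    if n_pos < config.folds:
        raise ValueError(
            f"{disease or 'disease'}: cannot stratify {config.folds} folds "
            f"with only {n_pos} positive genes"
        )
    k = config.resolved_k(matrix.n_features)
    cost_ratio = config.cost_ratio if config.cost_ratio is not None else n_neg / n_pos
    if cost_ratio <= 0:
        raise ValueError("cost_ratio must be positive")

    rng = np.random.default_rng(config.seed)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    oof = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        y_relab = metacost_relabel(X[train_idx], y[train_idx], cost_ratio,
                                   config.metacost_bags, rng)
        if len(np.unique(y_relab)) < 2:
            y_relab = y[train_idx]  # relabeling collapsed a class; keep original labels
        forest = RandomForestClassifier(
            n_estimators=config.trees,
            max_features=k,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(X[train_idx], y_relab)
        pos_col = list(forest.classes_).index(True)
        oof[test_idx] = forest.predict_proba(X[test_idx])[:, pos_col]

    pred = oof >= 0.5
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    tpr = tp / n_pos
    fpr = fp / n_neg
    precision = tp / (tp + fp) if tp + fp else 0.0
    f_measure = (2 * precision * tpr / (precision + tpr)) if precision + tpr else 0.0
    return CVMetrics(
        true_positive_rate=tpr,
        false_positive_rate=fpr,
        precision=precision,
        recall=tpr,
        roc_area=float(roc_auc_score(y, oof)),
        f_measure=f_measure,
        probabilities=pd.Series(oof, index=features.index, name="probability"),
        confusion=(tp, fp, tn, fn),
    )


def eligible_diseases(
    maps: list[DiseaseGeneMap],
    network: nx.Graph,
    min_targets: int = 10,
    min_gwas: int = 10,
) -> list[str]:
    """Diseases with at least ``min_targets`` drug targets and ``min_gwas``
    GWAS genes mapped to the network (boundaries inclusive)."""
    out = []
    for dm in maps:
        n_t = sum(1 for g in dm.target_genes if g in network)
        n_g = sum(1 for g in dm.gwas_genes if g in network)
        if n_t >= min_targets and n_g >= min_gwas:
            out.append(dm.disease)
    return out


@dataclass
class RepurposingCandidate:
    gene: str
    probability: float
    already_target_for: tuple[str, ...] = ()


def rank_repurposing_candidates(
    metrics: CVMetrics,
    matrix: FeatureMatrix,
    threshold: float = 0.5,
    target_diseases: dict[str, tuple[str, ...]] | None = None,
) -> list[RepurposingCandidate]:
    """Label-negative genes with out-of-fold probability >= threshold, in
    descending probability order (ties broken by gene ID).  These are the
    classifier's 'false positives': targets of drugs for other diseases
    whose network context resembles the focal disease's known targets."""
    labels = matrix.labels.reindex(metrics.probabilities.index)
    negatives = metrics.probabilities[~labels]
    hits = negatives[negatives >= threshold]
    order = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    lookup = target_diseases or {}
    return [
        RepurposingCandidate(gene=g, probability=float(p),
                             already_target_for=tuple(lookup.get(g, ())))
        for g, p in order
    ]
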