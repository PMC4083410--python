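"""Feature construction and the cost-sensitive random forest."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from conftest import random_simple_graph
from repurposenet.ml import (
    CVMetrics,
    FeatureMatrix,
    RFConfig,
    build_feature_matrix,
    common_neighbor_score,
    eligible_diseases,
    metacost_train_evaluate,
    rank_repurposing_candidates,
)
from repurposenet.types import DiseaseGeneMap


def brute_force_jaccard(g, a, b):
    na, nb = set(g[a]), set(g[b])
    inter = sum(1 for v in g.nodes if v in na and v in nb)
    union = sum(1 for v in g.nodes if v in na or v in nb)
    return inter / union if union else 0.0


class TestCommonNeighborScore:
    def test_partial_overlap(self):
        g = nx.Graph([("A", "a"), ("A", "b"), ("A", "c"), ("B", "b"), ("B", "c"), ("B", "d")])
        # N_A = {a,b,c}, N_B = {b,c,d} -> 2 shared of 4 total
        assert common_neighbor_score(g, "A", "B") == pytest.approx(0.5)

    def test_identical_neighbor_sets_score_one(self):
        g = nx.Graph([("A", "x"), ("A", "y"), ("B", "x"), ("B", "y")])
        assert common_neighbor_score(g, "A", "B") == 1.0

    def test_isolated_pair_scores_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        assert common_neighbor_score(g, "A", "B") == 0.0

    def test_absent_gene_rejected(self):
        g = nx.Graph([("A", "x")])
        with pytest.raises(ValueError):
            common_neighbor_score(g, "A", "missing")

    def test_symmetric_and_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            g = random_simple_graph(rng, 15)
            for a, b in itertools.combinations(g.nodes, 2):
                s = common_neighbor_score(g, a, b)
                assert s == common_neighbor_score(g, b, a)
                assert s == pytest.approx(brute_force_jaccard(g, a, b))


class TestBuildFeatureMatrix:
    def test_toy_graph_cells_match_hand_computation(self, toy_graph):
        gwas = {"H", "e"}
        universe = {"a", "b", "d", "Z"}
        fm = build_feature_matrix(toy_graph, gwas, universe, focal_targets={"a"})
        f = fm.features
        assert list(f.columns) == [
            "gwas_first_neighbors", "degree", "gwas_second_neighbors", "cn__H", "cn__e",
        ]
        # a: neighbors {H,b}; H is GWAS; e at distance 3 via b-c-d-e? a-b-c-d-e -> 4
        assert f.loc["a"].tolist() == pytest.approx([
            1, 2, 0, brute_force_jaccard(toy_graph, "a", "H"),
            brute_force_jaccard(toy_graph, "a", "e"),
        ])
        # d: neighbors {c,e}; e is GWAS (first); H at distance 2 via c (second)
        assert f.loc["d", "gwas_first_neighbors"] == 1
        assert f.loc["d", "gwas_second_neighbors"] == 1
        assert fm.labels.sum() == 1

    def test_isolated_node_row_is_all_zero(self, toy_graph):
        fm = build_feature_matrix(toy_graph, {"H"}, {"Z"}, set())
        assert (fm.features.loc["Z"] == 0).all()

    def test_column_count_is_three_plus_n(self):
        g = nx.complete_graph(14)
        gwas = set(range(10))
        fm = build_feature_matrix(g, gwas, {10, 11, 12, 13}, {10})
        assert fm.n_features == 13
        assert fm.features.loc[10, "degree"] == 13
        assert fm.features.loc[10, "gwas_first_neighbors"] == 10

    def test_first_neighbors_never_exceed_degree(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            g = random_simple_graph(rng, 25)
            nodes = list(g.nodes)
            if len(nodes) < 6:
                continue
            gwas = set(nodes[:3])
            fm = build_feature_matrix(g, gwas, set(nodes), set(nodes[:2]))
            assert (fm.features.gwas_first_neighbors <= fm.features.degree).all()
            cn = fm.features.filter(like="cn__")
            assert ((cn >= 0) & (cn <= 1)).all().all()

    def test_no_mapped_gwas_genes_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            build_feature_matrix(toy_graph, {"nope"}, {"a"}, set())


def separable_matrix(n_pos=20, n_neg=180, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.uniform(10, 20, n_pos), rng.uniform(5, 9, n_pos),
                           rng.uniform(0, 3, n_pos)])
    neg = np.column_stack([np.zeros(n_neg), rng.uniform(5, 9, n_neg),
                           rng.uniform(0, 3, n_neg)])
    X = np.vstack([pos, neg])
    genes = [f"g{i:03d}" for i in range(n_pos + n_neg)]
    feats = pd.DataFrame(X, index=pd.Index(genes, name="gene"),
                         columns=["gwas_first_neighbors", "degree", "gwas_second_neighbors"])
    labels = pd.Series([True] * n_pos + [False] * n_neg, index=feats.index)
    return FeatureMatrix(feats, labels, gwas_genes=("gw1",))


class TestMetaCostForest:
    def test_separable_features_classified_perfectly(self):
        fm = separable_matrix()
        m = metacost_train_evaluate(fm, RFConfig(seed=3))
        assert m.roc_area == 1.0
        assert m.true_positive_rate == 1.0

    def test_confusion_counts_cover_universe(self):
        fm = separable_matrix()
        m = metacost_train_evaluate(fm, RFConfig(seed=3))
        assert sum(m.confusion) == len(fm.labels)
        assert m.recall == m.true_positive_rate

    def test_row_permutation_leaves_metrics_unchanged(self):
        fm = separable_matrix(seed=5)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(fm.labels))
        fm_perm = FeatureMatrix(fm.features.iloc[perm], fm.labels.iloc[perm], fm.gwas_genes)
        m1 = metacost_train_evaluate(fm, RFConfig(seed=11))
        m2 = metacost_train_evaluate(fm_perm, RFConfig(seed=11))
        assert m1.roc_area == m2.roc_area
        assert m1.confusion == m2.confusion

    def test_unit_cost_ratio_matches_plain_forest(self):
        # with cost ratio 1 MetaCost reduces to plurality relabeling, so
        # metrics should track an uncosted forest within stochastic noise
        rng = np.random.default_rng(13)
        n = 240
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + 0.8 * rng.normal(size=n)) > 0.4
        genes = [f"g{i:03d}" for i in range(n)]
        feats = pd.DataFrame(
            X, index=pd.Index(genes, name="gene"),
            columns=["gwas_first_neighbors", "degree", "gwas_second_neighbors", "cn__x"])
        fm = FeatureMatrix(feats, pd.Series(y, index=feats.index), ("x",))
        m = metacost_train_evaluate(fm, RFConfig(seed=17, cost_ratio=1.0))

        skf = StratifiedKFold(10, shuffle=True, random_state=17)
        oof = np.zeros(n)
        for tr, te in skf.split(X, y):
            f = RandomForestClassifier(50, max_features=2, random_state=17).fit(X[tr], y[tr])
            oof[te] = f.predict_proba(X[te])[:, 1]
        assert abs(m.roc_area - roc_auc_score(y, oof)) < 0.1

    def test_too_few_positives_for_folds_names_disease(self):
        fm = separable_matrix(n_pos=4, n_neg=100)
        with pytest.raises(ValueError, match="lupus"):
            metacost_train_evaluate(fm, RFConfig(seed=1), disease="lupus")

    def test_degenerate_single_class_rejected(self):
        fm = separable_matrix(n_pos=1, n_neg=50)
        with pytest.raises(ValueError):
            metacost_train_evaluate(fm, RFConfig(seed=1))

    def test_k_defaults_to_sqrt_of_feature_count(self):
        cfg = RFConfig()
        assert cfg.resolved_k(13) == 3
        assert cfg.resolved_k(23) == 4
        with pytest.raises(ValueError):
            RFConfig(features_per_split=99).resolved_k(13)


class TestEligibleDiseases:
    def graph(self):
        g = nx.complete_graph(40)
        return nx.relabel_nodes(g, {i: f"g{i}" for i in range(40)})

    def make(self, n_targets, n_gwas):
        return DiseaseGeneMap(
            "d", {f"g{i}" for i in range(n_gwas)}, set(),
            {f"g{i + 20}" for i in range(n_targets)},
        )

    def test_boundary_counts_inclusive(self):
        g = self.graph()
        assert eligible_diseases([self.make(10, 10)], g) == ["d"]
        assert eligible_diseases([self.make(9, 10)], g) == []
        assert eligible_diseases([self.make(10, 9)], g) == []

    def test_unmapped_genes_do_not_count(self):
        g = self.graph()
        dm = self.make(10, 10)
        dm.target_genes |= {"absent1", "absent2"}
        dm.gwas_genes = {f"g{i}" for i in range(9)} | {"absent3"}
        assert eligible_diseases([dm], g) == []


class TestRankCandidates:
    def fake_metrics(self, probs: dict[str, float], labels: dict[str, bool]):
        genes = sorted(probs)
        feats = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"),
                             columns=["gwas_first_neighbors", "degree",
                                      "gwas_second_neighbors", "cn__x"])
        fm = FeatureMatrix(feats, pd.Series([labels[g] for g in genes], index=feats.index), ("x",))
        met = CVMetrics(0, 0, 0, 0, 0.5, 0,
                        probabilities=pd.Series({g: probs[g] for g in genes}))
        return met, fm

    def test_all_below_threshold_gives_empty_list(self):
        met, fm = self.fake_metrics({"a": 0.1, "b": 0.2}, {"a": False, "b": False})
        assert rank_repurposing_candidates(met, fm) == []

    def test_ties_broken_by_gene_id(self):
        met, fm = self.fake_metrics(
            {"MAPK3": 1.0, "RAF1": 0.96, "PIK3R1": 0.96, "known": 0.99},
            {"MAPK3": False, "RAF1": False, "PIK3R1": False, "known": True},
        )
        out = rank_repurposing_candidates(met, fm)
        assert [c.gene for c in out] == ["MAPK3", "PIK3R1", "RAF1"]

    def test_other_disease_memberships_attached(self):
        met, fm = self.fake_metrics({"a": 0.9, "b": 0.1}, {"a": False, "b": False})
        out = rank_repurposing_candidates(met, fm, target_diseases={"a": ("gout",)})
        assert out[0].already_target_for == ("gout",)
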