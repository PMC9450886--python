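"""Similarity graph, Louvain communities, k selection, and out-of-sample assignment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import fishclust.clustering as fcc
from fishclust import (
    CohortSpec,
    assign,
    build_knn_graph,
    fit,
    generate_feature_cohort,
    load_model,
    louvain_partition,
    save_model,
    scan_k,
    select_k,
    similarity,
    standardize,
)
from fishclust.clustering import ClusterModel, StandardizationParams
from fishclust.features import FEATURE_NAMES

from conftest import make_blobs


class TestStandardize:
    def test_reference_moments(self, blob_cohort):
        df, _ = blob_cohort
        Z, params = standardize(df)
        assert Z.mean().to_numpy() == pytest.approx(np.zeros(4), abs=1e-12)
        assert Z.std(ddof=1).to_numpy() == pytest.approx(np.ones(4))

    def test_reference_anchored(self, blob_cohort):
        df, _ = blob_cohort
        Z1, params = standardize(df)
        Z2, _ = standardize(df, params)
        pd.testing.assert_frame_equal(Z1, Z2)

    def test_fish_at_reference_mean_is_zero(self, blob_cohort):
        df, _ = blob_cohort
        _, params = standardize(df)
        new = pd.DataFrame([params.mean.to_dict()])
        Z, _ = standardize(new, params)
        assert Z.to_numpy() == pytest.approx(np.zeros((1, 4)), abs=1e-12)

    def test_zero_variance_errors(self):
        df = pd.DataFrame(np.ones((5, 4)), columns=FEATURE_NAMES)
        with pytest.raises(ValueError):
            standardize(df)


class TestSimilarity:
    def test_chosen_form_values(self):
        # rows at exact Euclidean distances 0, 1, 3 from the origin row
        X = np.zeros((3, 4))
        X[1, 0] = 1.0
        X[2, 0] = 3.0
        S = similarity(X)
        assert S[0, 0] == 1.0
        assert S[0, 1] == pytest.approx(0.5)
        assert S[0, 2] == pytest.approx(0.25)
        assert np.array_equal(S, S.T)

    def test_identical_fish(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0], (2, 1))
        assert similarity(X)[0, 1] == pytest.approx(1.0)

    def test_exp_form(self):
        X = np.zeros((2, 4))
        X[1, 0] = 1.0
        assert similarity(X, form="exp")[0, 1] == pytest.approx(np.exp(-1))

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            similarity(np.array([[np.nan, 0, 0, 0], [0, 0, 0, 0]]))


class TestKnnGraph:
    def test_pair_and_outlier(self):
        X = np.array([[0.0], [0.1], [10.0]])
        S = 1.0 / (1.0 + np.abs(X - X.T))
        G = build_knn_graph(S, k=1)
        assert G.has_edge(0, 1)
        # the outlier's single nearest neighbor attaches it to the pair
        assert G.degree(2) == 1

    def test_complete_graph(self):
        rng = np.random.default_rng(0)
        S = similarity(rng.normal(size=(6, 4)))
        G = build_knn_graph(S, k=5)
        assert G.number_of_edges() == 15

    def test_tie_break_to_lower_index(self):
        # node 0 equidistant from 1 and 2; k=1 must pick the lower index
        S = np.array([
            [1.0, 0.5, 0.5, 0.1],
            [0.5, 1.0, 0.2, 0.1],
            [0.5, 0.2, 1.0, 0.1],
            [0.1, 0.1, 0.1, 1.0],
        ])
        G = build_knn_graph(S, k=1)
        # hand enumeration: 0->1 (tie with 2 broken low), 1->0, 2->0, 3->0|1|2 tie -> 0
        assert set(G.edges()) == {(0, 1), (0, 2), (0, 3)}

    def test_k_out_of_range(self):
        S = np.eye(3)
        with pytest.raises(ValueError):
            build_knn_graph(S, k=3)


class TestLouvain:
    def test_two_cliques(self):
        G = nx.Graph()
        for base in (0, 10):
            for i, j in itertools.combinations(range(base, base + 10), 2):
                G.add_edge(i, j, weight=1.0)
        G.add_edge(0, 10, weight=1.0)
        labels = louvain_partition(G, seed=1)
        assert labels.max() == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1

    def test_uniform_complete_graph_single_community(self):
        G = nx.complete_graph(10)
        nx.set_edge_attributes(G, 1.0, "weight")
        labels = louvain_partition(G, seed=0)
        assert labels.max() == 1

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            louvain_partition(nx.Graph())

    def test_modularity_beats_trivial_partitions(self, blob_cohort):
        df, _ = blob_cohort
        Z, _ = standardize(df)
        G = build_knn_graph(similarity(Z), k=10)
        labels = louvain_partition(G, seed=0)
        parts = [set(np.flatnonzero(labels == c)) for c in range(1, labels.max() + 1)]
        q = nx.community.modularity(G, parts, weight="weight")
        singletons = [{v} for v in G.nodes()]
        assert q >= nx.community.modularity(G, singletons, weight="weight")
        assert q >= nx.community.modularity(G, [set(G.nodes())], weight="weight")

    def test_brute_force_modularity_oracle(self):
        """On a tiny planted fixture Louvain attains the exact modularity optimum."""
        df, truth = make_blobs([4, 4], sd=0.3, seed=3)
        Z, _ = standardize(df)
        G = build_knn_graph(similarity(Z), k=3)
        labels = louvain_partition(G, seed=0)
        parts = [set(np.flatnonzero(labels == c)) for c in range(1, labels.max() + 1)]
        q_louvain = nx.community.modularity(G, parts, weight="weight")

        def set_partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for part in set_partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1:]
                yield [[first]] + part

        q_best = max(
            nx.community.modularity(G, [set(b) for b in p], weight="weight")
            for p in set_partitions(list(G.nodes()))
        )
        assert q_louvain == pytest.approx(q_best, abs=1e-9)

    def test_igraph_cross_check(self, blob_cohort):
        """Independent Louvain implementation recovers the same partition."""
        igraph = pytest.importorskip("igraph")
        df, truth = blob_cohort
        Z, _ = standardize(df)
        S = similarity(Z)
        G = build_knn_graph(S, k=10)
        labels = louvain_partition(G, seed=0)
        g = igraph.Graph.TupleList(
            ((int(u), int(v), d["weight"]) for u, v, d in G.edges(data=True)),
            weights=True,
        )
        ig_labels = np.empty(len(df), dtype=int)
        member = g.community_multilevel(weights="weight").membership
        for vert, lab in zip(g.vs["name"], member):
            ig_labels[vert] = lab
        assert adjusted_rand_score(labels, ig_labels) == 1.0


class TestKSelection:
    def test_plateau_midpoint(self):
        ks = list(range(50, 201, 10))
        scan = pd.DataFrame(
            {
                "k": ks,
                "n_communities": [4] * len(ks),
                "calinski_harabasz": [100.0 + (80 <= k <= 140) * 50 for k in ks],
                "silhouette": [0.3 + (80 <= k <= 140) * 0.3 for k in ks],
                "davies_bouldin": [1.0 - (80 <= k <= 140) * 0.5 for k in ks],
            }
        )
        assert select_k(scan) == 110

    def test_single_best_with_warning(self):
        scan = pd.DataFrame(
            {
                "k": [10, 20, 30],
                "n_communities": [4, 4, 4],
                "calinski_harabasz": [10.0, 90.0, 10.0],
                "silhouette": [0.1, 0.9, 0.1],
                "davies_bouldin": [2.0, 0.5, 2.0],
            }
        )
        with pytest.warns(UserWarning, match="plateau"):
            assert select_k(scan) == 20

    def test_scan_on_separated_blobs(self, blob_cohort):
        df, truth = blob_cohort
        scan = scan_k(df, k_values=[5, 10, 15, 20, 25, 30], seed=0)
        four = scan[scan["n_communities"] == 4]
        assert not four.empty
        # CH is maximized inside the 4-community regime
        assert scan.loc[scan["calinski_harabasz"].idxmax(), "n_communities"] == 4

    def test_point_mass_silhouette(self):
        df = pd.DataFrame(
            np.vstack([np.zeros((5, 4)), np.ones((5, 4)) * 8]), columns=FEATURE_NAMES
        )
        scan = scan_k(df, k_values=[3], seed=0)
        assert scan["n_communities"].iloc[0] == 2
        assert scan["silhouette"].iloc[0] == pytest.approx(1.0)

    def test_single_community_indices_undefined(self, monkeypatch, blob_cohort):
        df, _ = blob_cohort
        monkeypatch.setattr(
            fcc, "louvain_partition", lambda G, seed=0: np.ones(G.number_of_nodes(), dtype=int)
        )
        scan = scan_k(df, k_values=[10], seed=0)
        assert scan["n_communities"].iloc[0] == 1
        assert scan[["calinski_harabasz", "silhouette", "davies_bouldin"]].isna().all().all()


class TestFitAssign:
    def test_planted_sizes_and_m_assign(self):
        df, truth = make_blobs([82, 100, 120, 124], sd=1.0, seed=1)
        model = fit(df, k=40, seed=0)
        assert model.n_communities == 4
        assert adjusted_rand_score(truth, model.labels) == 1.0
        assert model.n_min == 82
        assert model.m_assign == 41

    def test_two_cluster_recovery(self):
        # k must be a sizable fraction of the cluster size: sparser graphs let
        # modularity subdivide a well-separated blob into sub-communities
        df, truth = make_blobs([30, 50], sd=1.0, seed=2)
        model = fit(df, k=30, seed=0)
        assert model.n_communities == 2
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_seed_reproducibility(self, blob_cohort):
        df, _ = blob_cohort
        m1 = fit(df, k=12, seed=3)
        m2 = fit(df, k=12, seed=3)
        assert np.array_equal(m1.labels, m2.labels)
        assert nx.utils.graphs_equal(m1.graph, m2.graph)

    def test_row_order_invariance(self, blob_cohort):
        df, _ = blob_cohort
        m1 = fit(df, k=12, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(df))
        m2 = fit(df.iloc[perm].reset_index(drop=True), k=12, seed=3)
        # community ids are size-ordered, so labels must transport through the permutation
        assert np.array_equal(m2.labels, m1.labels[perm])

    def test_assign_reproduces_reference_labels(self, blob_cohort):
        df, _ = blob_cohort
        model = fit(df, k=12, seed=0)
        assert np.array_equal(assign(model, df), model.labels)

    def test_assign_deep_interior_point(self, blob_cohort):
        df, _ = blob_cohort
        model = fit(df, k=12, seed=0)
        i = 0
        new = df.iloc[[i]].reset_index(drop=True)
        assert assign(model, new)[0] == model.labels[i]

    def test_assign_tie_contract(self):
        """A perfectly symmetric new point resolves by total similarity, then lower id."""
        Z = pd.DataFrame(
            [[-1.0, 0, 0, 0], [-1.0, 0.1, 0, 0], [-1.0, -0.1, 0, 0], [-1.0, 0, 0.1, 0],
             [1.0, 0, 0, 0], [1.0, 0.1, 0, 0], [1.0, -0.1, 0, 0], [1.0, 0, 0.1, 0]],
            columns=FEATURE_NAMES,
        )
        model = ClusterModel(
            reference=Z,
            fish_ids=pd.Series([f"r{i}" for i in range(8)]),
            params=StandardizationParams(
                mean=pd.Series(0.0, index=FEATURE_NAMES),
                sd=pd.Series(1.0, index=FEATURE_NAMES),
            ),
            graph=nx.empty_graph(8),
            labels=np.array([1, 1, 1, 1, 2, 2, 2, 2]),
            k=1,
            seed=0,
        )
        assert model.m_assign == 2
        center = pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], columns=FEATURE_NAMES)
        assert assign(model, center)[0] == 1

    def test_persistent_cohort_day2_assignment(self):
        spec = CohortSpec(persistence=1.0, n_sessions=2, seed=5)
        feats, meta, truth = generate_feature_cohort(spec)
        f1 = feats[feats["session"] == "1"].reset_index(drop=True)
        f2 = feats[feats["session"] == "2"].reset_index(drop=True)
        model = fit(f1, k=60, seed=0)
        agreement = np.mean(assign(model, f2) == model.labels)
        assert agreement >= 0.95


class TestSerialization:
    def test_roundtrip(self, tmp_path, blob_cohort):
        df, _ = blob_cohort
        model = fit(df, k=12, seed=1)
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        assert np.array_equal(loaded.labels, model.labels)
        assert loaded.k == model.k and loaded.m_assign == model.m_assign
        new = df.sample(10, random_state=0).reset_index(drop=True)
        assert np.array_equal(assign(loaded, new), assign(model, new))

    def test_file_bytes_roundtrip(self, tmp_path, blob_cohort):
        df, _ = blob_cohort
        model = fit(df, k=12, seed=1)
        save_model(model, tmp_path / "m1")
        save_model(load_model(tmp_path / "m1"), tmp_path / "m2")
        for name in ("params.json", "edges.csv", "labels.csv", "reference.csv"):
            assert (tmp_path / "m1" / name).read_bytes() == (tmp_path / "m2" / name).read_bytes()
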