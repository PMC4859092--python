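import numpy as np
import pandas as pd
import igraph as ig
import pytest
from sklearn.metrics import adjusted_rand_score

from psfsom.similarity import (
    build_disease_graph,
    coregulation_count,
    cut_first_split,
    dendrogram_newick,
    graph_to_edge_list,
    hierarchical_cluster,
    run_ica,
    second_level_som,
    walktrap_communities,
)


def profiles_from(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T


def diff_table(sig_sinks, deltas=None):
    sinks = [f"pw{i // 2:02d}:s{i % 2}" for i in range(10)]
    deltas = deltas or {}
    return pd.DataFrame({
        "sink_id": sinks,
        "delta": [deltas.get(s, 1.0) for s in sinks],
        "p_value": 0.01, "q_value": 0.01,
        "significant": [s in sig_sinks for s in sinks],
    })


class TestHierarchical:
    def test_identical_classes_merge_first_at_zero(self):
        prof = profiles_from({
            "a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [9.0, 1.0, 4.0]
        })
        link, labels = hierarchical_cluster(prof, "euclidean")
        first = link[0]
        merged = {labels[int(first[0])], labels[int(first[1])]}
        assert merged == {"a", "b"} and first[2] == 0.0

    def test_pearson_is_scale_invariant(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.normal(size=(4, 20)),
                            index=list("abcd"))
        link1, _ = hierarchical_cluster(prof, "pearson")
        doubled = prof.copy()
        doubled.loc["b"] *= 2.0
        link2, _ = hierarchical_cluster(doubled, "pearson")
        np.testing.assert_allclose(link1, link2, atol=1e-12)

    def test_planted_supergroups_split_first(self, block_psf, block_dataset):
        from psfsom.benchmark import differential_class_profiles

        truth = block_dataset["truth"]
        prof = differential_class_profiles(
            block_psf["psf"], block_dataset["sheet"], truth.control_label
        )
        groups = [
            {l for l, g in truth.supergroups.items() if g == k} for k in (0, 1)
        ]
        for metric in ("pearson", "euclidean"):
            link, labels = hierarchical_cluster(prof, metric)
            g1, g2 = cut_first_split(link, labels)
            assert (groups[0] <= g1 and groups[1] <= g2) or (
                groups[0] <= g2 and groups[1] <= g1
            )

    def test_heights_monotone_under_average_linkage(self, block_psf,
                                                    block_dataset):
        from psfsom.benchmark import differential_class_profiles

        prof = differential_class_profiles(
            block_psf["psf"], block_dataset["sheet"], "HC"
        )
        link, _ = hierarchical_cluster(prof, "euclidean")
        assert (np.diff(link[:, 2]) >= -1e-12).all()

    def test_constant_profile_under_pearson_is_error(self):
        prof = profiles_from({"a": [1.0, 1.0], "b": [1.0, 2.0], "c": [2.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            hierarchical_cluster(prof, "pearson")

    def test_newick_serialization_contains_all_leaves(self):
        prof = profiles_from({
            "a": [1.0, 2.0], "b": [1.1, 2.0], "c": [5.0, 0.0], "d": [9.0, 9.0]
        })
        link, labels = hierarchical_cluster(prof, "euclidean")
        nwk = dendrogram_newick(link, labels)
        assert nwk.endswith(";")
        for leaf in "abcd":
            assert leaf in nwk


class TestSecondLevelSOM:
    def test_identical_classes_share_a_unit(self):
        prof = profiles_from({
            "a": [1.0, 2.0, 1.0], "b": [1.0, 2.0, 1.0],
            "c": [8.0, 0.0, 3.0], "d": [8.1, 0.1, 3.0],
        })
        coords = second_level_som(prof, grid=(4, 4), seed=0)
        assert coords.loc["a"].tolist() == coords.loc["b"].tolist()

    def test_supergroups_separate_on_grid(self):
        rng = np.random.default_rng(4)
        center = rng.normal(0, 1, 30)
        prof = pd.DataFrame(
            [center + rng.normal(0, 0.2, 30) + (8.0 if i < 4 else -8.0)
             for i in range(8)],
            index=[f"c{i}" for i in range(8)],
        )
        coords = second_level_som(prof, grid=(6, 6), seed=1)
        g0, g1 = [f"c{i}" for i in range(4)], [f"c{i}" for i in range(4, 8)]
        within = np.linalg.norm(
            coords.loc[g0].to_numpy() - coords.loc[g0].mean().to_numpy(), axis=1
        ).mean()
        between = np.linalg.norm(
            coords.loc[g1].to_numpy() - coords.loc[g0].mean().to_numpy(), axis=1
        ).mean()
        assert between > within

    def test_seeded_repeat_identical(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.normal(size=(6, 10)),
                            index=[f"c{i}" for i in range(6)])
        c1 = second_level_som(prof, grid=(5, 5), seed=7)
        c2 = second_level_som(prof, grid=(5, 5), seed=7)
        pd.testing.assert_frame_equal(c1, c2)


class TestICA:
    def test_sources_recovered_from_mixture(self):
        rng = np.random.default_rng(1)
        n_obs, n_feat = 12, 300
        sources = np.vstack([
            np.sign(rng.normal(size=n_obs)), rng.laplace(size=n_obs)
        ]).T
        mixing = rng.normal(size=(2, n_feat))
        x = pd.DataFrame(sources @ mixing,
                         index=[f"c{i:02d}" for i in range(n_obs)])
        scores = run_ica(x, n_components=2, seed=0)
        corr = np.abs(np.corrcoef(
            np.hstack([scores.to_numpy(), sources]).T
        )[:2, 2:])
        # each recovered component matches one true source
        assert corr.max(axis=1).min() >= 0.9

    def test_component_separates_supergroups(self, block_psf, block_dataset):
        from psfsom.benchmark import differential_class_profiles

        truth = block_dataset["truth"]
        prof = differential_class_profiles(
            block_psf["psf"], block_dataset["sheet"], truth.control_label
        )
        scores = run_ica(prof, n_components=3, seed=0)
        g = pd.Series(truth.supergroups)
        separated = False
        for col in scores.columns:
            lo = scores.loc[g[g == 0].index, col]
            hi = scores.loc[g[g == 1].index, col]
            if lo.max() < hi.min() or hi.max() < lo.min():
                separated = True
        assert separated

    def test_seeded_repeat_identical(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.normal(size=(8, 50)),
                            index=[f"c{i}" for i in range(8)])
        pd.testing.assert_frame_equal(
            run_ica(prof, 3, seed=4), run_ica(prof, 3, seed=4)
        )

    def test_too_many_components_rejected(self):
        prof = profiles_from({"a": [1.0, 2.0], "b": [2.0, 1.0], "c": [0.0, 1.0]})
        with pytest.raises(ValueError):
            run_ica(prof, n_components=3, seed=0)


class TestDiseaseGraph:
    def test_shared_pathways_counted(self):
        sig = {f"pw{i:02d}:s0" for i in range(5)}
        d = {"A": diff_table(sig), "B": diff_table(sig)}
        g = build_disease_graph(d)
        edges = graph_to_edge_list(g)
        assert edges.shape[0] == 1
        assert edges.loc[0, "weight"] == 5

    def test_opposite_delta_signs_do_not_coregulate(self):
        sig = {"pw00:s0"}
        a = diff_table(sig, deltas={"pw00:s0": 1.0})
        b = diff_table(sig, deltas={"pw00:s0": -1.0})
        assert coregulation_count(a, b) == 0
        g = build_disease_graph({"A": a, "B": b})
        assert g.ecount() == 0

    def test_sink_level_counting(self):
        sig = {"pw00:s0", "pw00:s1", "pw01:s0"}
        a = diff_table(sig)
        assert coregulation_count(a, a, level="pathway") == 2
        assert coregulation_count(a, a, level="sink") == 3

    def test_shared_deregulation_links_only_those_classes(self):
        shared = {"pw00:s0", "pw01:s0"}
        d = {
            "A": diff_table(shared), "B": diff_table(shared),
            "C": diff_table({"pw04:s1"}),
        }
        edges = graph_to_edge_list(build_disease_graph(d))
        assert set(map(tuple, edges[["class_a", "class_b"]].values)) == {("A", "B")}

    def test_edge_weights_symmetric_integer(self, block_psf, block_dataset):
        from psfsom.stats import differential_all_classes

        diffs = differential_all_classes(
            block_psf["psf"], block_dataset["sheet"], "HC"
        )
        g = build_disease_graph(diffs, level="sink")
        weights = g.es["weight"]
        assert all(isinstance(w, int) and w >= 1 for w in weights)


class TestWalktrap:
    def test_two_cliques_two_communities(self):
        g = ig.Graph.Full(4) + ig.Graph.Full(4)
        g.vs["name"] = [f"n{i}" for i in range(8)]
        g.es["weight"] = 1
        comm = walktrap_communities(g)
        assert comm.nunique() == 2
        assert comm["n0"] == comm["n3"] and comm["n4"] == comm["n7"]
        assert comm["n0"] != comm["n4"]

    def test_isolated_node_is_singleton(self):
        g = ig.Graph.Full(3)
        g.add_vertex()
        g.vs["name"] = ["a", "b", "c", "lonely"]
        g.es["weight"] = 2
        comm = walktrap_communities(g)
        assert (comm == comm["lonely"]).sum() == 1

    def test_planted_partition_recovery(self):
        """Co-regulation block graphs: each class pair co-regulates each of
        10 pathways with probability 0.9 within a block and 0.1 between;
        the edge weight is the resulting shared-pathway count."""
        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            names = [f"c{i:02d}" for i in range(12)]
            blocks = {n: i // 3 for i, n in enumerate(names)}
            g = ig.Graph()
            g.add_vertices(names)
            edges, weights = [], []
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    p = 0.9 if blocks[a] == blocks[b] else 0.1
                    w = int(rng.binomial(10, p))
                    if w >= 1:
                        edges.append((a, b))
                        weights.append(w)
            g.add_edges(edges)
            g.es["weight"] = weights
            comm = walktrap_communities(g)
            aris.append(adjusted_rand_score(
                [blocks[n] for n in names], [comm[n] for n in names]
            ))
        assert np.mean(aris) >= 0.9

    def test_modularity_beats_singletons(self, block_psf, block_dataset):
        from psfsom.stats import differential_all_classes

        diffs = differential_all_classes(
            block_psf["psf"], block_dataset["sheet"], "HC"
        )
        g = build_disease_graph(diffs, level="sink")
        comm = walktrap_communities(g)
        q = g.modularity(
            [comm[n] for n in g.vs["name"]], weights="weight"
        )
        q_singletons = g.modularity(range(g.vcount()), weights="weight")
        assert q >= q_singletons

    def test_empty_graph_rejected(self):
        g = ig.Graph()
        g.add_vertices(["a", "b"])
        with pytest.raises(ValueError):
            walktrap_communities(g)
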