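import numpy as np
import pandas as pd
import pytest

from psfsom.som import (
    Portrait,
    SOMConfig,
    SOMModel,
    all_portraits,
    class_portrait,
    detect_spots,
    summary_spot_map,
    train_som,
)


def small_config(seed=0, rows=10, cols=10):
    return SOMConfig(grid_rows=rows, grid_cols=cols, epochs=12, seed=seed)


def two_cluster_data(n_per=8, dim=12, sep=20.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.5, (n_per, dim))
    b = rng.normal(sep, 0.5, (n_per, dim))
    idx = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    return pd.DataFrame(np.vstack([a, b]), index=idx)


class TestTraining:
    def test_identical_profiles_collapse_to_one_unit(self):
        data = pd.DataFrame(np.tile([1.0, -2.0, 3.0], (6, 1)),
                            index=[f"s{i}" for i in range(6)])
        config = SOMConfig(grid_rows=4, grid_cols=4, learning_rate=0.5,
                           lr_constant=0.001, epochs=300, seed=0)
        model = train_som(data, config)
        assert model.assignment.nunique() == 1
        unit = int(model.assignment.iloc[0])
        np.testing.assert_allclose(model.weights[unit], [1.0, -2.0, 3.0],
                                   atol=1e-2)

    def test_separated_clusters_map_to_distant_units(self):
        data = two_cluster_data()
        model = train_som(data, small_config())
        coords = np.array([model.unit_coords(int(u)) for u in model.assignment])
        a, b = coords[:8].mean(axis=0), coords[8:].mean(axis=0)
        assert np.linalg.norm(a - b) > model.config.radius

    def test_seeded_determinism(self):
        data = two_cluster_data(seed=3)
        m1 = train_som(data, small_config(seed=5))
        m2 = train_som(data, small_config(seed=5))
        np.testing.assert_array_equal(m1.weights, m2.weights)
        pd.testing.assert_series_equal(m1.assignment, m2.assignment)

    def test_topology_preservation(self, block_psf):
        model = train_som(block_psf["centralized"], small_config(seed=2))
        w = model.weights
        rows, cols = model.grid_shape
        adjacent = []
        for r in range(rows):
            for c in range(cols):
                u = r * cols + c
                if c + 1 < cols:
                    adjacent.append(np.linalg.norm(w[u] - w[u + 1]))
                if r + 1 < rows:
                    adjacent.append(np.linalg.norm(w[u] - w[u + cols]))
        rng = np.random.default_rng(0)
        pairs = rng.integers(0, rows * cols, size=(500, 2))
        random_d = [np.linalg.norm(w[i] - w[j]) for i, j in pairs if i != j]
        assert np.mean(adjacent) < np.mean(random_d)

    def test_planted_block_sinks_cluster_on_grid(self):
        """Co-deregulated sinks of one planted block land within the
        neighborhood radius of each other in >= 90% of seeded runs."""
        from psfsom import expression as expr_mod
        from psfsom import psf as psf_mod
        from psfsom.synth import (
            ClassSpec, SyntheticDesign, generate_dataset, generate_pathways,
            private_branch,
        )

        clustered = 0
        total = 0
        for seed in range(10):
            base = SyntheticDesign(seed=seed, n_pathways=10,
                                   classes=(ClassSpec("HC"),))
            graphs, _, _ = generate_pathways(base)
            classes = (ClassSpec("HC", 20),) + tuple(
                ClassSpec(
                    f"D{k + 1}", 20, effect_size=4.0, direction="up",
                    target_sinks=tuple(
                        f"{graphs[k].pathway_id}:{s}"
                        for s in sorted(graphs[k].sinks)
                        if len(private_branch(graphs[k], s)) == 1
                    ),
                )
                for k in range(4)
            )
            design = SyntheticDesign(seed=seed, n_pathways=10,
                                     classes=classes)
            graphs, _, expr, sheet, truth = generate_dataset(design)
            linear, _ = expr_mod.detect_and_linearize(expr)
            fc = expr_mod.compute_fold_change(linear, sheet)
            cent = psf_mod.centralize(psf_mod.compute_psf_matrix(graphs, fc))
            model = train_som(cent, small_config(seed=seed))
            for label, sinks in truth.class_sinks.items():
                coords = np.array([
                    model.unit_coords(int(model.assignment[s]))
                    for s, sign in sinks.items() if sign > 0
                ])
                dist = np.linalg.norm(
                    coords[:, None, :] - coords[None, :, :], axis=-1
                )
                pairs = dist[np.triu_indices(len(coords), k=1)]
                total += len(pairs)
                clustered += int((pairs <= model.config.radius).sum())
        assert clustered / total >= 0.9

    def test_nonfinite_input_rejected(self):
        data = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            train_som(data, small_config())

    def test_save_load_round_trip(self, tmp_path):
        model = train_som(two_cluster_data(), small_config(seed=9))
        model.save(tmp_path / "m.json", tmp_path / "w.tsv")
        loaded = SOMModel.load(tmp_path / "m.json", tmp_path / "w.tsv")
        np.testing.assert_allclose(loaded.weights, model.weights, atol=1e-12)
        assert loaded.assignment.to_dict() == {
            str(k): v for k, v in model.assignment.to_dict().items()
        }


@pytest.fixture(scope="module")
def trained(block_psf):
    return train_som(block_psf["centralized"], small_config(seed=4))


class TestPortraits:

    def test_single_sample_class_equals_weight_slice(self, trained):
        sheet = pd.DataFrame({
            "sample_id": [trained.sample_ids[0]],
            "class_label": ["solo"],
            "dataset_id": ["d"], "is_control": [False],
        })
        p = class_portrait(trained, sheet, "solo")
        np.testing.assert_array_equal(
            p.grid.ravel(), trained.weights[:, 0]
        )

    def test_two_sample_class_is_elementwise_mean(self, trained):
        sheet = pd.DataFrame({
            "sample_id": trained.sample_ids[:2],
            "class_label": ["pair", "pair"],
            "dataset_id": "d", "is_control": False,
        })
        p = class_portrait(trained, sheet, "pair")
        np.testing.assert_allclose(
            p.grid.ravel(), trained.weights[:, :2].mean(axis=1)
        )

    def test_all_sample_portrait_mean_near_zero(self, trained, block_dataset):
        sheet = block_dataset["sheet"].copy()
        sheet["class_label"] = "all"
        p = class_portrait(trained, sheet, "all")
        # centralization pushes the grand mean of meta-PSFs towards zero
        assert abs(p.grid.mean()) < 0.1

    def test_unknown_class_is_error(self, trained, block_dataset):
        with pytest.raises(ValueError):
            class_portrait(trained, block_dataset["sheet"], "no-such-class")


def bump_portrait(rows=10, cols=10, center=(2, 2), amp=1.0, width=1.2):
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid = amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                        / (2 * width ** 2))
    return Portrait("toy", grid)


def dummy_model(rows=10, cols=10, n_samples=4):
    sinks = [f"s{u}" for u in range(rows * cols)]
    return SOMModel(
        SOMConfig(grid_rows=rows, grid_cols=cols),
        np.zeros((rows * cols, n_samples)),
        pd.Series(np.arange(rows * cols), index=sinks),
        [f"x{i}" for i in range(n_samples)],
    )


class TestSpots:
    def test_single_bump_gives_one_over_spot(self):
        model = dummy_model()
        spots = detect_spots(bump_portrait(), model)
        over = spots.by_polarity("over")
        assert len(over) == 1
        assert 2 * 10 + 2 in over[0].units  # the peak unit
        assert not spots.by_polarity("under")
        assert over[0].sink_ids  # sinks of member units reported

    def test_bump_and_dip_give_both_polarities(self):
        p = bump_portrait()
        p.grid -= bump_portrait(center=(7, 7)).grid
        spots = detect_spots(p, dummy_model())
        assert len(spots.by_polarity("over")) == 1
        assert len(spots.by_polarity("under")) == 1

    def test_flat_portrait_yields_no_spots(self):
        spots = detect_spots(Portrait("flat", np.zeros((10, 10))), dummy_model())
        assert spots.spots == []

    def test_threshold_predicate_exact(self):
        p = bump_portrait()
        model = dummy_model()
        spots = detect_spots(p, model, threshold_fraction=0.9)
        passing = set(np.flatnonzero(p.grid.ravel() >= 0.9 * p.grid.max()))
        got = {u for s in spots.by_polarity("over") for u in s.units}
        assert got == passing

    def test_kmeans_method_finds_the_bump(self):
        spots = detect_spots(bump_portrait(), dummy_model(), method="kmeans")
        over = spots.by_polarity("over")
        assert any(2 * 10 + 2 in s.units for s in over)


class TestSummaryMap:
    def test_disjoint_spots_stay_separate(self):
        model = dummy_model()
        s1 = detect_spots(bump_portrait(center=(1, 1)), model)
        s1.class_label = "c1"
        s2 = detect_spots(bump_portrait(center=(8, 8), amp=2.0), model)
        s2.class_label = "c2"
        summary = summary_spot_map([s1, s2], model)
        assert len(summary) == 2
        assert summary[0].label == "A" and summary[0].peak_value == pytest.approx(2.0)
        assert summary[0].classes == ["c2"]  # lettering by descending peak

    def test_overlapping_spots_merge(self):
        model = dummy_model()
        s1 = detect_spots(bump_portrait(center=(4, 4)), model)
        s1.class_label = "c1"
        s2 = detect_spots(bump_portrait(center=(4, 5)), model)
        s2.class_label = "c2"
        summary = summary_spot_map([s1, s2], model)
        assert len(summary) == 1
        assert summary[0].classes == ["c1", "c2"]

    def test_four_planted_branches_recovered_as_summary_spots(self):
        """4 classes each up-regulating the sinks of one pathway yield 4
        summary spots that together recover >= 80% of the planted sinks."""
        from psfsom import expression as expr_mod
        from psfsom import psf as psf_mod
        from psfsom.synth import ClassSpec, SyntheticDesign, generate_dataset

        targets = {}
        # first pass: discover sink ids of each pathway to plant on; keep
        # sinks whose private branch is the sink itself so the planted
        # amplitude is uniform within a class
        base = SyntheticDesign(seed=21, n_pathways=6,
                               classes=(ClassSpec("HC"),))
        from psfsom.synth import generate_pathways, private_branch

        graphs, _, _ = generate_pathways(base)
        for k in range(4):
            g = graphs[k]
            targets[f"D{k + 1}"] = tuple(
                f"{g.pathway_id}:{s}" for s in sorted(g.sinks)
                if len(private_branch(g, s)) == 1
            )
        classes = (ClassSpec("HC", 20),) + tuple(
            ClassSpec(label, 20, effect_size=4.0, direction="up",
                      target_sinks=sinks)
            for label, sinks in targets.items()
        )
        design = SyntheticDesign(seed=21, n_pathways=6, classes=classes)
        graphs, _, expr, sheet, truth = generate_dataset(design)
        linear, _ = expr_mod.detect_and_linearize(expr)
        fc = expr_mod.compute_fold_change(linear, sheet)
        psf_matrix = psf_mod.compute_psf_matrix(graphs, fc)
        model = train_som(psf_mod.centralize(psf_matrix), small_config(seed=2))
        spotsets = [detect_spots(p, model)
                    for p in all_portraits(model, sheet).values()]
        summary = summary_spot_map(spotsets, model, polarity="over")
        covered = {s for spot in summary for s in spot.sink_ids}
        planted = {s for sinks in truth.class_sinks.values()
                   for s, sign in sinks.items() if sign > 0}
        assert len(summary) >= 4
        assert len(planted & covered) / len(planted) >= 0.8
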