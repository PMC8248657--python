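"""Self-organizing map: determinism, convergence, topology, map summaries."""

import json

import numpy as np
import pandas as pd
import pytest

import hdweight as hw
from hdweight.som import SOMConfig, SOMModel, feature_columns, quantization_error


@pytest.fixture(scope="module")
def cluster_data():
    """16 well-separated point clouds of 20 samples in 5 dimensions."""
    rng = np.random.default_rng(3)
    centers = rng.uniform(0, 100, size=(16, 5))
    data = np.vstack([c + rng.normal(0, 0.5, size=(20, 5)) for c in centers])
    labels = np.repeat(np.arange(16), 20)
    return pd.DataFrame(data, columns=[f"f{i}" for i in range(5)]), labels


@pytest.fixture(scope="module")
def cluster_model(cluster_data):
    df, _ = cluster_data
    return hw.train_som(df, SOMConfig(epochs=100, seed=1))


def test_training_deterministic(cluster_data):
    df, _ = cluster_data
    a = hw.train_som(df, SOMConfig(epochs=20, seed=5))
    b = hw.train_som(df, SOMConfig(epochs=20, seed=5))
    assert np.array_equal(a.codebook, b.codebook)
    assert a.qe_trace == b.qe_trace


def test_quantization_error_decreases(cluster_model):
    assert cluster_model.qe_trace[-1] < cluster_model.qe_trace[0]


def test_separable_clusters_map_coherently(cluster_data, cluster_model):
    """Same-cluster samples share a BMU or land on grid-adjacent nodes."""
    df, labels = cluster_data
    bmus = np.array([hw.best_matching_unit(cluster_model, x)
                     for x in df.to_numpy()])
    ok = 0
    for k in range(16):
        nodes = bmus[labels == k]
        anchor = np.bincount(nodes).argmax()
        ar, ac = cluster_model.grid_position(anchor)
        for node in nodes:
            r, c = cluster_model.grid_position(node)
            ok += max(abs(r - ar), abs(c - ac)) <= 1
    assert ok / len(labels) >= 0.95


def test_bmu_nearest_identity_and_tie():
    model = SOMModel(config=SOMConfig(grid_rows=1, grid_cols=2, epochs=1),
                     columns=["a", "b"],
                     codebook=np.array([[0.0, 0.0], [1.0, 1.0]]))
    assert hw.best_matching_unit(model, np.array([0.9, 0.9])) == 2
    assert hw.best_matching_unit(model, np.array([1.0, 1.0])) == 2
    assert hw.best_matching_unit(model, np.array([0.5, 0.5])) == 1  # tie: low index
    with pytest.raises(ValueError):
        hw.best_matching_unit(model, np.array([1.0, 2.0, 3.0]))


def test_node_numbering_row_major_from_bottom_left():
    model = SOMModel(config=SOMConfig(grid_rows=4, grid_cols=4, epochs=1),
                     columns=["a"], codebook=np.zeros((16, 1)))
    assert model.grid_position(1) == (0, 0)
    assert model.grid_position(4) == (0, 3)
    assert model.grid_position(16) == (3, 3)


def test_count_plot_conservation(cluster_data, cluster_model):
    df, _ = cluster_data
    counts = hw.count_plot(cluster_model, df)
    assert counts["count"].sum() == len(df)
    assert len(counts) == cluster_model.n_nodes
    assert (counts["count"] >= 0).all()


def test_single_node_grid_collects_everything(cluster_data):
    df, _ = cluster_data
    model = hw.train_som(df, SOMConfig(grid_rows=1, grid_cols=1, epochs=5, seed=0))
    counts = hw.count_plot(model, df)
    assert counts["count"].tolist() == [len(df)]


def test_node_class_distribution(planted_kb):
    model = hw.train_som(planted_kb, SOMConfig(epochs=30, seed=2))
    dist = hw.node_class_distribution(model, planted_kb, "wtCat")
    sums = dist.sum(axis=1)
    assert ((sums == 0) | np.isclose(sums, 1.0)).all()
    # weighting by node occupancy recovers the marginal class distribution
    counts = hw.count_plot(model, planted_kb)["count"].to_numpy()
    marginal = (dist.to_numpy() * counts[:, None]).sum(axis=0) / counts.sum()
    expected = planted_kb["wtCat"].value_counts(normalize=True) \
        .reindex(dist.columns, fill_value=0.0).to_numpy()
    np.testing.assert_allclose(marginal, expected, atol=1e-12)
    with pytest.raises(KeyError):
        hw.node_class_distribution(model, planted_kb, "nosuch")


def test_component_heatmap_shape_and_bounds(cluster_data, cluster_model):
    df, _ = cluster_data
    grid, lo, hi = hw.component_heatmap(cluster_model, "f0")
    assert grid.shape == (4, 4)
    assert lo == grid.min() and hi == grid.max()
    # convex updates keep codebooks inside the data range per component
    assert grid.min() >= df["f0"].min() - 1e-9
    assert grid.max() <= df["f0"].max() + 1e-9
    with pytest.raises(KeyError):
        hw.component_heatmap(cluster_model, "nosuch")


def test_constant_factor_converges_to_constant():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"a": np.full(64, 3.0), "b": rng.normal(size=64)})
    model = hw.train_som(df, SOMConfig(epochs=10, seed=0))
    grid, _, _ = hw.component_heatmap(model, "a")
    np.testing.assert_allclose(grid, 3.0, atol=1e-6)


def test_codes_profile_consistency(cluster_model):
    profile = hw.codes_profile(cluster_model)
    assert len(profile) == cluster_model.n_nodes
    grid, _, _ = hw.component_heatmap(cluster_model, "f2")
    np.testing.assert_allclose(
        profile.sort_values("node")["f2"].to_numpy().reshape(4, 4), grid)


def test_model_json_round_trip(cluster_model):
    payload = json.loads(json.dumps(cluster_model.to_json_dict()))
    restored = SOMModel.from_json_dict(payload)
    np.testing.assert_allclose(restored.codebook, cluster_model.codebook)
    assert restored.columns == cluster_model.columns
    assert restored.qe_trace == pytest.approx(cluster_model.qe_trace)


def test_fewer_rows_than_nodes_rejected():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
    with pytest.raises(ValueError):
        hw.train_som(df, SOMConfig(grid_rows=4, grid_cols=4))


def test_class_column_toggle(planted_kb):
    with_class = feature_columns(planted_kb, include_class=True)
    without = feature_columns(planted_kb, include_class=False)
    assert "wtCat" in with_class and "wtCat" not in without
    model = hw.train_som(planted_kb.head(100),
                         SOMConfig(epochs=5, seed=0, include_class=False))
    assert "wtCat" not in model.columns
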