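"""Self-organizing map over ordinal-coded subject records.

A rectangular grid of codebook vectors is trained online with competitive
learning: each presented record is assigned to its best matching unit (BMU,
the node with the smallest Euclidean distance) and all nodes within the
current neighborhood radius move toward the record, scaled by the learning
rate and a Gaussian kernel of grid distance.  Learning rate and radius decay
linearly over the epochs.  Nodes are numbered 1..rows*cols row-major from
the bottom-left corner of the grid, matching the map layout used in the
summaries (node 1 bottom-left, node rows*cols top-right).

Category codes are used as raw numeric coordinates (their ordinal/numeric
property is deliberately preserved); optional per-column min-max scaling is
available for data whose factors span very different code ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rules import META_COLUMNS


@dataclass
class SOMConfig:
    grid_rows: int = 4
    grid_cols: int = 4
    epochs: int = 500
    learning_rate: tuple[float, float] = (0.05, 0.01)   # initial, final
    radius: tuple[float, float] | None = None           # default max(grid)/2 -> 1
    minmax_scale: bool = False
    include_class: bool = True        # keep the weight-category column as a coordinate
    seed: int = 0


@dataclass
class SOMModel:
    config: SOMConfig
    columns: list[str]
    codebook: np.ndarray                  # (n_nodes, n_features)
    qe_trace: list[float] = field(default_factory=list)
    scale_min: np.ndarray | None = None
    scale_range: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.config.grid_rows * self.config.grid_cols

    def grid_position(self, node: int) -> tuple[int, int]:
        """(row, col) of a 1-based node index; row 0 is the bottom of the map."""
        idx = node - 1
        return divmod(idx, self.config.grid_cols)

    def _grid_coords(self) -> np.ndarray:
        return np.array([self.grid_position(i + 1) for i in range(self.n_nodes)],
                        dtype=float)

    def transform(self, data: np.ndarray) -> np.ndarray:
        if self.scale_min is not None:
            return (data - self.scale_min) / self.scale_range
        return data

    def to_json_dict(self) -> dict:
        return {
            "config": {
                "grid_rows": self.config.grid_rows,
                "grid_cols": self.config.grid_cols,
                "epochs": self.config.epochs,
                "learning_rate": list(self.config.learning_rate),
                "radius": list(self.config.radius) if self.config.radius else None,
                "minmax_scale": self.config.minmax_scale,
                "include_class": self.config.include_class,
                "seed": self.config.seed,
            },
            "columns": self.columns,
            "codebook": self.codebook.tolist(),
            "qe_trace": self.qe_trace,
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "SOMModel":
        cfg = payload["config"]
        config = SOMConfig(grid_rows=cfg["grid_rows"], grid_cols=cfg["grid_cols"],
                           epochs=cfg["epochs"],
                           learning_rate=tuple(cfg["learning_rate"]),
                           radius=tuple(cfg["radius"]) if cfg["radius"] else None,
                           minmax_scale=cfg["minmax_scale"],
                           include_class=cfg["include_class"], seed=cfg["seed"])
        return cls(config=config, columns=list(payload["columns"]),
                   codebook=np.asarray(payload["codebook"], dtype=float),
                   qe_trace=list(payload["qe_trace"]))


def _data_matrix(dataset: pd.DataFrame, model_columns: list[str]) -> np.ndarray:
    return dataset[model_columns].to_numpy(dtype=float)


def feature_columns(dataset: pd.DataFrame, include_class: bool = True,
                    class_column: str = "wtCat") -> list[str]:
    cols = [c for c in dataset.columns if c not in META_COLUMNS]
    if not include_class and class_column in cols:
        cols.remove(class_column)
    return cols


def train_som(dataset: pd.DataFrame, config: SOMConfig | None = None) -> SOMModel:
    """Train a SOM on the categorical dataset; deterministic given the seed.

    Codebooks are initialized uniformly within each feature's observed range.
    Records are presented in a freshly shuffled order every epoch.  The
    per-epoch mean record-to-BMU distance (quantization error, computed at
    assignment time) is recorded as the training trace.
    """
    if config is None:
        config = SOMConfig()
    cols = feature_columns(dataset, include_class=config.include_class)
    data = dataset[cols].to_numpy(dtype=float)
    n_nodes = config.grid_rows * config.grid_cols
    if len(data) < n_nodes:
        raise ValueError(
            f"dataset has {len(data)} rows, fewer than the {n_nodes} map nodes")
    rng = np.random.default_rng(config.seed)

    model = SOMModel(config=config, columns=cols,
                     codebook=np.empty((n_nodes, data.shape[1])))
    if config.minmax_scale:
        model.scale_min = data.min(axis=0)
        rng_span = data.max(axis=0) - model.scale_min
        model.scale_range = np.where(rng_span > 0, rng_span, 1.0)
        data = model.transform(data)

    lo, hi = data.min(axis=0), data.max(axis=0)
    model.codebook[:] = rng.uniform(lo, hi, size=(n_nodes, data.shape[1]))

    grid = model._grid_coords()
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)

    lr0, lr1 = config.learning_rate
    if config.radius is None:
        r0, r1 = max(config.grid_rows, config.grid_cols) / 2.0, 1.0
    else:
        r0, r1 = config.radius
    epochs = config.epochs
    codebook = model.codebook
    for epoch in range(epochs):
        t = epoch / max(epochs - 1, 1)
        lr = lr0 + (lr1 - lr0) * t
        radius = r0 + (r1 - r0) * t
        kernel_scale = 2.0 * radius * radius
        order = rng.permutation(len(data))
        qe_sum = 0.0
        for i in order:
            x = data[i]
            d2 = ((codebook - x) ** 2).sum(axis=1)
            bmu = int(d2.argmin())
            qe_sum += float(np.sqrt(d2[bmu]))
            neighbor = grid_d2[bmu] <= radius * radius
            h = lr * np.exp(-grid_d2[bmu][neighbor] / kernel_scale)
            codebook[neighbor] += h[:, None] * (x - codebook[neighbor])
        model.qe_trace.append(qe_sum / len(data))
    return model


def best_matching_unit(model: SOMModel, record: np.ndarray) -> int:
    """1-based index of the node nearest to ``record``; ties pick the lowest index."""
    record = np.asarray(record, dtype=float)
    if record.shape != (model.codebook.shape[1],):
        raise ValueError(
            f"record length {record.shape} does not match codebook width "
            f"{model.codebook.shape[1]}")
    record = model.transform(record)
    d2 = ((model.codebook - record) ** 2).sum(axis=1)
    return int(d2.argmin()) + 1


def _bmu_assignments(model: SOMModel, dataset: pd.DataFrame) -> np.ndarray:
    data = model.transform(_data_matrix(dataset, model.columns))
    d2 = ((data[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1


def quantization_error(model: SOMModel, dataset: pd.DataFrame) -> float:
    """Mean Euclidean distance from each record to its BMU."""
    data = model.transform(_data_matrix(dataset, model.columns))
    d2 = ((data[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def count_plot(model: SOMModel, dataset: pd.DataFrame) -> pd.DataFrame:
    """Records per node: columns node, row, col, count (empty nodes report 0)."""
    bmus = _bmu_assignments(model, dataset)
    counts = np.bincount(bmus - 1, minlength=model.n_nodes)
    rows = [{"node": i + 1, "row": model.grid_position(i + 1)[0],
             "col": model.grid_position(i + 1)[1], "count": int(counts[i])}
            for i in range(model.n_nodes)]
    return pd.DataFrame(rows)


def node_class_distribution(model: SOMModel, dataset: pd.DataFrame,
                            factor: str = "wtCat") -> pd.DataFrame:
    """Per-node category frequencies of ``factor`` (each node's row sums to 1)."""
    if factor not in dataset.columns:
        raise KeyError(f"unknown factor {factor!r}")
    bmus = _bmu_assignments(model, dataset)
    cats = sorted(dataset[factor].unique())
    table = pd.DataFrame(0.0, index=pd.RangeIndex(1, model.n_nodes + 1, name="node"),
                         columns=cats)
    frame = pd.DataFrame({"node": bmus, factor: dataset[factor].to_numpy()})
    counts = frame.groupby(["node", factor]).size().unstack(fill_value=0)
    table.loc[counts.index, counts.columns] = counts.to_numpy(dtype=float)
    sums = table.sum(axis=1)
    nonempty = sums > 0
    table.loc[nonempty] = table.loc[nonempty].div(sums[nonempty], axis=0)
    return table


def component_heatmap(model: SOMModel, factor: str) -> tuple[np.ndarray, float, float]:
    """Codebook component of ``factor`` as a (rows, cols) grid plus its min/max.

    Row 0 of the returned grid is the bottom row of the map.
    """
    if factor not in model.columns:
        raise KeyError(f"unknown factor {factor!r}")
    j = model.columns.index(factor)
    grid = model.codebook[:, j].reshape(model.config.grid_rows,
                                        model.config.grid_cols)
    return grid, float(grid.min()), float(grid.max())


def codes_profile(model: SOMModel) -> pd.DataFrame:
    """All codebook vectors with node/grid coordinates, one row per node."""
    rows = []
    for i in range(model.n_nodes):
        r, c = model.grid_position(i + 1)
        row = {"node": i + 1, "row": r, "col": c}
        row.update({col: model.codebook[i, j] for j, col in enumerate(model.columns)})
        rows.append(row)
    return pd.DataFrame(rows)
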