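"""Self-organizing map portraits of pathway sink activity.

The centered log2 PSF profile of every pathway sink (one value per sample)
is placed on a rectangular SOM grid.  Each grid unit holds a weight vector
of the same length as a profile — a *meta-PSF*, the prototype of the sinks
assigned to that unit.  Averaging the unit weights over the samples of one
class gives that class's *portrait*, a 2-D image whose smooth red/blue
regions ("spots") correspond to concertedly up-/down-regulated sink
clusters.

Training is classic online Kohonen learning: winner by Euclidean distance,
inverse-time learning-rate decay alpha(t) = alpha0 / (1 + c * t), Gaussian
neighborhood truncated at the configured radius.  Defaults follow the
published configuration (50 x 50 grid, alpha0 = 0.02, c = 0.01, radius 3,
12 epochs); tests and desk-scale runs shrink the grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass
class SOMConfig:
    grid_rows: int = 50
    grid_cols: int = 50
    learning_rate: float = 0.02   # alpha0
    lr_constant: float = 0.01     # c in alpha(t) = alpha0 / (1 + c t)
    radius: float = 3.0
    epochs: int = 12
    seed: int = 0


@dataclass
class SOMModel:
    """Trained map: unit weights (meta-PSFs) plus the sink -> unit assignment."""

    config: SOMConfig
    weights: np.ndarray            # (rows*cols, n_samples)
    assignment: pd.Series          # sink_id -> flat unit index
    sample_ids: list[str]
    quantization_error: float = 0.0

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.config.grid_rows, self.config.grid_cols)

    def unit_coords(self, flat: int) -> tuple[int, int]:
        return divmod(flat, self.config.grid_cols)

    def sinks_of_unit(self, flat: int) -> list[str]:
        return sorted(self.assignment.index[self.assignment == flat])

    # portable, binary-free persistence --------------------------------------
    def save(self, json_path, weights_tsv_path) -> None:
        meta = {
            "config": vars(self.config),
            "sample_ids": list(map(str, self.sample_ids)),
            "assignment": {k: int(v) for k, v in self.assignment.items()},
            "quantization_error": self.quantization_error,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)
        pd.DataFrame(self.weights, columns=self.sample_ids).to_csv(
            weights_tsv_path, sep="\t", index_label="unit"
        )

    @classmethod
    def load(cls, json_path, weights_tsv_path) -> "SOMModel":
        with open(json_path) as fh:
            meta = json.load(fh)
        weights = pd.read_csv(weights_tsv_path, sep="\t", index_col="unit")
        return cls(
            SOMConfig(**meta["config"]),
            weights.to_numpy(dtype=float),
            pd.Series(meta["assignment"], dtype=int),
            meta["sample_ids"],
            meta.get("quantization_error", 0.0),
        )


def _neighborhood_kernel(rows: int, cols: int, radius: float):
    """Per-unit precomputed (unit_indices, gaussian_weights) within radius."""
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    kernel = []
    for u in range(rows * cols):
        d2 = (rr - rr[u]) ** 2 + (cc - cc[u]) ** 2
        inside = np.flatnonzero(d2 <= radius * radius)
        h = np.exp(-d2[inside] / (2.0 * radius * radius))
        kernel.append((inside, h[:, None]))
    return kernel


def train_som(centralized: pd.DataFrame, config: SOMConfig | None = None) -> SOMModel:
    """Train a SOM on sink profiles (rows of ``centralized``).

    Unit weights are linearly initialized on the first two principal
    components of the sink profiles.  Each epoch presents all sinks once in
    a freshly shuffled order;
    the best-matching unit is found by Euclidean distance and the unit
    neighborhood within ``radius`` is pulled towards the profile with a
    Gaussian falloff.  Fully deterministic for a fixed seed.
    """
    config = config or SOMConfig()
    data = centralized.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("SOM input contains non-finite values")
    n_sinks, n_samples = data.shape
    if n_sinks < 2 or n_samples < 2:
        raise ValueError("SOM training needs at least 2 sinks and 2 samples")

    rng = np.random.default_rng(config.seed)
    n_units = config.grid_rows * config.grid_cols
    # linear initialization: units start on the plane of the first two
    # principal components, so the map is globally ordered from the outset
    # and units never won by a sink still hold data-like profiles (a random
    # init would leave them with arbitrary values that can dominate class
    # portraits on sparse maps)
    mean = data.mean(axis=0)
    centered = data - mean
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores1 = centered @ vt[0]
    scores2 = centered @ vt[1] if len(s) > 1 else np.zeros(n_sinks)
    rr = np.linspace(scores1.min(), scores1.max(), config.grid_rows)
    cc = np.linspace(scores2.min(), scores2.max(), config.grid_cols)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    weights = (
        mean
        + grid_r.reshape(-1, 1) * vt[0]
        + (grid_c.reshape(-1, 1) * vt[1] if len(s) > 1 else 0.0)
    )
    kernel = _neighborhood_kernel(config.grid_rows, config.grid_cols, config.radius)

    # cached squared norms make the BMU search a single matvec per step
    norms = np.einsum("ij,ij->i", weights, weights)
    for epoch in range(config.epochs):
        # inverse learning-rate decay per epoch: alpha_e = alpha0 / (1 + c e)
        alpha = config.learning_rate / (1.0 + config.lr_constant * epoch)
        for i in rng.permutation(n_sinks):
            x = data[i]
            dist2 = norms - 2.0 * (weights @ x)  # + ||x||^2, constant in argmin
            bmu = int(np.argmin(dist2))
            units, h = kernel[bmu]
            weights[units] += alpha * h * (x - weights[units])
            norms[units] = np.einsum("ij,ij->i", weights[units], weights[units])

    # final hard assignment of every sink to its best-matching unit
    d = (
        norms[None, :]
        - 2.0 * data @ weights.T
        + np.einsum("ij,ij->i", data, data)[:, None]
    )
    bmus = d.argmin(axis=1)
    qe = float(np.sqrt(np.maximum(d[np.arange(n_sinks), bmus], 0.0)).mean())
    assignment = pd.Series(bmus, index=centralized.index, dtype=int)
    logger.info("SOM trained: %d sinks on %dx%d grid, QE=%.4f",
                n_sinks, config.grid_rows, config.grid_cols, qe)
    return SOMModel(config, weights, assignment, list(centralized.columns), qe)


# ---------------------------------------------------------------------------
# portraits
# ---------------------------------------------------------------------------

@dataclass
class Portrait:
    class_label: str
    grid: np.ndarray  # (rows, cols) meta-PSF values averaged over the class


def class_portrait(model: SOMModel, sheet: pd.DataFrame, class_label: str) -> Portrait:
    """Average the meta-PSF weights over the samples of one class."""
    cols = sheet.loc[sheet["class_label"] == class_label, "sample_id"].tolist()
    positions = [model.sample_ids.index(c) for c in cols if c in model.sample_ids]
    if not positions:
        raise ValueError(f"class {class_label!r} has no samples in the model")
    grid = model.weights[:, positions].mean(axis=1).reshape(model.grid_shape)
    return Portrait(class_label, grid)


def all_portraits(model: SOMModel, sheet: pd.DataFrame) -> dict[str, Portrait]:
    return {
        label: class_portrait(model, sheet, label)
        for label in sorted(sheet["class_label"].unique())
    }


def portrait_ascii(portrait: Portrait, levels: str = " .:-=+*#%@") -> str:
    """Coarse ASCII rendering of a portrait (low -> high)."""
    g = portrait.grid
    span = g.max() - g.min()
    scaled = np.zeros_like(g, dtype=int) if span == 0 else np.minimum(
        ((g - g.min()) / span * len(levels)).astype(int), len(levels) - 1
    )
    return "\n".join("".join(levels[v] for v in row) for row in scaled)


def portrait_png(portrait: Portrait, path) -> None:
    """Heatmap on the blue-yellow-red diverging palette used for portraits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    lim = max(abs(portrait.grid.min()), abs(portrait.grid.max())) or 1.0
    im = ax.imshow(portrait.grid, cmap="RdYlBu_r", vmin=-lim, vmax=lim)
    ax.set_title(portrait.class_label)
    ax.set_xticks([]); ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------

@dataclass
class Spot:
    polarity: str                # "over" | "under"
    units: list[int]             # flat unit indices, 4-connected component
    sink_ids: list[str]
    peak_value: float


@dataclass
class SpotSet:
    class_label: str
    spots: list[Spot] = field(default_factory=list)

    def by_polarity(self, polarity: str) -> list[Spot]:
        return [s for s in self.spots if s.polarity == polarity]


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _components(mask: np.ndarray) -> list[np.ndarray]:
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    flat = labels.ravel()
    return [np.flatnonzero(flat == k) for k in range(1, n + 1)]


def detect_spots(
    portrait: Portrait,
    model: SOMModel,
    threshold_fraction: float = 0.90,
    method: str = "threshold",
) -> SpotSet:
    """Find over-/under-expression spots of a portrait.

    With the default ``threshold`` method a unit belongs to an over-spot if
    its value is at least ``threshold_fraction`` of the portrait maximum
    (only when that maximum is positive); under-spots mirror this at the
    minimum.  Spots are the 4-connected components of qualifying units on
    the non-toroidal grid.  ``method="kmeans"`` instead clusters unit values
    into three groups and takes the extreme clusters.
    """
    g = portrait.grid
    if np.ptp(g) == 0:
        logger.warning("constant portrait %s: no spots", portrait.class_label)
        return SpotSet(portrait.class_label, [])

    if method == "threshold":
        over_mask = (g >= threshold_fraction * g.max()) if g.max() > 0 else \
            np.zeros_like(g, bool)
        under_mask = (g <= threshold_fraction * g.min()) if g.min() < 0 else \
            np.zeros_like(g, bool)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=3, n_init=5, random_state=0).fit(g.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_.ravel())
        lab = km.labels_.reshape(g.shape)
        over_mask = (lab == order[-1]) & (g > 0)
        under_mask = (lab == order[0]) & (g < 0)
    else:
        raise ValueError(f"unknown spot method {method!r}")

    spots: list[Spot] = []
    for polarity, mask in (("over", over_mask), ("under", under_mask)):
        for units in _components(mask):
            vals = g.ravel()[units]
            peak = float(vals.max() if polarity == "over" else vals.min())
            sinks = sorted(
                sid for u in units for sid in model.sinks_of_unit(int(u))
            )
            spots.append(Spot(polarity, [int(u) for u in units], sinks, peak))
    return SpotSet(portrait.class_label, spots)


@dataclass
class SummarySpot:
    label: str                   # "A", "B", ... by descending peak value
    units: list[int]
    sink_ids: list[str]
    classes: list[str]
    peak_value: float


def summary_spot_map(
    spotsets: list[SpotSet], model: SOMModel, polarity: str = "over"
) -> list[SummarySpot]:
    """Merge the class spots of one polarity into lettered summary spots.

    All class spots are projected onto one grid; overlapping or touching
    spots merge into a single summary spot (4-connected union), which
    records its member sinks and the classes whose portraits activate it.
    """
    if not spotsets:
        raise ValueError("summary map needs at least one class spot set")
    rows, cols = model.grid_shape
    mask = np.zeros(rows * cols, dtype=bool)
    peak = np.zeros(rows * cols)
    sign = 1.0 if polarity == "over" else -1.0
    for ss in spotsets:
        for spot in ss.by_polarity(polarity):
            mask[spot.units] = True
            peak[spot.units] = np.maximum(peak[spot.units], sign * spot.peak_value)

    comps = _components(mask.reshape(rows, cols))
    comps.sort(key=lambda units: -peak[units].max())
    out = []
    for i, units in enumerate(comps):
        unit_set = set(int(u) for u in units)
        classes = sorted(
            ss.class_label
            for ss in spotsets
            if any(set(s.units) & unit_set for s in ss.by_polarity(polarity))
        )
        sinks = sorted(sid for u in unit_set for sid in model.sinks_of_unit(u))
        label = chr(ord("A") + i) if i < 26 else f"S{i}"
        out.append(SummarySpot(label, sorted(unit_set), sinks, classes,
                               sign * peak[units].max()))
    return out


def spots_to_json(spotsets: list[SpotSet], summary: list[SummarySpot]) -> str:
    return json.dumps(
        {
            "classes": {
                ss.class_label: [
                    {
                        "polarity": s.polarity,
                        "units": s.units,
                        "sinks": s.sink_ids,
                        "peak": s.peak_value,
                    }
                    for s in ss.spots
                ]
                for ss in spotsets
            },
            "summary": [
                {
                    "label": s.label,
                    "units": s.units,
                    "sinks": s.sink_ids,
                    "classes": s.classes,
                    "peak": s.peak_value,
                }
                for s in summary
            ],
        },
        indent=1,
    )
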