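"""Class-level similarity: clustering, second-level SOM, ICA, communities.

Sample classes (diseases) are compared through their portrait profiles —
the flattened meta-PSF grids — and through the pattern of pathways they
deregulate versus the healthy controls.  The co-regulation graph connects
two classes by the number of pathways with at least one sink significantly
deregulated in the *same direction* in both; random-walk (walktrap)
community detection on this weighted graph groups diseases with shared
pathway deregulation states.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import igraph as ig
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import FastICA

from .som import SOMConfig, SOMModel, all_portraits, train_som


def class_profile_matrix(model: SOMModel, sheet: pd.DataFrame) -> pd.DataFrame:
    """Classes x meta-PSF matrix (flattened portraits), rows sorted by label."""
    portraits = all_portraits(model, sheet)
    return pd.DataFrame(
        {label: p.grid.ravel() for label, p in portraits.items()}
    ).T.sort_index()


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(
    class_profiles: pd.DataFrame, metric: str = "pearson"
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage dendrogram over class profiles.

    ``metric`` is ``pearson`` (distance 1 - r) or ``euclidean``.  Classes are
    processed in sorted label order so the linkage is deterministic.
    Returns ``(linkage_matrix, labels)``.
    """
    profiles = class_profiles.sort_index()
    labels = list(profiles.index)
    if len(labels) < 3:
        raise ValueError("hierarchical clustering needs at least 3 classes")
    x = profiles.to_numpy(dtype=float)
    if metric == "pearson":
        if np.any(x.std(axis=1) == 0):
            flat = [l for l, s in zip(labels, x.std(axis=1)) if s == 0]
            raise ValueError(f"constant profile(s) under Pearson: {flat}")
        dist = pdist(x, metric="correlation")  # 1 - r
    elif metric == "euclidean":
        dist = pdist(x, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return hierarchy.average(dist), labels


def cut_first_split(linkage: np.ndarray, labels: list[str]) -> tuple[set, set]:
    """The two groups produced by the dendrogram's topmost merge."""
    assignments = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    g1 = {l for l, a in zip(labels, assignments) if a == 1}
    g2 = {l for l, a in zip(labels, assignments) if a == 2}
    return g1, g2


def dendrogram_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# second-level SOM and ICA
# ---------------------------------------------------------------------------

def second_level_som(
    class_profiles: pd.DataFrame, grid: tuple[int, int] = (5, 5), seed: int = 0
) -> pd.DataFrame:
    """Place each class on a small SOM grid trained on class profiles.

    Returns a DataFrame indexed by class with ``row``/``col`` coordinates of
    each class's best-matching unit.
    """
    if class_profiles.shape[0] < 4:
        raise ValueError("second-level SOM needs at least 4 classes")
    cfg = SOMConfig(grid_rows=grid[0], grid_cols=grid[1], epochs=20, seed=seed)
    model = train_som(class_profiles.sort_index(), cfg)
    coords = {
        label: model.unit_coords(int(unit))
        for label, unit in model.assignment.items()
    }
    return pd.DataFrame(coords, index=["row", "col"]).T


def run_ica(
    class_profiles: pd.DataFrame, n_components: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Independent component scores per class, sign-fixed for determinism.

    Each component's sign is chosen so that its largest-magnitude class
    score is positive.
    """
    x = class_profiles.sort_index().to_numpy(dtype=float)
    if n_components > x.shape[0] - 1:
        raise ValueError("n_components must be <= number of classes - 1")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < n_components:
        raise ValueError("class profile matrix is rank degenerate for ICA")
    ica = FastICA(
        n_components=n_components, random_state=seed, whiten="unit-variance",
        max_iter=2000,
    )
    scores = ica.fit_transform(x)
    for j in range(scores.shape[1]):
        k = int(np.abs(scores[:, j]).argmax())
        if scores[k, j] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores,
        index=class_profiles.sort_index().index,
        columns=[f"IC{j + 1}" for j in range(n_components)],
    )


# ---------------------------------------------------------------------------
# co-regulation graph and communities
# ---------------------------------------------------------------------------

def _pathway_of(sink_id: str) -> str:
    return sink_id.split(":", 1)[0]


def coregulation_count(
    diff_a: pd.DataFrame, diff_b: pd.DataFrame, level: str = "pathway"
) -> int:
    """Number of pathways (or sinks) deregulated the same way in two classes.

    A sink co-regulates when it is significant in both classes with the same
    sign of delta; at ``level="pathway"`` one such sink suffices for the
    whole pathway to count.
    """
    merged = diff_a.merge(diff_b, on="sink_id", suffixes=("_a", "_b"))
    shared = merged[
        merged["significant_a"]
        & merged["significant_b"]
        & (np.sign(merged["delta_a"]) == np.sign(merged["delta_b"]))
        & (merged["delta_a"] != 0)
    ]
    if level == "sink":
        return int(shared.shape[0])
    return int(shared["sink_id"].map(_pathway_of).nunique())


def build_disease_graph(
    differential: dict[str, pd.DataFrame], level: str = "pathway"
) -> ig.Graph:
    """Weighted class graph; edge weight = co-regulated pathway count.

    ``differential`` maps each class label to its differential-vs-healthy
    table (:func:`psfsom.stats.differential_psf` output).  Classes with no
    shared deregulation stay unconnected.
    """
    labels = sorted(differential)
    g = ig.Graph()
    g.add_vertices(labels)
    edges, weights = [], []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            w = coregulation_count(differential[a], differential[b], level=level)
            if w >= 1:
                edges.append((a, b))
                weights.append(w)
    g.add_edges(edges)
    g.es["weight"] = weights
    return g


def walktrap_communities(graph: ig.Graph, steps: int = 4) -> pd.Series:
    """Walktrap community labels per class; isolates become singletons."""
    if graph.vcount() == 0 or graph.ecount() == 0:
        raise ValueError("disease graph has no edges")
    dendro = graph.community_walktrap(weights="weight", steps=steps)
    clustering = dendro.as_clustering()
    return pd.Series(clustering.membership, index=graph.vs["name"], name="community")


def graph_to_edge_list(graph: ig.Graph) -> pd.DataFrame:
    rows = [
        (graph.vs[e.source]["name"], graph.vs[e.target]["name"], int(e["weight"]))
        for e in graph.es
    ]
    return pd.DataFrame(rows, columns=["class_a", "class_b", "weight"])


def fruchterman_reingold_layout(graph: ig.Graph, seed: int = 0) -> pd.DataFrame:
    """Visualization-only 2-D layout of the disease graph."""
    import random

    random.seed(seed)
    coords = graph.layout_fruchterman_reingold(weights="weight", niter=500)
    return pd.DataFrame(coords.coords, index=graph.vs["name"], columns=["x", "y"])
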