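"""3x3 self-organizing map over time-course profiles and correlation trees.

The SOM is the classic online algorithm: codebook vectors on a small
rectangular grid, each training step pulls the best-matching unit (BMU) and
its grid neighbors (Gaussian neighborhood) toward one input profile, with
the learning rate and neighborhood radius decaying over iterations. The
codebook is initialized deterministically on the grid spanned by the first
two principal directions of the data, with a seeded random fallback for
degenerate inputs. Given a seed the result is fully reproducible.

Gene and condition trees use 1 - Spearman rank correlation as the
dissimilarity with average-linkage agglomeration (scipy), exported as
Newick.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_SHAPE = (3, 3)
DEFAULT_ITERATIONS = 2000
DEFAULT_LEARNING_RATE = 0.5


@dataclass
class SOMGrid:
    shape: tuple[int, int]
    codebook: np.ndarray            # (rows*cols, n_timepoints)
    assignments: pd.Series          # gene -> flat node index
    params: dict = field(default_factory=dict)

    def node_of(self, gene: str) -> tuple[int, int]:
        flat = int(self.assignments[gene])
        return divmod(flat, self.shape[1])

    @property
    def node_labels(self) -> pd.DataFrame:
        rows, cols = np.divmod(self.assignments.to_numpy(), self.shape[1])
        return pd.DataFrame(
            {"node": self.assignments, "row": rows, "col": cols},
            index=self.assignments.index,
        )

    def quantization_error(self, profiles: pd.DataFrame) -> float:
        X = profiles.to_numpy(dtype=float)
        assigned = self.codebook[self.assignments.to_numpy()]
        return float(np.sqrt(((X - assigned) ** 2).sum(axis=1)).mean())

    def write_tsv(self, assignments_path: str | Path, codebook_path: str | Path) -> None:
        self.node_labels.to_csv(assignments_path, sep="\t")
        pd.DataFrame(
            self.codebook,
            index=[f"node_{i}" for i in range(self.codebook.shape[0])],
        ).to_csv(codebook_path, sep="\t")


def _pca_grid_init(X: np.ndarray, shape: tuple[int, int]) -> np.ndarray | None:
    """Deterministic codebook: a grid spanned by the two leading PCs."""
    mean = X.mean(axis=0)
    centered = X - mean
    try:
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
    except np.linalg.LinAlgError:
        return None
    if s.size < 2 or s[1] <= 0:
        return None
    # fix sign convention so the init is reproducible across BLAS builds
    for i in range(2):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    sd = s[:2] / np.sqrt(max(X.shape[0] - 1, 1))
    rows, cols = shape
    ra = np.linspace(-1, 1, rows) if rows > 1 else np.zeros(1)
    ca = np.linspace(-1, 1, cols) if cols > 1 else np.zeros(1)
    book = np.empty((rows * cols, X.shape[1]))
    for r in range(rows):
        for c in range(cols):
            book[r * cols + c] = mean + ra[r] * sd[0] * vt[0] + ca[c] * sd[1] * vt[1]
    return book


def som_cluster(
    profiles: pd.DataFrame,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    n_iterations: int = DEFAULT_ITERATIONS,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
    init: str = "pca",
    metric: str = "euclidean",
) -> SOMGrid:
    """Train an online SOM and assign every profile to its best node.

    ``profiles`` is genes x time points (replicate-averaged, normalized and
    logged upstream). The neighborhood radius decays linearly from
    max(shape)/2 to 0.5 and the learning rate from ``learning_rate`` to 1%
    of it. BMU search uses Euclidean distance by default; ``metric
    ="correlation"`` searches by 1 - Pearson r instead.
    """
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain NaN or infinite values")
    n, d = X.shape
    rows, cols = shape
    n_nodes = rows * cols
    if n < n_nodes:
        raise ValueError(f"need at least {n_nodes} profiles for a {shape} grid")
    rng = np.random.default_rng(seed)

    if np.ptp(X) == 0:
        warnings.warn("constant input: all profiles assigned to node 0")
        book = np.tile(X[0], (n_nodes, 1)).astype(float)
        assignments = pd.Series(0, index=profiles.index, name="node")
        return SOMGrid((rows, cols), book, assignments, {"degenerate": True})

    book = _pca_grid_init(X, shape) if init == "pca" else None
    if book is None:
        book = X[rng.choice(n, size=n_nodes, replace=False)].astype(float).copy()
        init = "random"
    grid_pos = np.array([(r, c) for r in range(rows) for c in range(cols)], float)
    grid_d2 = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(-1)

    r0, r1 = max(rows, cols) / 2.0, 0.5
    lr0, lr1 = learning_rate, learning_rate * 0.01
    order = rng.permutation(n)
    for t in range(n_iterations):
        x = X[order[t % n]]
        if t % n == n - 1:  # reshuffle between epochs
            order = rng.permutation(n)
        frac = t / max(n_iterations - 1, 1)
        radius = r0 + (r1 - r0) * frac
        lr = lr0 + (lr1 - lr0) * frac
        bmu = _bmu(book, x, metric)
        h = np.exp(-grid_d2[bmu] / (2.0 * radius**2))
        book += (lr * h)[:, None] * (x - book)

    bmus = _bmu_batch(book, X, metric)
    assignments = pd.Series(bmus, index=profiles.index, name="node")
    return SOMGrid(
        (rows, cols),
        book,
        assignments,
        {
            "n_iterations": n_iterations,
            "learning_rate": learning_rate,
            "seed": seed,
            "init": init,
            "metric": metric,
        },
    )


def _bmu(book: np.ndarray, x: np.ndarray, metric: str) -> int:
    if metric == "euclidean":
        return int(np.argmin(((book - x) ** 2).sum(axis=1)))
    if metric == "correlation":
        bc = book - book.mean(axis=1, keepdims=True)
        xc = x - x.mean()
        denom = np.sqrt((bc**2).sum(axis=1) * (xc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, bc @ xc / denom, 0.0)
        return int(np.argmax(r))
    raise ValueError(f"unknown metric {metric!r}")


def _bmu_batch(book: np.ndarray, X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        d2 = ((X[:, None, :] - book[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)
    return np.array([_bmu(book, x, metric) for x in X])


def cluster_report(
    som: SOMGrid, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Per-node member count, member list and mean profile."""
    rows = []
    for node in range(som.shape[0] * som.shape[1]):
        members = list(som.assignments.index[som.assignments == node])
        mean = (
            profiles.loc[members].mean(axis=0)
            if members
            else pd.Series(np.nan, index=profiles.columns)
        )
        r, c = divmod(node, som.shape[1])
        rows.append(
            {
                "node": node,
                "row": r,
                "col": c,
                "n_members": len(members),
                "members": ",".join(members),
                **{f"mean_{t}": mean[t] for t in profiles.columns},
            }
        )
    report = pd.DataFrame(rows).set_index("node")
    assert report["n_members"].sum() == len(som.assignments)
    return report


# ---------------------------------------------------------------------------
# Spearman / average-linkage trees


@dataclass
class Dendrogram:
    linkage: np.ndarray        # scipy linkage matrix
    labels: list[str]
    dropped: list[str]         # constant items excluded from the tree

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def build_tree(matrix: pd.DataFrame, axis: str = "genes") -> Dendrogram:
    """Average-linkage tree on 1 - Spearman rank correlation.

    ``axis="genes"`` clusters rows, ``axis="conditions"`` clusters columns.
    Constant items have undefined rank correlation and are dropped with a
    warning.
    """
    if axis == "conditions":
        matrix = matrix.T
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'conditions'")
    X = matrix.to_numpy(dtype=float)
    labels = [str(i) for i in matrix.index]
    const = np.ptp(X, axis=1) == 0
    dropped = [labels[i] for i in np.flatnonzero(const)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant item(s) with undefined "
            f"rank correlation: {dropped[:5]}"
        )
        X = X[~const]
        labels = [l for l, c in zip(labels, const) if not c]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 non-constant items to build a tree")
    ranks = pd.DataFrame(X).rank(axis=1).to_numpy()
    rho = np.corrcoef(ranks)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)  # enforce exact symmetry
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(Z, labels, dropped)
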