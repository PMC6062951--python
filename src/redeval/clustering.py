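"""Single-linkage clustering of models and Kolmogorov-Smirnov consistency
scoring.

All n * 2^c models (every parameter set under every reduction) are
clustered agglomeratively with the symmetric trajectory error as
dissimilarity; inter-cluster distance is the minimum pairwise error.  Each
model's *dendrogram position* is its leaf index in a canonical left-to-right
ordering of the dendrogram.  A reduction's score is the two-sample
Kolmogorov-Smirnov statistic between its n positions and the full model's n
positions: 0 means the reduction is distributed through the dendrogram
exactly like the full model, 1 means complete separation.  Reductions
scoring below a threshold alpha (default 0.2) are *consistent*, and the
best reduced model is the consistent one clamping the most complexes (ties:
lowest score, then lexicographically smallest bitmask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp

from .metrics import DissimilarityMatrix

__all__ = [
    "LinkageTree",
    "single_linkage",
    "leaf_positions",
    "ks_score",
    "score_all",
    "best_model",
    "prefilter_reductions",
    "write_linkage",
    "write_score_table",
]

DEFAULT_ALPHA = 0.2


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history in SciPy linkage layout: row i merges
    clusters ``merges[i, 0]`` and ``merges[i, 1]`` (ids < N are leaves,
    id N + i is the cluster created by row i) at height ``merges[i, 2]``
    into a cluster of size ``merges[i, 3]``."""

    merges: np.ndarray  # (N-1, 4)
    leaf_count: int

    def __post_init__(self):
        m = np.asarray(self.merges, dtype=float)
        object.__setattr__(self, "merges", m)
        if self.leaf_count >= 2 and m.shape != (self.leaf_count - 1, 4):
            raise ValueError("expected N-1 merge rows")


def single_linkage(D: DissimilarityMatrix) -> LinkageTree:
    """Single-linkage tree of the dissimilarity matrix.

    Merge heights are the minimum pairwise symmetric errors and are
    non-decreasing along the merge sequence.
    """
    V = D.values
    if not np.all(np.isfinite(V)):
        raise ValueError("dissimilarity matrix contains non-finite entries")
    if D.n == 1:
        return LinkageTree(np.empty((0, 4)), 1)
    condensed = squareform(np.maximum(V, V.T), checks=False)
    return LinkageTree(linkage(condensed, method="single"), D.n)


def leaf_positions(tree: LinkageTree) -> np.ndarray:
    """Position (1..N) of each leaf in the canonical dendrogram ordering.

    The ordering is a depth-first left-to-right traversal in which, at
    every merge, the child cluster created earlier is placed on the left
    (leaves count as created at time zero, ordered by label; merged
    clusters in merge order).  Cluster ids already encode creation order,
    so "earlier" is simply the smaller id.
    """
    N = tree.leaf_count
    if N == 1:
        return np.array([1])
    order: list[int] = []
    stack = [2 * N - 2]  # root cluster id
    while stack:
        node = stack.pop()
        if node < N:
            order.append(node)
        else:
            a, b = int(tree.merges[node - N, 0]), int(tree.merges[node - N, 1])
            left, right = min(a, b), max(a, b)
            stack.append(right)
            stack.append(left)
    positions = np.empty(N, dtype=int)
    positions[order] = np.arange(1, N + 1)
    return positions


def ks_score(positions_reduction: np.ndarray, positions_full: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic between two position
    samples: the supremum absolute difference of their empirical CDFs."""
    a = np.asarray(positions_reduction, dtype=float)
    b = np.asarray(positions_full, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("position samples must be non-empty")
    return float(ks_2samp(a, b).statistic)


def score_all(tree: LinkageTree, labels, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Score every reduction against the full model.

    ``labels`` is the (set id, bitmask) label per leaf, aligned with the
    dissimilarity-matrix rows the tree was built from.  Returns a table
    with one row per bitmask: reduction size, KS score, consistency flag
    (score < alpha) and the best-model marker.  The full model (all-zero
    bitmask) scores 0 by definition.
    """
    labels = list(labels)
    if len(labels) != tree.leaf_count:
        raise ValueError("one label required per leaf")
    positions = leaf_positions(tree)
    masks = [m for _, m in labels]
    full_mask = "0" * len(masks[0])
    by_mask: dict[str, list[int]] = {}
    for pos, mask in zip(positions, masks):
        by_mask.setdefault(mask, []).append(pos)
    if full_mask not in by_mask:
        raise ValueError("full model (all-zero bitmask) missing from labels")
    full_pos = np.array(by_mask[full_mask])
    rows = []
    for mask in sorted(by_mask, key=lambda m: (m.count("1"), m)):
        score = 0.0 if mask == full_mask else ks_score(np.array(by_mask[mask]), full_pos)
        rows.append({
            "bitmask": mask,
            "size": mask.count("1"),
            "score": score,
            "consistent": bool(score < alpha),
        })
    table = pd.DataFrame(rows)
    table["best"] = False
    best = best_model(table)
    if best is not None:
        table.loc[table["bitmask"] == best, "best"] = True
    return table


def best_model(table: pd.DataFrame) -> str | None:
    """Bitmask of the consistent reduction with the most clamped complexes;
    ties broken by lowest score, then lexicographically smallest bitmask."""
    cons = table[table["consistent"]]
    if cons.empty:
        return None
    cons = cons.sort_values(["size", "score", "bitmask"],
                            ascending=[False, True, True], kind="mergesort")
    return str(cons.iloc[0]["bitmask"])


def prefilter_reductions(table: pd.DataFrame, threshold: float) -> list[str]:
    """Bitmasks scoring below ``threshold`` in a pilot run, for carrying
    into a larger run; the full model is always retained."""
    full_mask = "0" * len(str(table["bitmask"].iloc[0]))
    keep = [str(m) for m, s in zip(table["bitmask"], table["score"]) if s < threshold]
    if full_mask not in keep:
        keep.insert(0, full_mask)
    return sorted(keep, key=lambda m: (m.count("1"), m))


# -- text exports ----------------------------------------------------------


def write_linkage(path, tree: LinkageTree) -> None:
    """Merge table: left id, right id, height, new cluster size."""
    with open(path, "w") as fh:
        fh.write("left\tright\theight\tsize\n")
        for a, b, h, s in tree.merges:
            fh.write(f"{int(a)}\t{int(b)}\t{repr(float(h))}\t{int(s)}\n")


def write_score_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=None)
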