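"""Author-to-lattice matching and author similarity.

Each author's thresholded z-map is compared to every lattice node's weight
volume with the cosine similarity, giving the match matrix C (authors x
nodes); standardized scores Z = (C - mean) / sd are pooled over all entries
of C, so a node query like "authors with Z > 1.96" selects the top ~2.5% of
all match scores. Pairwise Euclidean distances between rows of C give the
author-author distance matrix M, the basis for ranked similar-author lists
and hierarchical clustering (complete linkage on M as the dissimilarity),
with the tree cut both at fixed heights and at fixed group counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .lattice import Lattice
from .revinf import LabelMap

#: Default standardized-score threshold for node queries (top ~2.5%).
DEFAULT_Z_CUT = 1.96
#: Default cap on the number of authors a node query returns.
DEFAULT_MATCH_CAP = 50
#: Default dendrogram cut heights.
DEFAULT_CUT_HEIGHTS = (1.0, 2.0, 2.5, 3.0, 3.5, 4.0)
#: Default dendrogram cut group counts.
DEFAULT_CUT_KS = (5, 10, 15, 20, 25, 30, 50, 60, 70, 80, 90, 100)


def cosine(a, b) -> float:
    """Cosine of the angle between two vectors.

    A zero-norm vector (an author map with no significant voxels) makes the
    angle undefined; 0 is returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine of a zero-norm vector is undefined; returning 0",
                      stacklevel=2)
        return 0.0
    return float(a @ b / (na * nb))


@dataclass
class MatchMatrix:
    """C: authors x nodes cosine scores; Z: standardized over all entries."""

    authors: list[str]
    n_nodes: int
    C: np.ndarray
    Z: np.ndarray = field(default=None)  # type: ignore[assignment]
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.authors), self.n_nodes):
            raise ValueError("C shape does not match authors x nodes")
        if self.Z is None:
            self.Z = standardize(self.C)
        else:
            self.Z = np.asarray(self.Z, dtype=float)

    def row(self, author: str) -> np.ndarray:
        try:
            return self.C[self.authors.index(author)]
        except ValueError:
            raise KeyError(f"unknown author: {author}") from None


def standardize(C: np.ndarray) -> np.ndarray:
    """(C - mean) / sd pooled over all entries; all-zero if sd degenerates."""
    sd = C.std(ddof=1) if C.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(C)
    return (C - C.mean()) / sd


def match_matrix(
    author_maps: dict[str, LabelMap | np.ndarray], lattice: Lattice
) -> MatchMatrix:
    """Cosine of every author z-map against every node weight vector.

    Author rows are sorted by author id. Authors whose map is all-zero get
    a zero row and are flagged.
    """
    authors = sorted(author_maps)
    if not authors:
        raise ValueError("no author maps")
    vecs = np.vstack(
        [
            author_maps[a].z
            if isinstance(author_maps[a], LabelMap)
            else np.asarray(author_maps[a], float)
            for a in authors
        ]
    )
    if vecs.shape[1] != lattice.n_voxels:
        raise ValueError("author maps and lattice weights are on different grids")
    a_norm = np.linalg.norm(vecs, axis=1)
    w_norm = np.linalg.norm(lattice.weights, axis=1)
    flagged = [authors[i] for i in np.flatnonzero(a_norm == 0)]
    denom = np.outer(np.where(a_norm == 0, 1.0, a_norm), np.where(w_norm == 0, 1.0, w_norm))
    C = (vecs @ lattice.weights.T) / denom
    C[a_norm == 0, :] = 0.0
    C[:, w_norm == 0] = 0.0
    return MatchMatrix(authors=authors, n_nodes=lattice.n_nodes, C=C, flagged=flagged)


def top_authors_for_node(
    mm: MatchMatrix,
    node: int,
    z_cut: float = DEFAULT_Z_CUT,
    cap: int = DEFAULT_MATCH_CAP,
) -> list[tuple[str, float]]:
    """Authors most highly matched to a node: standardized score above
    ``z_cut``, ranked by descending raw cosine, truncated to ``cap``."""
    if not 0 <= node < mm.n_nodes:
        raise ValueError(f"node {node} out of range")
    hits = np.flatnonzero(mm.Z[:, node] > z_cut)
    ranked = sorted(
        ((mm.authors[i], float(mm.C[i, node])) for i in hits),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:cap]


@dataclass
class DistanceMatrix:
    """Authors x authors Euclidean distances between rows of C."""

    authors: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.authors)
        if self.M.shape != (n, n):
            raise ValueError("M must be square over the author list")


def distance_matrix(mm: MatchMatrix) -> DistanceMatrix:
    if len(mm.authors) < 2:
        raise ValueError("need at least 2 authors")
    M = squareform(pdist(mm.C, metric="euclidean"))
    return DistanceMatrix(authors=list(mm.authors), M=M)


def ranked_list(dm: DistanceMatrix, author: str) -> list[tuple[str, float]]:
    """Similarity ranking for one author: the author itself first (distance
    0), then all others by ascending distance, ties by author id."""
    if author not in dm.authors:
        raise KeyError(f"unknown author: {author}")
    i = dm.authors.index(author)
    others = sorted(
        ((dm.authors[j], float(dm.M[i, j])) for j in range(len(dm.authors)) if j != i),
        key=lambda t: (t[1], t[0]),
    )
    return [(author, 0.0)] + others


@dataclass
class Dendrogram:
    """Agglomerative clustering result: scipy linkage over the author list."""

    authors: list[str]
    linkage: np.ndarray


def hcluster(dm: DistanceMatrix, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of authors with M as the dissimilarity.

    Complete linkage by default (the R ``hclust`` default).
    """
    condensed = squareform(dm.M, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(authors=list(dm.authors), linkage=Z)


def cut(
    dendro: Dendrogram,
    heights=DEFAULT_CUT_HEIGHTS,
    ks=DEFAULT_CUT_KS,
) -> dict[str, dict[str, int]]:
    """Cut the tree at each height and each group count.

    Returns ``{"h:2.5": {author: group}, "k:20": {...}, ...}`` with group
    ids 1-based. Cutting by k yields exactly k groups (k <= n required);
    cutting at height h keeps together everything merged at height <= h.
    """
    n = len(dendro.authors)
    out: dict[str, dict[str, int]] = {}
    for h in heights:
        flat = hierarchy.fcluster(dendro.linkage, t=h, criterion="distance")
        out[f"h:{_fmt(h)}"] = dict(zip(dendro.authors, (int(g) for g in flat)))
    for k in ks:
        if k > n:
            raise ValueError(f"cannot cut {n} authors into {k} groups")
        flat = hierarchy.cut_tree(dendro.linkage, n_clusters=k).ravel()
        out[f"k:{k}"] = dict(zip(dendro.authors, (int(g) + 1 for g in flat)))
    return out


def _fmt(h: float) -> str:
    return f"{h:g}"


def write_matrix_csv(values: np.ndarray, row_ids, col_ids, path) -> None:
    pd.DataFrame(values, index=list(row_ids), columns=list(col_ids)).to_csv(path)


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_groups_json(groups: dict[str, dict[str, int]], path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(groups, indent=1, sort_keys=True))


def read_groups_json(path) -> dict[str, dict[str, int]]:
    from pathlib import Path

    return json.loads(Path(path).read_text())
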