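"""Structural landscape of a mutant panel: similarity matrix, PCA, k-means.

The all-pairs overall-similarity matrix over the native and mutant
structure models is projected onto its first two principal components;
the number of structural groups is chosen from the k-means inertia curve
(elbow = largest second difference) and constructs are grouped by k-means
with many restarts.  Each group reports a centroid construct: the member
closest to the group mean in the projected plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .compare import overall_similarity
from .fold import PairProbabilityMatrix

__all__ = [
    "SimilarityMatrix",
    "StructureGrouping",
    "build_similarity_matrix",
    "pca_project",
    "choose_k_inertia",
    "kmeans_groups",
]

DEFAULT_K_RANGE = range(1, 9)
KMEANS_RESTARTS = 100


@dataclass
class SimilarityMatrix:
    labels: list
    values: np.ndarray  # square, diagonal 1, entries in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class StructureGrouping:
    labels: list
    group: np.ndarray            # group index per construct
    centroids: dict              # group index -> centroid construct label
    k: int
    inertia_curve: dict = field(default_factory=dict)
    coords: Optional[np.ndarray] = None

    def members(self, g: int) -> list:
        return [lab for lab, gg in zip(self.labels, self.group) if gg == g]


def build_similarity_matrix(
    matrices: Sequence[tuple[str, PairProbabilityMatrix]],
    region: Optional[tuple[int, int]] = None,
    cutoff: float = 0.1,
    symmetric: bool = False,
) -> SimilarityMatrix:
    """All-pairs overall similarity over labeled pairing-probability matrices.

    Entry (a, b) treats construct b as the reference; the diagonal is
    forced to exactly 1.
    """
    labels = [lab for lab, _ in matrices]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate construct labels: {dupes}")
    if len(labels) < 2:
        raise ValueError("need at least 2 constructs")
    n = len(labels)
    vals = np.eye(n)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            vals[a, b] = overall_similarity(
                matrices[a][1], matrices[b][1], region=region,
                cutoff=cutoff, symmetric=symmetric,
            )
    return SimilarityMatrix(labels=labels, values=vals)


def pca_project(matrix: SimilarityMatrix, n_components: int = 2):
    """Project similarity-matrix rows onto the top principal components.

    Returns ``(coords, explained_variance_ratio)``.  Component signs are
    fixed by making the largest-magnitude loading positive, so the
    projection is fully deterministic.
    """
    if matrix.n < n_components:
        raise ValueError("more components than constructs")
    rows = matrix.values
    if np.allclose(rows.std(axis=0), 0):
        return np.zeros((matrix.n, n_components)), np.zeros(n_components)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(rows)
    for c in range(n_components):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    return coords, pca.explained_variance_ratio_


def _inertia(coords: np.ndarray, k: int, seed: int) -> float:
    if k == 1:
        center = coords.mean(axis=0)
        return float(((coords - center) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    km.fit(coords)
    return float(km.inertia_)


def choose_k_inertia(
    matrix: SimilarityMatrix,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    seed: int = 0,
    coords: Optional[np.ndarray] = None,
    noise_floor: float = 1e-3,
) -> tuple[int, dict]:
    """Pick k from the k-means inertia curve.

    The elbow is the k with the largest second difference of the
    log-inertia curve.  The logarithmic scale makes the elbow invariant
    to the absolute separation scale, which matters when cluster sizes
    are unbalanced (the distance between a large group and the rest then
    dwarfs the distances among small groups).  Inertia below
    ``noise_floor`` times the total (k = 1) inertia is clamped as noise.
    Returns ``(k, inertia_curve)``.
    """
    if matrix.n < 3:
        return 1, {}
    if coords is None:
        coords, _ = pca_project(matrix)
    ks = sorted(k for k in k_range if 1 <= k <= matrix.n - 1)
    curve = {k: _inertia(coords, k, seed) for k in ks}
    total = curve[ks[0]]
    if total <= 1e-12:
        return 1, curve
    floor = noise_floor * total
    logc = {k: np.log(max(v, floor)) for k, v in curve.items()}
    best_k, best_d2 = 1, 0.0
    for idx in range(1, len(ks) - 1):
        k = ks[idx]
        d2 = logc[ks[idx - 1]] - 2 * logc[k] + logc[ks[idx + 1]]
        if d2 > best_d2:
            best_k, best_d2 = k, d2
    return best_k, curve


def kmeans_groups(
    matrix: SimilarityMatrix,
    k: Optional[int] = None,
    seed: int = 0,
    on_projection: bool = True,
) -> StructureGrouping:
    """Cluster constructs into structural groups.

    Clustering runs on the 2-D PCA projection by default (set
    ``on_projection=False`` to cluster the raw similarity rows).  Group
    indices are relabeled by the smallest member index so the output is
    invariant to construct input order, and each group's centroid
    construct is its member nearest the group mean.
    """
    coords, _ = pca_project(matrix)
    data = coords if on_projection else matrix.values
    if k is None:
        k, curve = choose_k_inertia(matrix, seed=seed, coords=coords)
    else:
        curve = {}
    if not 1 <= k <= matrix.n:
        raise ValueError(f"k={k} outside [1, {matrix.n}]")
    if k == 1:
        assign = np.zeros(matrix.n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
        assign = km.fit_predict(data)

    # canonical relabeling: order groups by their first occurrence among
    # lexicographically sorted labels (input-order invariant)
    order = np.argsort(np.array([str(l) for l in matrix.labels], dtype=object))
    relabel = {}
    for idx in order:
        g = assign[idx]
        if g not in relabel:
            relabel[g] = len(relabel)
    group = np.array([relabel[g] for g in assign])

    centroids = {}
    for g in range(k):
        members = np.nonzero(group == g)[0]
        center = data[members].mean(axis=0)
        dists = np.linalg.norm(data[members] - center, axis=1)
        centroids[g] = matrix.labels[members[int(np.argmin(dists))]]
    return StructureGrouping(
        labels=list(matrix.labels), group=group, centroids=centroids,
        k=k, inertia_curve=curve, coords=coords,
    )
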