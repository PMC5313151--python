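"""Landscape classification into forestland types.

Forestland types are distinct combinations of species a site can carry;
they are derived here by seeded k-means clustering of the per-cell vectors
of original PSD values, with a labelling rule naming each type after its
highest-suitability species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from compsd.psd import PsdStack
from compsd.raster import RasterSurface

__all__ = ["ForestlandMap", "classify_forestland", "label_types"]


@dataclass
class ForestlandMap:
    """Categorical type map plus per-type centroid suitability vectors."""

    raster: RasterSurface  # integer type ids 1..n, NaN where unclassified
    centroids: pd.DataFrame  # index: type id, columns: species codes
    labels: dict[int, str]

    @property
    def type_ids(self) -> list[int]:
        return [int(i) for i in self.centroids.index]


def classify_forestland(
    psd_stack: PsdStack, n_types: int = 12, seed: int = 0
) -> ForestlandMap:
    """Partition jointly-valid cells into n_types by k-means on PSD vectors.

    Deterministic for a given seed (k-means++ initialization, 10 restarts).
    Type ids are renumbered 1..n by decreasing cluster size so the numbering
    is stable under permutations of the species order.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    mat, mask = psd_stack.as_matrix()
    if mat.shape[0] < n_types:
        raise ValueError(
            f"only {mat.shape[0]} valid cells but n_types={n_types} requested"
        )
    km = KMeans(n_clusters=n_types, n_init=10, random_state=seed)
    raw = km.fit_predict(mat)
    # renumber clusters by decreasing size (ties by centroid order) -> ids 1..n
    sizes = np.bincount(raw, minlength=n_types)
    order = np.argsort(-sizes, kind="stable")
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    ids = np.array([remap[int(c)] for c in raw])

    grid = np.full(psd_stack[psd_stack.species[0]].shape, np.nan)
    grid[mask] = ids
    template = psd_stack[psd_stack.species[0]]
    raster = template.copy_with(grid)
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, n_types + 1),
        columns=psd_stack.species,
    )
    fmap = ForestlandMap(raster=raster, centroids=centroids, labels={})
    return label_types(fmap)


def label_types(
    fmap: ForestlandMap, top_n: int = 3, min_centroid: float = 0.2
) -> ForestlandMap:
    """Name each type by its up-to-top_n species with centroid PSD >= min_centroid.

    Codes are hyphen-joined in decreasing centroid order ("rS-wP-eH" style);
    a type with no species above the cutoff falls back to "type<i>".
    Duplicate names get a numeric suffix so labels stay unique.
    """
    labels: dict[int, str] = {}
    used: dict[str, int] = {}
    for tid in fmap.type_ids:
        row = fmap.centroids.loc[tid]
        qual = row[row >= min_centroid].sort_values(ascending=False, kind="stable")
        name = "-".join(qual.index[:top_n]) if len(qual) else f"type{tid}"
        if name in used:
            used[name] += 1
            name = f"{name}.{used[name]}"
        else:
            used[name] = 1
        labels[tid] = name
    fmap.labels = labels
    return fmap
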