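"""Spatial niches and neighborhood cell-type composition embeddings.

Each observation's *niche* is the set of spatially adjacent observations:
itself plus its k nearest neighbors (single-cell resolution) or itself plus
all spots strictly within ``radius_multiplier`` grid units (spot
resolution, where one grid unit is the median nearest-neighbor distance).
The embedding row of an observation is the mean annotation row over its
niche — a probability vector over cell types that fuses spatial context
with the cell-type annotation.  Because the vocabulary of cell types is
shared across slices, per-slice embeddings concatenate into one comparable
matrix, which is what makes joint multi-slice domain detection possible
without any batch correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .data import MultiSliceSet, SpatialSlice, SIMPLEX_ATOL

__all__ = [
    "NeighborParams",
    "NeighborGraph",
    "NicheEmbedding",
    "knn_neighbors",
    "radius_neighbors",
    "compute_embedding",
    "concat_embeddings",
    "embed_multislice",
]

# brute-force all-pairs distances below this size: exact, fully deterministic
# (distance ties broken by ascending index); KD-tree above it
_BRUTE_FORCE_MAX = 4096


@dataclass(frozen=True)
class NeighborParams:
    """Niche construction parameters.

    ``k`` (default 30) applies in KNN mode; ``radius_multiplier`` (default
    2) applies in radius mode, measured in multiples of ``grid_unit``, the
    median distance from an observation to its nearest other observation.
    """

    mode: str
    k: int = 30
    radius_multiplier: float = 2.0
    include_self: bool = True
    grid_unit: float | None = None

    def __post_init__(self):
        if self.mode not in ("knn", "radius"):
            raise ValueError("mode must be 'knn' or 'radius'")
        if self.mode == "knn" and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode == "radius" and self.radius_multiplier <= 0:
            raise ValueError("radius_multiplier must be positive")


@dataclass(frozen=True)
class NeighborGraph:
    """Per-observation niches within one slice (lists of row indices)."""

    neighbors: tuple[np.ndarray, ...]
    params: NeighborParams

    def __post_init__(self):
        n = len(self.neighbors)
        for i, nb in enumerate(self.neighbors):
            if len(np.unique(nb)) != len(nb):
                raise ValueError(f"duplicate indices in niche of observation {i}")
            if len(nb) and (nb.min() < 0 or nb.max() >= n):
                raise ValueError(f"niche of observation {i} has out-of-range indices")
            if self.params.include_self and i not in nb:
                raise ValueError(f"niche of observation {i} does not contain itself")

    def sizes(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])


def knn_neighbors(
    slice_: SpatialSlice, k: int = 30, include_self: bool = True
) -> NeighborGraph:
    """Niches = self plus the ``k`` nearest other observations (Euclidean).

    Distance ties are broken by ascending observation index so that results
    are identical across runs and platforms.
    """
    params = NeighborParams("knn", k=k, include_self=include_self)
    n = slice_.n_obs
    if k >= n:
        raise ValueError(
            f"k={k} requires at least k+1={k + 1} observations in slice "
            f"{slice_.slice_id!r} (has {n}); reduce k"
        )
    coords = slice_.coords
    neighbors = []
    if n <= _BRUTE_FORCE_MAX:
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        for i in range(n):
            row = d2[i].copy()
            row[i] = -1.0  # self always sorts first
            order = np.argsort(row, kind="stable")  # stable => index tie-break
            nb = order[: k + 1]
            if not include_self:
                nb = order[1 : k + 1]
            neighbors.append(np.array(sorted(nb), dtype=int))
    else:
        tree = cKDTree(coords)
        dist, idx = tree.query(coords, k=k + 1)
        for i in range(n):
            order = np.lexsort((idx[i], dist[i]))
            nb = idx[i][order]
            nb = nb[nb != i][:k]
            if include_self:
                nb = np.concatenate(([i], nb))
            neighbors.append(np.array(sorted(nb), dtype=int))
    return NeighborGraph(tuple(neighbors), params)


def estimate_grid_unit(coords: np.ndarray) -> float:
    """Median distance from each observation to its nearest other one."""
    if coords.shape[0] < 2:
        raise ValueError("at least two observations are needed to estimate grid unit")
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    unit = float(np.median(dist[:, 1]))
    if unit <= 0:
        raise ValueError("grid unit is zero (all coordinates coincide?)")
    return unit


def radius_neighbors(
    slice_: SpatialSlice, radius_multiplier: float = 2.0, include_self: bool = True
) -> NeighborGraph:
    """Niches = self plus all spots strictly closer than
    ``radius_multiplier`` grid units.

    The strict cutoff means that on a regular grid ``radius_multiplier=1``
    yields self-only niches (the embedding then degenerates to the spot's
    own annotation), while ``radius_multiplier=2`` captures the 3x3 block
    of adjacent spots.  A relative guard of 1e-9 keeps spots at exactly the
    cutoff distance out despite floating-point rounding.
    """
    if radius_multiplier <= 0:
        raise ValueError("radius_multiplier must be positive")
    unit = estimate_grid_unit(slice_.coords)
    params = NeighborParams(
        "radius",
        radius_multiplier=radius_multiplier,
        include_self=include_self,
        grid_unit=unit,
    )
    r = radius_multiplier * unit
    tree = cKDTree(slice_.coords)
    raw = tree.query_ball_point(slice_.coords, r)
    neighbors = []
    for i, cand in enumerate(raw):
        cand = np.array(sorted(cand), dtype=int)
        d = np.linalg.norm(slice_.coords[cand] - slice_.coords[i], axis=1)
        keep = cand[d < r * (1.0 - 1e-9)]
        if not include_self:
            keep = keep[keep != i]
        elif i not in keep:  # defensive; self is at distance 0
            keep = np.sort(np.concatenate(([i], keep)))
        neighbors.append(keep)
    return NeighborGraph(tuple(neighbors), params)


@dataclass(frozen=True)
class NicheEmbedding:
    """Per-observation probability vectors over cell types.

    Rows live on the simplex; ``slice_of`` records the originating slice of
    each row so that multi-slice results can be backtracked.
    """

    values: np.ndarray
    cell_types: tuple[str, ...]
    obs_ids: tuple[str, ...]
    slice_of: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "obs_ids", tuple(self.obs_ids))
        object.__setattr__(self, "slice_of", tuple(self.slice_of))
        n, t = values.shape
        if len(self.obs_ids) != n or len(self.slice_of) != n:
            raise ValueError("obs_ids/slice_of length must match the value rows")
        if len(self.cell_types) != t:
            raise ValueError("cell_types length must match the value columns")
        if np.any(values < -SIMPLEX_ATOL) or np.any(values > 1 + SIMPLEX_ATOL):
            raise ValueError("embedding entries must lie in [0, 1]")
        if n and not np.allclose(values.sum(axis=1), 1.0, atol=SIMPLEX_ATOL, rtol=0):
            raise ValueError("embedding rows must sum to 1")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.cell_types))
        df.insert(0, "slice_id", list(self.slice_of))
        df.insert(0, "obs_id", list(self.obs_ids))
        return df

    @classmethod
    def from_frame(cls, df) -> "NicheEmbedding":
        cols = [c for c in df.columns if c not in ("obs_id", "slice_id")]
        return cls(
            df[cols].to_numpy(dtype=float),
            tuple(cols),
            tuple(df["obs_id"].astype(str)),
            tuple(df["slice_id"].astype(str)),
        )


def compute_embedding(slice_: SpatialSlice, graph: NeighborGraph) -> NicheEmbedding:
    """Embedding row i = mean annotation row over niche(i)."""
    ann = slice_.annotation.values
    if len(graph.neighbors) != slice_.n_obs:
        raise ValueError("neighbor graph was built on a different slice")
    values = np.empty_like(ann)
    for i, nb in enumerate(graph.neighbors):
        if len(nb) == 0:
            raise ValueError(
                f"observation {i} in slice {slice_.slice_id!r} has an empty niche"
            )
        values[i] = ann[nb].mean(axis=0)
    return NicheEmbedding(
        values,
        slice_.cell_types,
        slice_.obs_ids,
        tuple([slice_.slice_id] * slice_.n_obs),
    )


def concat_embeddings(
    mset: MultiSliceSet, per_slice: list[NicheEmbedding]
) -> NicheEmbedding:
    """Row-stack per-slice embeddings (slice order, then observation order)."""
    ref = per_slice[0].cell_types
    for emb in per_slice[1:]:
        if emb.cell_types != ref:
            raise ValueError("embeddings have mismatched cell-type orderings")
    if len(per_slice) != len(mset):
        raise ValueError("one embedding per slice is required")
    return NicheEmbedding(
        np.vstack([e.values for e in per_slice]),
        ref,
        tuple(o for e in per_slice for o in e.obs_ids),
        tuple(s for e in per_slice for s in e.slice_of),
    )


def embed_multislice(
    mset: MultiSliceSet,
    mode: str = "knn",
    k: int = 30,
    radius_multiplier: float = 2.0,
    include_self: bool = True,
) -> NicheEmbedding:
    """Per-slice niches + embedding, concatenated across slices."""
    embs = []
    for s in mset:
        if mode == "knn":
            graph = knn_neighbors(s, k=k, include_self=include_self)
        elif mode == "radius":
            graph = radius_neighbors(
                s, radius_multiplier=radius_multiplier, include_self=include_self
            )
        else:
            raise ValueError("mode must be 'knn' or 'radius'")
        embs.append(compute_embedding(s, graph))
    return concat_embeddings(mset, embs)
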