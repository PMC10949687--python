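"""Slice-level clustering from spatial-domain composition.

After joint multi-slice domain detection, every slice i is summarized by
its domain composition C^i = [D_ij / M_i] for j = 1..N, where D_ij counts
the slice's members of domain j (0 when the domain is absent) and M_i is
the slice's observation count.  Hierarchical clustering of these
composition rows groups slices by shared spatial organization — e.g.
developmental time points or disease conditions — and is contrasted with
the spatially blind baseline that uses each slice's global cell-type
composition instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import MultiSliceSet
from .distances import pairwise_distances
from .domains import Dendrogram, DomainAssignment, backtrack_to_slices, hierarchical_cluster

__all__ = [
    "SliceComposition",
    "slice_composition",
    "composition_from_assignment",
    "cluster_slices",
    "baseline_celltype_composition",
]


@dataclass(frozen=True)
class SliceComposition:
    """Per-slice probability vector over columns (domains or cell types)."""

    slice_ids: tuple[str, ...]
    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "slice_ids", tuple(self.slice_ids))
        object.__setattr__(self, "columns", tuple(self.columns))
        if v.ndim != 2 or v.shape[0] != len(self.slice_ids):
            raise ValueError("one value row per slice is required")
        if v.shape[1] != len(self.columns):
            raise ValueError("one column name per value column is required")
        if np.any(v < 0) or not np.allclose(v.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("composition rows must lie on the simplex")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "slice_id", list(self.slice_ids))
        return df


def slice_composition(
    per_slice_assignments: Mapping[str, Sequence[int]], n_domains: int
) -> SliceComposition:
    """C^i = [D_ij / M_i] from per-slice domain label vectors (labels 1..N)."""
    slice_ids, rows = [], []
    for sid, labels in per_slice_assignments.items():
        labels = np.asarray(labels, dtype=int)
        if labels.size == 0:
            raise ValueError(f"slice {sid!r} has no observations")
        if labels.min() < 1 or labels.max() > n_domains:
            raise ValueError(
                f"slice {sid!r} has domain labels outside 1..{n_domains}"
            )
        counts = np.bincount(labels, minlength=n_domains + 1)[1:]
        slice_ids.append(str(sid))
        rows.append(counts / labels.size)
    columns = tuple(f"Domain_{n_domains}_{j}" for j in range(1, n_domains + 1))
    return SliceComposition(tuple(slice_ids), np.array(rows), columns)


def composition_from_assignment(
    assignment: DomainAssignment, mset: MultiSliceSet
) -> SliceComposition:
    """Convenience: joint assignment -> per-slice tables -> composition."""
    per_slice = backtrack_to_slices(assignment, mset)
    return slice_composition(
        {sid: df["domain_label"].to_numpy() for sid, df in per_slice.items()},
        assignment.n_domains,
    )


def cluster_slices(
    comp: SliceComposition,
    metric: str = "euclidean",
    linkage: str = "complete",
    n_groups: int | None = None,
):
    """Hierarchical clustering of slices by composition rows.

    Defaults follow the usual heatmap-clustering convention (Euclidean
    distance, complete linkage); ``jsd`` is also valid since rows are
    probability vectors.  Returns ``(dendrogram, group_labels)`` where
    ``group_labels`` is ``None`` unless ``n_groups`` requests a cut.
    """
    if comp.n_slices < 2:
        raise ValueError("at least two slices are required for slice clustering")
    dist = pairwise_distances(comp.values, metric=metric)
    tree = hierarchical_cluster(dist, linkage=linkage)
    labels = None
    if n_groups is not None:
        from scipy.cluster import hierarchy

        if not 1 <= n_groups <= comp.n_slices:
            raise ValueError("n_groups out of range")
        labels = hierarchy.cut_tree(tree.linkage, n_clusters=n_groups).ravel() + 1
    return tree, labels


def baseline_celltype_composition(mset: MultiSliceSet) -> SliceComposition:
    """Spatially blind baseline: per-slice mean cell-type annotation row."""
    rows = [s.annotation.values.mean(axis=0) for s in mset]
    return SliceComposition(mset.slice_ids, np.array(rows), mset.cell_types)
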