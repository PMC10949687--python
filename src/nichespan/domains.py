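"""Hierarchical spatial-domain detection on embedding distances.

Observations from all slices are clustered jointly (never per slice and
then matched): agglomerative clustering of the pairwise embedding
distances yields one dendrogram whose cuts define spatial domains at any
resolution.  A partition into ``N1`` domains names its members
``Domain_{N1}_{N2}`` where ``N2`` indexes domains by decreasing size, so
``Domain_{N1}_1`` is always the dominant structure at that resolution and
partitions at higher resolutions refine those at lower ones.  The number
of domains can be chosen automatically from the tree shape (an adaptive
gap cut in the spirit of dynamic tree cutting), set manually, or explored
across resolutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .data import MultiSliceSet
from .distances import DistanceMatrix, pairwise_distances
from .embedding import NicheEmbedding, embed_multislice

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "DomainAssignment",
    "DomainProfile",
    "hierarchical_cluster",
    "cut_domains",
    "auto_domain_number",
    "backtrack_to_slices",
    "domain_profile",
    "detect_domains",
]

LINKAGES = ("complete", "average", "ward", "single")

# deepSplit sensitivity -> (max diameter ratio, min relative separation).
# A candidate cut into k clusters is accepted only when (a) the clusters'
# internal diameter (the height just below the cut) is at most the given
# fraction of the merge height just above it, and (b) the mean
# between-cluster distance exceeds the mean within-cluster distance by the
# given relative margin.  Lower levels are more conservative.
_DEEP_SPLIT_PARAMS = {
    0: (0.15, 0.95),
    1: (0.25, 0.90),
    2: (0.35, 0.85),
    3: (0.45, 0.70),
    4: (0.60, 0.50),
}


@dataclass(frozen=True)
class Dendrogram:
    """An agglomerative tree in SciPy linkage-matrix form (n-1 merges)."""

    linkage: np.ndarray
    method: str

    def __post_init__(self):
        z = np.asarray(self.linkage, dtype=float)
        if z.ndim != 2 or z.shape[1] != 4:
            raise ValueError("linkage matrix must have shape (n-1, 4)")
        object.__setattr__(self, "linkage", z)

    @property
    def n_leaves(self) -> int:
        return self.linkage.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.linkage)

    def to_newick(self, leaf_names=None) -> str:
        """Serialize as a Newick string with height-difference branch lengths."""
        n = self.n_leaves
        if leaf_names is None:
            leaf_names = [f"obs{i}" for i in range(n)]
        if len(leaf_names) != n:
            raise ValueError("one leaf name per observation is required")
        tree = hierarchy.to_tree(self.linkage)
        # iterative post-order traversal; trees can be deep for chained merges
        parts: dict[int, str] = {}
        stack = [(tree, False)]
        while stack:
            node, expanded = stack.pop()
            if node.is_leaf():
                parts[node.id] = str(leaf_names[node.id])
                continue
            if not expanded:
                stack.append((node, True))
                stack.append((node.left, False))
                stack.append((node.right, False))
            else:
                lb = max(node.dist - node.left.dist, 0.0)
                rb = max(node.dist - node.right.dist, 0.0)
                parts[node.id] = (
                    f"({parts[node.left.id]}:{lb:g},{parts[node.right.id]}:{rb:g})"
                )
        return parts[tree.id] + ";"


@dataclass(frozen=True)
class DomainAssignment:
    """Per-observation domain labels at one resolution.

    ``labels`` are integers in ``1..n_domains``; ``names`` follow the
    ``Domain_{N1}_{N2}`` convention with ``N2`` equal to the own label.
    """

    labels: np.ndarray
    names: np.ndarray
    n_domains: int
    dendrogram: Dendrogram | None = None

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        names = np.asarray(self.names, dtype=object)
        if labels.shape != names.shape:
            raise ValueError("labels and names must align")
        if labels.size and (labels.min() < 1 or labels.max() > self.n_domains):
            raise ValueError("labels must lie in 1..n_domains")
        for lab, name in zip(labels, names):
            if name != f"Domain_{self.n_domains}_{lab}":
                raise ValueError(f"name {name!r} does not match label {lab}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "names", names)

    @property
    def n_obs(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class DomainProfile:
    """Per-domain size and mean cell-type composition."""

    domain_names: tuple[str, ...]
    counts: np.ndarray
    compositions: np.ndarray
    cell_types: tuple[str, ...]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.compositions, columns=list(self.cell_types))
        df.insert(0, "count", self.counts)
        df.insert(0, "domain_name", list(self.domain_names))
        return df


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a distance matrix (default complete linkage)."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if dist.n < 2:
        raise ValueError("at least two observations are required for clustering")
    z = hierarchy.linkage(dist.condensed(), method=linkage)
    return Dendrogram(z, linkage)


def cut_domains(tree: Dendrogram, n_domains: int) -> DomainAssignment:
    """Cut the tree into exactly ``n_domains`` clusters and name them.

    Domain index ``N2`` is assigned by decreasing cluster size; size ties
    are broken by the smallest contained observation index.
    """
    n = tree.n_leaves
    if not 1 <= n_domains <= n:
        raise ValueError(f"n_domains must be in 1..{n}, got {n_domains}")
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=n_domains).ravel()
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    names = np.array([f"Domain_{n_domains}_{lab}" for lab in labels], dtype=object)
    return DomainAssignment(labels, names, n_domains, tree)


def _cut_separation(dist_values: np.ndarray, labels: np.ndarray) -> float:
    """Relative separation (B - W) / B of a partition, where W and B are
    the mean within- and between-cluster pairwise distances."""
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    within = dist_values[same & off]
    between = dist_values[~same]
    if between.size == 0:
        return 0.0
    w = float(within.mean()) if within.size else 0.0
    b = float(between.mean())
    if b <= 0:
        return 0.0
    return (b - w) / b


def auto_domain_number(
    tree: Dendrogram,
    dist: DistanceMatrix,
    deep_split: int = 2,
    min_cluster_size: int = 20,
) -> int:
    """Select the number of domains adaptively from the tree shape.

    An adaptive variant of dynamic tree cutting: the candidate resolution
    is the cut whose merge-height gap is largest (considering up to n/2
    clusters).  The cut is kept only when its clusters look like genuine
    structure rather than an arbitrary slice through a homogeneous cloud:
    the clusters must merge well above their own internal diameter, and
    the mean between-cluster distance must exceed the mean within-cluster
    distance by a margin.  Both thresholds are controlled by
    ``deep_split`` (default level 2; higher levels split more eagerly).
    A tree without such structure is a single homogeneous domain and
    returns 1.  Clusters smaller than ``min_cluster_size`` (capped at
    n/2) are absorbed into their siblings rather than counted.
    """
    n = tree.n_leaves
    if n < 4:
        raise ValueError(
            "automatic domain-number selection needs at least 4 observations; "
            "set the domain number manually"
        )
    if deep_split not in _DEEP_SPLIT_PARAMS:
        raise ValueError("deep_split must be in 0..4")
    if dist.n != n:
        raise ValueError("distance matrix does not match the tree")
    max_diameter_ratio, min_separation = _DEEP_SPLIT_PARAMS[deep_split]
    min_size = max(1, min(min_cluster_size, n // 2))
    h = np.sort(tree.heights)
    if h[-1] - h[0] <= 0:
        return 1
    k_max = max(2, n // 2)
    ks = np.arange(2, min(k_max, n - 1) + 1)
    # cutting into k clusters removes the top k-1 merges; the admissible
    # threshold window for k clusters has width h[n-k] - h[n-k-1]
    gaps = h[n - ks] - h[n - ks - 1]
    k_star = int(ks[np.argmax(gaps)])
    diameter, merge_height = h[n - k_star - 1], h[n - k_star]
    if merge_height <= 0 or diameter / merge_height > max_diameter_ratio:
        return 1
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=k_star).ravel()
    if _cut_separation(dist.values, raw) < min_separation:
        return 1
    sizes = np.bincount(raw)
    n_big = int((sizes >= min_size).sum())
    if n_big <= 1:
        return 1
    if n_big < k_star:
        logger.info(
            "absorbed %d cluster(s) smaller than %d members",
            k_star - n_big,
            min_size,
        )
    return n_big


def backtrack_to_slices(assignment: DomainAssignment, mset: MultiSliceSet) -> dict:
    """Split a joint assignment back into per-slice tables.

    Returns ``{slice_id: DataFrame(obs_id, domain_label, domain_name)}``;
    global domain identities are preserved, so a domain absent from a slice
    simply contributes no rows there.
    """
    import pandas as pd

    if assignment.n_obs != mset.n_obs:
        raise ValueError(
            f"assignment covers {assignment.n_obs} observations, slice set has "
            f"{mset.n_obs}"
        )
    out = {}
    offset = 0
    for s in mset:
        sl = slice(offset, offset + s.n_obs)
        out[s.slice_id] = pd.DataFrame(
            {
                "obs_id": list(s.obs_ids),
                "domain_label": assignment.labels[sl],
                "domain_name": assignment.names[sl],
            }
        )
        offset += s.n_obs
    return out


def domain_profile(
    assignment: DomainAssignment, embedding: NicheEmbedding
) -> DomainProfile:
    """Mean embedding row and member count per domain."""
    if assignment.n_obs != embedding.n_obs:
        raise ValueError("assignment and embedding must align")
    names, counts, comps = [], [], []
    for lab in range(1, assignment.n_domains + 1):
        mask = assignment.labels == lab
        if not mask.any():
            logger.warning("domain %d is empty and excluded from the profile", lab)
            continue
        names.append(f"Domain_{assignment.n_domains}_{lab}")
        counts.append(int(mask.sum()))
        comps.append(embedding.values[mask].mean(axis=0))
    return DomainProfile(
        tuple(names), np.array(counts), np.array(comps), embedding.cell_types
    )


def detect_domains(
    mset: MultiSliceSet,
    n_domains: int | str = "auto",
    metric: str = "jsd",
    linkage: str = "complete",
    mode: str = "knn",
    k: int = 30,
    radius_multiplier: float = 2.0,
    include_self: bool = True,
    deep_split: int = 2,
    min_cluster_size: int = 20,
):
    """End-to-end multi-slice domain detection.

    Embeds every slice, concatenates, computes pairwise distances, builds
    the dendrogram and cuts it at ``n_domains`` (or at the automatically
    selected resolution when ``"auto"``).  Returns
    ``(assignment, embedding, dendrogram)``.
    """
    emb = embed_multislice(
        mset, mode=mode, k=k, radius_multiplier=radius_multiplier,
        include_self=include_self,
    )
    dist = pairwise_distances(emb, metric=metric)
    tree = hierarchical_cluster(dist, linkage=linkage)
    if n_domains == "auto":
        n_domains = auto_domain_number(
            tree, dist, deep_split=deep_split, min_cluster_size=min_cluster_size
        )
    assignment = cut_domains(tree, int(n_domains))
    return assignment, emb, tree
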