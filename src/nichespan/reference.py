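"""Reference-based spatial-domain annotation by centroid matching.

A *spatial reference* is a domain-annotated data set reduced to one
centroid per domain: the mean niche-composition embedding of all its
members (which stays on the simplex).  A query observation is annotated in
four steps: build the reference centroids, embed the query, compute the
Jensen-Shannon divergence from each query row to every centroid, and
assign the domain with minimum divergence.  The achieved minimum is
reported as a confidence score (0 = exact centroid match, ln 2 = maximal
divergence).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import _pairwise_jsd
from .domains import DomainAssignment
from .embedding import NicheEmbedding

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialReference",
    "build_reference",
    "annotate_query",
    "enumerate_reference_query_pairs",
]


@dataclass(frozen=True)
class SpatialReference:
    """Per-domain centroid composition vectors with domain names."""

    cell_types: tuple[str, ...]
    centroids: np.ndarray
    domain_names: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.centroids, dtype=float)
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "domain_names", tuple(self.domain_names))
        if c.ndim != 2 or c.shape[0] < 1:
            raise ValueError("centroids must be a (D, T) matrix with D >= 1")
        if c.shape[0] != len(self.domain_names):
            raise ValueError("one domain name per centroid is required")
        if c.shape[1] != len(self.cell_types):
            raise ValueError("centroid columns must match cell types")
        if len(set(self.domain_names)) != len(self.domain_names):
            raise ValueError("domain names must be unique")
        if np.any(c < 0) or not np.allclose(c.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("centroid rows must lie on the simplex")

    @property
    def n_domains(self) -> int:
        return self.centroids.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.centroids, columns=list(self.cell_types))
        df.insert(0, "domain_name", list(self.domain_names))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpatialReference":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "domain_name"]
        return cls(tuple(cols), df[cols].to_numpy(float), tuple(df["domain_name"].astype(str)))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cell_types": list(self.cell_types),
                    "domain_names": list(self.domain_names),
                    "centroids": self.centroids.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "SpatialReference":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["cell_types"]), np.array(d["centroids"]), tuple(d["domain_names"])
        )

    @classmethod
    def load(cls, path) -> "SpatialReference":
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls.from_json(path)
        return cls.from_csv(path)


def build_reference(
    embedding: NicheEmbedding, assignment: DomainAssignment
) -> SpatialReference:
    """Centroid per domain = mean embedding row over its members."""
    if embedding.n_obs != assignment.n_obs:
        raise ValueError("embedding and assignment must align")
    names, centroids = [], []
    for lab in range(1, assignment.n_domains + 1):
        mask = assignment.labels == lab
        if not mask.any():
            raise ValueError(f"domain {lab} has no members; cannot build a centroid")
        names.append(f"Domain_{assignment.n_domains}_{lab}")
        centroids.append(embedding.values[mask].mean(axis=0))
    return SpatialReference(embedding.cell_types, np.array(centroids), tuple(names))


def _harmonize_query(
    query: NicheEmbedding, ref: SpatialReference
) -> np.ndarray:
    """Reorder/zero-fill query columns to the reference vocabulary, then
    renormalize rows.  Query-only cell types are dropped (their mass is
    redistributed by the renormalization); rows with no mass on shared
    types fall back to the uniform distribution with a warning."""
    shared = [c for c in ref.cell_types if c in query.cell_types]
    if not shared:
        raise ValueError("query and reference share no cell types")
    t = len(ref.cell_types)
    out = np.zeros((query.n_obs, t))
    qpos = {c: j for j, c in enumerate(query.cell_types)}
    for j, c in enumerate(ref.cell_types):
        if c in qpos:
            out[:, j] = query.values[:, qpos[c]]
    sums = out.sum(axis=1)
    dead = sums == 0
    if np.any(dead):
        logger.warning(
            "%d query row(s) have no mass on reference cell types; "
            "falling back to a uniform composition",
            int(dead.sum()),
        )
        out[dead] = 1.0 / t
        sums[dead] = 1.0
    return out / sums[:, None]


def annotate_query(
    query: NicheEmbedding, ref: SpatialReference, max_jsd: float | None = None
) -> pd.DataFrame:
    """Assign each query observation the reference domain with minimum JSD.

    Ties go to the first-listed reference domain.  When ``max_jsd`` is set,
    observations whose best divergence exceeds it are labelled
    ``"unassigned"`` (off by default: the minimum is otherwise assigned
    unconditionally).  Returns a table with columns
    ``obs_id, slice_id, domain_name, jsd_score``.
    """
    q = _harmonize_query(query, ref)
    stacked = np.vstack([q, ref.centroids])
    d = _pairwise_jsd(stacked)[: q.shape[0], q.shape[0]:]
    best = np.argmin(d, axis=1)  # first minimum wins ties
    scores = d[np.arange(q.shape[0]), best]
    names = np.array([ref.domain_names[b] for b in best], dtype=object)
    if max_jsd is not None:
        names[scores > max_jsd] = "unassigned"
    return pd.DataFrame(
        {
            "obs_id": list(query.obs_ids),
            "slice_id": list(query.slice_of),
            "domain_name": names,
            "jsd_score": scores,
        }
    )


def enumerate_reference_query_pairs(dataset_ids) -> list[tuple[str, str]]:
    """All ordered (reference, query) pairs over distinct data sets.

    With ``D`` data sets each serving as reference and as query (never
    against itself) this yields ``D * (D - 1)`` ordered pairs — 56 for
    eight data sets.
    """
    ids = [str(d) for d in dataset_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset ids must be unique")
    return list(permutations(ids, 2))
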