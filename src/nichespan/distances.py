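"""Divergences and pairwise distance matrices between embedding rows.

The default dissimilarity between two niche composition vectors P and Q is
the Jensen-Shannon divergence

    JSD(P, Q) = (KL(P, M) + KL(Q, M)) / 2,   M = (P + Q) / 2,

built from the Kullback-Leibler divergence KL(P, Q) = sum_i P_i log(P_i/Q_i)
with natural logarithms (0 log 0 = 0), so JSD is symmetric, finite on the
simplex and bounded by ln 2.  Five alternatives are supported for
robustness studies: Manhattan, Euclidean, and the cosine / Pearson /
Spearman similarities converted through ``1 - similarity``.  The choice of
log base only rescales JSD and leaves every ranking and clustering
unchanged; it is switchable via the ``base`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "kl_divergence",
    "jsd",
    "manhattan",
    "pairwise_distances",
    "DistanceMatrix",
    "METRICS",
]

METRICS = ("jsd", "manhattan", "euclidean", "cosine", "pearson", "spearman")


def _check_prob(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    if not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError(f"{name} must sum to 1 (got {v.sum():.6g})")
    return v


def kl_divergence(p, q, base: float | None = None) -> float:
    """KL(P, Q) = sum_i P_i log(P_i / Q_i), with 0 log 0 = 0.

    Requires Q_i > 0 wherever P_i > 0; otherwise the divergence is infinite
    and a ``ValueError`` is raised.  (The mixture in :func:`jsd` guarantees
    this never happens there.)
    """
    p = _check_prob(p, "P")
    q = _check_prob(q, "Q")
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same length")
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("KL divergence is infinite: P has mass where Q has none")
    val = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    if base is not None:
        val /= np.log(base)
    return val


def jsd(p, q, base: float | None = None) -> float:
    """Jensen-Shannon divergence; in [0, ln 2] for natural logs.

    Smaller values indicate more similar composition vectors.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same length")
    m = 0.5 * (p + q)
    val = 0.5 * (kl_divergence(p, m) + kl_divergence(q, m))
    val = max(val, 0.0)  # clip float round-off at identity
    if base is not None:
        val /= np.log(base)
    return val


def manhattan(p, q) -> float:
    """Sum of absolute coordinate differences."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same length")
    return float(np.abs(p - q).sum())


def _entropy_rows(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(x > 0, x * np.log(x), 0.0)
    return -t.sum(axis=1)


def _pairwise_jsd(x: np.ndarray) -> np.ndarray:
    """All-pairs JSD via JSD(P,Q) = H(M) - (H(P) + H(Q)) / 2, blockwise."""
    n = x.shape[0]
    h = _entropy_rows(x)
    out = np.empty((n, n))
    block = max(1, int(4_000_000 / max(n * x.shape[1], 1)))
    for start in range(0, n, block):
        stop = min(n, start + block)
        m = 0.5 * (x[start:stop, None, :] + x[None, :, :])
        hm = _entropy_rows(m.reshape(-1, x.shape[1])).reshape(stop - start, n)
        out[start:stop] = hm - 0.5 * (h[start:stop, None] + h[None, :])
    return np.maximum(out, 0.0)


def _correlation_distance(x: np.ndarray, warn_label: str) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows get similarity 0."""
    sd = x.std(axis=1)
    constant = sd == 0
    if np.any(constant):
        logger.warning(
            "%d constant row(s) have undefined %s correlation; "
            "similarity set to 0",
            int(constant.sum()),
            warn_label,
        )
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1)
    norm_safe = np.where(norm == 0, 1.0, norm)
    r = (xc @ xc.T) / np.outer(norm_safe, norm_safe)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    return 1.0 - np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if self.metric in ("jsd", "manhattan", "euclidean") and np.any(v < 0):
            raise ValueError(f"{self.metric} distances must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def pairwise_distances(embedding, metric: str = "jsd") -> DistanceMatrix:
    """Full pairwise dissimilarity matrix under one of the six metrics.

    ``embedding`` is a :class:`~nichespan.embedding.NicheEmbedding` or a
    plain ``(n, T)`` array of rows.  Correlation-style metrics (cosine,
    pearson, spearman) are computed as similarities and converted through
    ``1 - similarity``; rows with undefined correlation (zero variance) get
    similarity 0 with a logged warning instead of aborting the run.
    """
    x = getattr(embedding, "values", embedding)
    x = np.asarray(x, dtype=float)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "jsd":
        d = _pairwise_jsd(x)
    elif metric == "manhattan":
        d = squareform(pdist(x, metric="cityblock"), checks=False)
    elif metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"), checks=False)
    elif metric == "cosine":
        norm = np.linalg.norm(x, axis=1)
        zero = norm == 0
        if np.any(zero):
            logger.warning(
                "%d zero row(s) have undefined cosine similarity; set to 0",
                int(zero.sum()),
            )
        norm_safe = np.where(zero, 1.0, norm)
        sim = (x @ x.T) / np.outer(norm_safe, norm_safe)
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
        d = 1.0 - np.clip(sim, -1.0, 1.0)
    elif metric == "pearson":
        d = _correlation_distance(x, "Pearson")
    else:  # spearman, average ranks for ties
        ranks = rankdata(x, axis=1, method="average")
        d = _correlation_distance(ranks, "Spearman")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, metric)
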