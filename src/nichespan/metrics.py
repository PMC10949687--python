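"""Partition-agreement metrics: adjusted Rand index and macro-F1.

Both are computed from the contingency table between predicted and true
labels.  The ARI is the chance-corrected pair-counting index

    ARI = [ sum_ij C(n_ij,2) - E ] / [ (sum_i C(a_i,2) + sum_j C(b_j,2))/2 - E ]

with E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2), where n_ij counts
observations in predicted cluster i and true cluster j and a_i, b_j are
the margins.  macro-F1 averages the per-true-domain F1 = 2PR/(P+R) over
the N distinct truth domains; zero denominators (a domain never predicted,
or never true) yield 0 with a warning, so degenerate one-cluster
predictions score low instead of erroring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ContingencyTable", "ari", "macro_f1", "per_domain_prf"]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts n_ij of observations in predicted cluster i / true cluster j."""

    counts: np.ndarray
    pred_labels: tuple
    true_labels: tuple

    @classmethod
    def from_labels(cls, pred, truth) -> "ContingencyTable":
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        if pred.shape != truth.shape or pred.ndim != 1:
            raise ValueError("pred and truth must be 1-D vectors of equal length")
        pl, pi = np.unique(pred, return_inverse=True)
        tl, ti = np.unique(truth, return_inverse=True)
        counts = np.zeros((len(pl), len(tl)), dtype=np.int64)
        np.add.at(counts, (pi, ti), 1)
        return cls(counts, tuple(pl.tolist()), tuple(tl.tolist()))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def a(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def b(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _comb2(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def ari(pred, truth) -> float:
    """Adjusted Rand index between two labelings (any hashable labels).

    1 for identical partitions, ~0 for independent ones (and exactly 0 for
    a single-cluster prediction against any non-trivial truth); can be
    negative.  When both partitions are trivial (all singletons or one
    block) the partitions are identical and 1 is returned.
    """
    table = ContingencyTable.from_labels(pred, truth)
    if table.n < 2:
        raise ValueError("at least two observations are required")
    sum_ij = _comb2(table.counts).sum()
    sum_a = _comb2(table.a).sum()
    sum_b = _comb2(table.b).sum()
    expected = sum_a * sum_b / _comb2(table.n)
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        return 1.0
    return float((sum_ij - expected) / denom)


def per_domain_prf(pred, truth) -> dict:
    """Precision, recall and F1 per *true* domain label.

    Labels are compared by name, as after reference-based annotation where
    prediction and truth share a naming scheme.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be nonempty vectors of equal length")
    out = {}
    for dom in sorted(set(truth.tolist()), key=str):
        tp = int(np.sum((pred == dom) & (truth == dom)))
        n_pred = int(np.sum(pred == dom))
        n_true = int(np.sum(truth == dom))
        if n_pred == 0:
            logger.warning("domain %r never predicted; precision set to 0", dom)
            precision = 0.0
        else:
            precision = tp / n_pred
        recall = tp / n_true
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        out[dom] = {"precision": precision, "recall": recall, "f1": f1}
    return out


def macro_f1(pred, truth) -> float:
    """Unweighted mean of per-true-domain F1 over the N distinct truth domains."""
    prf = per_domain_prf(pred, truth)
    return float(np.mean([v["f1"] for v in prf.values()]))
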