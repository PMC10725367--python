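"""Correlation-band edge anomaly filtering.

Edges are banded by correlation strength: weak (< 0.4), strong (>= 0.7) and
an untouched middle band.  Two kinds of edges are treated as anomalies and
removed: strong edges joining nodes of *different* classes, and weak edges
joining nodes of the *same* class.  Middle-band edges always pass through.
A count report is emitted with the filtered table so the removal arithmetic
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .graph import EdgeTable

WEAK_CUT = 0.4     # weight <  WEAK_CUT  -> weak band
STRONG_CUT = 0.7   # weight >= STRONG_CUT -> strong band


class LabelError(KeyError):
    pass


@dataclass(frozen=True)
class EdgeClusters:
    weak: EdgeTable
    strong: EdgeTable
    other: EdgeTable


@dataclass(frozen=True)
class FilterReport:
    total: int
    strong: int
    strong_cross_class_removed: int
    after_strong_removal: int
    weak: int
    weak_same_class_removed: int
    final: int

    def to_dict(self) -> dict:
        return asdict(self)


def _subset(edges: EdgeTable, keep: np.ndarray) -> EdgeTable:
    return EdgeTable(edges.source[keep], edges.target[keep],
                     edges.weight[keep], edges.n_nodes)


def cluster_edges(edges: EdgeTable, weak_cut: float = WEAK_CUT,
                  strong_cut: float = STRONG_CUT) -> EdgeClusters:
    """Partition edges into weak / other / strong correlation bands."""
    w = edges.weight
    weak = w < weak_cut
    strong = w >= strong_cut
    return EdgeClusters(weak=_subset(edges, weak),
                        strong=_subset(edges, strong),
                        other=_subset(edges, ~(weak | strong)))


def filter_anomalies(edges: EdgeTable, labels,
                     weak_cut: float = WEAK_CUT,
                     strong_cut: float = STRONG_CUT):
    """Remove strong cross-class and weak same-class edges.

    Returns (filtered EdgeTable, FilterReport).  Idempotent; conserves
    counts: final = total - strong_removed - weak_removed.
    """
    labels = np.asarray(labels)
    if len(edges) and (edges.source.max() >= labels.size or
                       edges.target.max() >= labels.size):
        raise LabelError("edge endpoint has no label")
    if np.asarray(labels, dtype=float).size and not np.isfinite(
            np.asarray(labels, dtype=float)).all():
        raise LabelError("labels must be finite")
    w = edges.weight
    same = labels[edges.source] == labels[edges.target]
    strong = w >= strong_cut
    weak = w < weak_cut
    drop_strong = strong & ~same
    drop_weak = weak & same
    keep = ~(drop_strong | drop_weak)
    report = FilterReport(
        total=len(edges),
        strong=int(strong.sum()),
        strong_cross_class_removed=int(drop_strong.sum()),
        after_strong_removal=len(edges) - int(drop_strong.sum()),
        weak=int(weak.sum()),
        weak_same_class_removed=int(drop_weak.sum()),
        final=int(keep.sum()),
    )
    return _subset(edges, keep), report


def filter_arithmetic(total: int, strong: int, strong_cross_class: int,
                      weak: int, weak_same_class: int) -> FilterReport:
    """The filter's bookkeeping applied to externally supplied band counts.

    Useful for auditing externally reported removal counts without the underlying
    edge list: intermediate = total - strong_cross_class and
    final = intermediate - weak_same_class.
    """
    return FilterReport(
        total=total,
        strong=strong,
        strong_cross_class_removed=strong_cross_class,
        after_strong_removal=total - strong_cross_class,
        weak=weak,
        weak_same_class_removed=weak_same_class,
        final=total - strong_cross_class - weak_same_class,
    )
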