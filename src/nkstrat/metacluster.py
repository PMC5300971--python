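"""Pool per-sample cluster centroids, rescale, merge and name NK populations.

The pooled centroids are linearly rescaled per marker so the empirical
5th/95th percentiles map to -3/+3 (values outside that band are kept, not
clipped), hierarchically clustered (Euclidean distance, average linkage),
cut into a fixed number of metaclusters, filtered for rarely represented
groups, and annotated into named NK populations by marker-level rules on
the rescaled scale: neg < -1, low in [-1, 0), dim in [0, 1.5),
bright/high >= 1.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_gating import NK_MARKERS
from . import synthetic as _syn

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

# level cutoffs on the rescaled (-3..+3-anchored) scale
CUT_HIGH = 1.5
CUT_LOW = 0.0
CUT_NEG = -1.0


@dataclass
class RescaledCenters:
    """Pooled cluster centroids after the per-marker percentile rescale."""

    table: pd.DataFrame  # sample_id, cluster_id, then rescaled marker columns
    anchors: dict[str, tuple[float, float]]  # marker -> (p5, p95) of the input
    markers: list[str]

    def matrix(self) -> np.ndarray:
        return self.table[self.markers].to_numpy(float)

    def keys(self) -> list[tuple]:
        return list(zip(self.table["sample_id"], self.table["cluster_id"]))

    def apply_map(self, marker: str, value: float) -> float:
        """Evaluate the stored linear map of one marker at a raw value."""
        p5, p95 = self.anchors[marker]
        return -3.0 + 6.0 * (value - p5) / (p95 - p5)


def rescale_centers(
    cluster_table: pd.DataFrame, markers: Sequence[str] = NK_MARKERS
) -> RescaledCenters:
    """Anchor each marker's pooled 5th/95th percentile to -3/+3.

    Percentiles use inclusive linear interpolation; a marker whose two
    anchors coincide cannot be rescaled and raises a ValueError naming it.
    """
    markers = list(markers)
    out = cluster_table[["sample_id", "cluster_id"]].copy()
    anchors: dict[str, tuple[float, float]] = {}
    for marker in markers:
        values = cluster_table[marker].to_numpy(float)
        if len(np.unique(values)) < 2:
            raise ValueError(f"marker {marker}: fewer than 2 distinct center values")
        p5, p95 = np.percentile(values, [5.0, 95.0])
        if p95 == p5:
            raise ValueError(f"marker {marker}: 5th and 95th percentiles coincide")
        anchors[marker] = (float(p5), float(p95))
        out[marker] = -3.0 + 6.0 * (values - p5) / (p95 - p5)
    return RescaledCenters(table=out, anchors=anchors, markers=markers)


@dataclass
class Dendrogram:
    """Merge tree of the pooled centroids (scipy linkage encoding)."""

    linkage_matrix: np.ndarray  # (n-1, 4) scipy format
    labels: list  # leaf identifiers, input order
    metric: str
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage_matrix))


def hcl(
    data: RescaledCenters | pd.DataFrame | np.ndarray,
    metric: str = "euclidean",
    method: str = "average",
    labels: Sequence | None = None,
) -> Dendrogram:
    """Hierarchical clustering of rows (default Euclidean, average linkage)."""
    if isinstance(data, RescaledCenters):
        X = data.matrix()
        labels = labels if labels is not None else data.keys()
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy(float)
        labels = labels if labels is not None else list(data.index)
    else:
        X = np.asarray(data, dtype=float)
        labels = labels if labels is not None else list(range(len(X)))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in the input")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    return Dendrogram(
        linkage_matrix=Z, labels=list(labels), metric=metric, method=method
    )


def cut_dendrogram(dendrogram: Dendrogram, n_groups: int) -> np.ndarray:
    """Cut into exactly ``n_groups`` connected components.

    Returns one integer label per leaf, in input order, numbered 0..n-1.
    """
    n = dendrogram.n_leaves
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must be in [1, {n}], got {n_groups}")
    labels = hierarchy.cut_tree(dendrogram.linkage_matrix, n_clusters=n_groups)[:, 0]
    return np.asarray(labels, dtype=int)


@dataclass
class Metacluster:
    """A group of merged clusters interpreted as one NK population."""

    id: int
    members: list[tuple]  # (sample_id, cluster_id) keys
    signature: dict[str, float]  # unweighted mean of member centroids (rescaled)
    name: str = UNCLASSIFIED
    retained: bool = True

    @property
    def n_members(self) -> int:
        return len(self.members)


def build_metaclusters(
    rescaled: RescaledCenters, labels: np.ndarray
) -> list[Metacluster]:
    """Group the rescaled centroids by cut label; signatures are unweighted
    means of member centroids."""
    keys = rescaled.keys()
    X = rescaled.matrix()
    out = []
    for g in sorted(set(int(v) for v in labels)):
        idx = np.flatnonzero(labels == g)
        sig = X[idx].mean(axis=0)
        out.append(
            Metacluster(
                id=g,
                members=[keys[i] for i in idx],
                signature=dict(zip(rescaled.markers, map(float, sig))),
            )
        )
    return out


def filter_rare(
    metaclusters: Sequence[Metacluster], min_members: int = 3
) -> list[Metacluster]:
    """Flag metaclusters with fewer than ``min_members`` member clusters as
    not retained. Their events stay in the total-NK denominator downstream;
    they simply contribute no named population."""
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    out = [replace(m, retained=m.n_members >= min_members) for m in metaclusters]
    if all(not m.retained for m in out):
        logger.warning(
            "min_members=%d flags every metacluster as rare", min_members
        )
    return out


@dataclass(frozen=True)
class AnnotationRule:
    """Priority-ordered conjunction of per-marker level predicates."""

    name: str
    conditions: tuple[tuple[str, str, float], ...]  # (marker, "ge"|"lt", cutoff)

    def matches(self, signature: dict[str, float]) -> bool:
        for marker, op, cut in self.conditions:
            v = signature[marker]
            if op == "ge" and not v >= cut:
                return False
            if op == "lt" and not v < cut:
                return False
        return True


def default_annotation_rules(
    high: float = CUT_HIGH, low: float = CUT_LOW, neg: float = CUT_NEG
) -> list[AnnotationRule]:
    """Rules for the 13 default NK populations, most specific first."""
    CD56, CD16, A, C, S = NK_MARKERS  # A=NKG2A, C=NKG2C, S=CD57

    def rule(name, *conds):
        return AnnotationRule(name, tuple(conds))

    dim = ((CD56, "ge", neg), (CD56, "lt", high))
    return [
        rule(_syn.P_BRIGHT, (CD56, "ge", high), (CD16, "lt", neg)),
        rule(_syn.P_BRIGHT_LOW, (CD56, "ge", high), (CD16, "lt", low)),
        rule(_syn.P_NEG_A, (CD56, "lt", neg), (CD16, "ge", low), (A, "ge", low)),
        rule(_syn.P_NEG_57, (CD56, "lt", neg), (CD16, "ge", low), (S, "ge", low)),
        rule(_syn.P_NEG, (CD56, "lt", neg), (CD16, "ge", low)),
        rule(_syn.P_DIM_LOW, *dim, (CD16, "lt", low)),
        rule(_syn.P_AC, *dim, (CD16, "ge", low), (A, "ge", low), (C, "ge", low)),
        rule(_syn.P_A57, *dim, (CD16, "ge", low), (A, "ge", low), (S, "ge", low)),
        rule(_syn.P_A, *dim, (CD16, "ge", low), (A, "ge", low)),
        rule(_syn.P_C57, *dim, (CD16, "ge", low), (C, "ge", low), (S, "ge", low)),
        rule(_syn.P_C, *dim, (CD16, "ge", low), (C, "ge", low)),
        rule(_syn.P_57, *dim, (CD16, "ge", low), (S, "ge", low)),
        rule(
            _syn.P_TN,
            (CD56, "ge", low), (CD56, "lt", high), (CD16, "ge", low),
            (A, "lt", low), (C, "lt", low), (S, "lt", low),
        ),
    ]


DEFAULT_ANNOTATION_RULES = default_annotation_rules()


def annotate(
    metaclusters: Sequence[Metacluster],
    rules: Sequence[AnnotationRule] = DEFAULT_ANNOTATION_RULES,
) -> list[Metacluster]:
    """Name each retained metacluster by the first matching rule.

    Several metaclusters may share a name (they are pooled downstream);
    signatures matching no rule are labelled ``unclassified``.
    """
    out = []
    for m in metaclusters:
        if not m.retained:
            out.append(replace(m, name=UNCLASSIFIED))
            continue
        name = next((r.name for r in rules if r.matches(m.signature)), UNCLASSIFIED)
        out.append(replace(m, name=name))
    return out


# ---------------------------------------------------------------------------
# exports

def to_newick(dendrogram: Dendrogram, name_leaf: Callable | None = None) -> str:
    """Newick string with branch lengths derived from merge heights."""
    Z = dendrogram.linkage_matrix
    n = dendrogram.n_leaves
    heights = {i: 0.0 for i in range(n)}

    def leaf_name(i):
        lbl = dendrogram.labels[i]
        if name_leaf is not None:
            return name_leaf(lbl)
        if isinstance(lbl, tuple):
            return "_".join(str(p) for p in lbl)
        return str(lbl)

    parts: dict[int, str] = {i: leaf_name(i) for i in range(n)}
    for j, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node = n + j
        parts[node] = f"({parts[a]}:{la:.6g},{parts[b]}:{lb:.6g})"
        heights[node] = h
    return parts[2 * n - 2] + ";"


def to_expression_table(rescaled: RescaledCenters) -> pd.DataFrame:
    """MeV-style expression table: one row per cluster, marker columns."""
    df = rescaled.table.copy()
    df.index = [f"{s}:{c}" for s, c in zip(df["sample_id"], df["cluster_id"])]
    return df[rescaled.markers]


__all__ = [
    "RescaledCenters", "Dendrogram", "Metacluster", "AnnotationRule",
    "rescale_centers", "hcl", "cut_dendrogram", "build_metaclusters",
    "filter_rare", "annotate", "default_annotation_rules",
    "DEFAULT_ANNOTATION_RULES", "to_newick", "to_expression_table",
    "UNCLASSIFIED", "CUT_HIGH", "CUT_LOW", "CUT_NEG",
]
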